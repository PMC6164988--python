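# Methods

## The model

`quantrisk` fits Bayesian spatiotemporal *quantile* regression to areal
disease counts. For area `i` and period `t` with observed count `y_it` and
expected count `e_it`,

    y_it ~ Poisson(e_it * mu_it)
    log(mu_it) = eta_it + eps_it
    eta_it = X_it' beta + u_i + v_i + lambda_t + theta_it

where `mu_it` is the relative risk. The error `eps_it` follows an
asymmetric Laplace (AL) law at level `tau` with scale `sigma`, i.e. `mu_it`
is log-Laplace `LL(eta_it, tau, sigma)`. Because the AL error has its
`tau`-quantile at zero, `exp(eta_it)` *is* the `tau`-quantile of the
relative risk: the model regresses a chosen quantile of risk directly,
sidestepping the ill-defined quantiles of the discrete count itself (the
usual alternative — jittering the counts with uniform noise — distorts
small counts badly).

The random effects are the standard disease-mapping set: `u` is an
intrinsic CAR (ICAR) field — each area conditionally Gaussian around its
neighbours' mean with variance `sigma_u^2 / n_i` — forming, with the IID
Gaussian effect `v`, a BYM convolution; `lambda` is a first-order random
walk in time; `theta` is an IID space-time interaction. All standard
deviations carry Unif(0, 10) priors (`sd_prior_upper` is configurable);
regression coefficients, when covariates are supplied, get diffuse
N(0, 1000^2) priors. The AL scale `sigma` receives the same uniform prior
as the other scales — the natural symmetric choice. In the fitted model the
random walk is anchored by `lambda_1 ~ N(0, sigma_lambda^2)`, matching the
generator and making the temporal prior proper.

The mean-regression comparator replaces the AL error with a zero-mean
Gaussian and keeps everything else identical; its `tau`-quantile estimates
are the empirical quantiles of the posterior `mu_it` draws (linear
interpolation of order statistics, the "type 7" rule).

### The log-Laplace density

The three-parameter form `LL(delta, a, b)` has density
`(1/delta) ab/(a+b) (mu/delta)^{b-1}` below `delta` and
`(1/delta) ab/(a+b) (delta/mu)^{a+1}` above. Substituting
`delta = exp(mu_tau)`, `a = tau/sigma`, `b = (1-tau)/sigma` gives the
quantile parameterization with normalizing factor
`(1/mu) tau(1-tau)/sigma` — the algebra is verified in the test suite both
symbolically (pointwise equivalence to 1e-12) and by quadrature
(normalization to 1e-6), including shapes with `b < 1` whose density
diverges (integrably) at zero. Density work is done in log space; the
linear-scale pdf is a thin wrapper. Parameter validation raises rather than
clamps: silently repaired `tau` or `sigma` would corrupt the quantile
semantics downstream.

## Inference

Sampling is adaptive Metropolis-within-Gibbs, written so every block
vectorizes:

- latent `z = log(mu)`: elementwise Gaussian random walks (the conditionals
  are independent across cells given `eta`);
- `theta`, `v`: elementwise / per-region walks;
- `u`: simultaneous elementwise updates within graph color classes (no two
  same-color areas are neighbours, so elementwise accept/reject is exact),
  with the field re-centered to mean zero after each update — the
  conventional resolution of the intrinsic prior's flat direction;
- `lambda`: the same trick on even/odd periods;
- scales: log-scale random walks with a Jacobian and hard rejection outside
  the uniform prior's support. The pairwise-difference ICAR prior is
  normalized with rank `n - 1` on a connected graph.

Two extra move families fight the hierarchy's weak identification, which
otherwise leaves the scale parameters mixing far too slowly for desk-scale
chains. *Group scaling* moves rescale a block and its scale together,
`(x, s) -> (g x, g s)`, walking the (effect, scale) ridge. *Transfer* moves
shift level between blocks whose sum is all the likelihood sees — trend vs
region effects, region effects vs interaction rows, structured vs
unstructured spatial effects — and are decided by the prior terms alone.
Both are standard reparameterization-style moves; they are repeated three
times per sweep (they cost little next to the field updates) and cut the
worst-case R-hat on the variance components from ~3 to ~1.05 at desk-scale
chain lengths.

Step sizes adapt toward 0.44 acceptance during burn-in (Robbins-Monro,
frozen afterwards so the retained chain is a valid Markov chain). Chains
start overdispersed: `z` at the jittered log SIR, effects and scales drawn
at random per chain. Runs are bit-reproducible: one root seed spawns
independent per-chain streams.

Defaults are 2 chains x (4,000 burn-in + 4,000 retained) — desk-scale
settings chosen so a 16-region, 5-period fit takes tens of seconds;
production analyses of this model family have historically used chains an
order of magnitude longer, and the `iterations`/`burn_in`/`thin` arguments
expose that choice. Convergence is reported via the classic two-stage
Gelman potential scale reduction factor (between/within chain variances,
not the newer rank-normalized split variant), computed per monitored scalar
(the five scales and every latent log risk); a fit whose worst monitored
R-hat reaches 1.1 emits a `ConvergenceWarning` rather than failing
silently. Disconnected region graphs are rejected outright — islands under
an ICAR prior need conventions there is no agreed standard for.

## Adverse-risk detection

Two estimators of the exceedence probability `P(mu_it >= c)`:

- **Monte Carlo**: the fraction of retained posterior draws with
  `mu_it >= c` (inclusive inequality). Nonincreasing in `c` by
  construction.
- **Threshold-quantile**: pin the quantile surface at the threshold,
  `log(c) = log(mu_it) + eps_it`, let the *level* `tau_it` of the AL error
  be unknown with a flat Beta(1, 1) prior, and report its posterior mean
  (median available): under the quantile constraint
  `tau_it = P(c <= mu_it)` exactly. The latent `log(mu_it)` keeps its
  Poisson likelihood; the shared AL scale keeps its uniform prior. Spatial
  and temporal random effects are not duplicated into this model — with
  the location pinned at `log c`, a saturated latent surface would absorb
  them — which is the minimal coherent reading of the construction.

A behaviour worth knowing: with the AL scale *estimated*, the
threshold-quantile model is scale-adaptive. On homogeneous data with `c`
far outside the observed risk range, the scale grows with the distance to
the threshold and the level estimate plateaus mid-range (around 0.4/0.6)
instead of saturating at 0/1; rank ordering across units — what cluster
detection uses — is unaffected, and heterogeneous data anchor the scale so
that genuinely extreme units do approach 0/1. Pinning `sigma` (the `sigma`
argument) restores saturation if absolute calibration at far thresholds is
wanted.

Flags are raised where the exceedence probability passes a conventional
cut-off (0.95 by default; 0.975 and 0.99 are common stricter choices), with
`c = 1` the null-risk baseline and `c = 2` a high-risk screen.

## The synthetic-data generator

The generator emulates the study conditions used throughout the package on
an arbitrary connected graph (a rook lattice stands in for a real county
map): ICAR `u` (variance 1), IID `v`, RW1 `lambda`, interaction `theta`
(each variance 0.2), no intercept and no covariates, log-scale error from a
Student t rescaled to unit variance with df equal to the region's expected
count — large regions get near-Gaussian noise, small ones heavy tails; the
truth is deliberately *not* log-Laplace, so fitting the quantile model is a
misspecification test, and df <= 2 is rejected because a unit-variance
rescaling needs a finite variance. Counts are Poisson with offset `e_i`,
constant over time; when expected counts are not supplied they are drawn
log-uniformly in [20, 2000] so the df = e_i rule produces a realistic
mixture of tail weights. With these settings on a 46-region map the middle
80% of generated risks spans roughly two orders of magnitude — extreme but
matching observed single-county epidemics.

The random effects are drawn **once** per configuration: they define the
fixed true quantile surfaces `Q_tau(mu_it) = exp(eta_it + F_t^{-1}(tau))`
(with the scaled-t quantile of the error), while replicates redraw only the
error and the Poisson layer. The empirical quantile of simulated risks over
replicates therefore converges to the analytic surface cell by cell, and at
`tau = 0.5` the truth is exactly `exp(eta)` by symmetry. ICAR draws use the
spectral pseudo-inverse of the graph Laplacian restricted to its non-null
eigenspace — exact, fast, and verified against the conditional
specification by a Monte-Carlo covariance test. The default replicate
count is 50.

What the generator does not emulate: real adjacency irregularity (county
maps are less regular than lattices), population-driven expected counts,
reporting artefacts, or overdispersion beyond the heavy-tailed log error.
Passing tests demonstrate correct recovery under the stated generative law,
not performance on real surveillance data.

## Evaluation protocol and problem sizes

The evaluation module fits both models to each replicate (the mean model
once — it does not depend on `tau` — the quantile model per level),
extracts the `tau`-quantile surfaces, and aggregates squared error against
the truth. Both mean-per-cell and summed aggregation are exposed (published
tables of this kind rarely state the scale); mean is the default, and the
two differ only by the fixed factor `n x T`. Comparisons in the test suite
run at 10 replicates x 3 levels on the 4x4 lattice.

Recovery checks compare the *replicate-averaged* fitted median surface
with the fixed truth, mirroring how simulation studies of this model
family present estimates averaged over simulated data sets. A single
replicate cannot identify the surface to high precision under these
conditions: the unit-variance error is irreducibly confounded with the
variance-0.2 interaction term, capping the single-fit correlation with
`exp(eta)` near 0.8 for *any* estimator (a Gaussian oracle given the true
hyperparameters does no better); averaging eight replicates lifts the
ceiling above 0.95. The package runs desk-scale problem sizes throughout —
4x4 regions, 5 periods, expected counts in [50, 500] — as its own choice
of test conditions.

## Numerical choices and edge cases

- Empirical quantiles of posterior draws: type-7 linear interpolation.
- R-hat threshold 1.1; the degenerate zero-within-variance case returns 1.
- `ll_cdf` routes the kink value to the lower branch so
  `F(exp(mu_tau)) = tau` is exact in floating point.
- Region/time indexing is label-based in files and dense 0-based
  internally; time periods are ordered integers with no calendar
  semantics.
- Expected counts must be strictly positive; counts may be zero. Readers
  reject malformed input rather than repairing it, with one documented
  exception: one-directional adjacency edges are symmetrized with a
  warning.
- Endemic-window standardization: `e_i = pop_i * (total window counts /
  window length) / total population`, constant over time; the window is a
  set of period indices and `|window|` counts periods.

## Known limitations

- The Metropolis-within-Gibbs sampler is robust but not fast for large
  maps; hundreds of regions with long chains would benefit from the latent
  normal-exponential mixture representation of the AL error (a possible
  extension, not required for correctness here).
- The ICAR field's hard re-centering each sweep is the conventional, not
  exactly measure-preserving, treatment of the intrinsic prior; with the
  transfer moves the induced level shift is absorbed by `v` within a sweep.
- No negative-binomial or zero-inflated observation layers; extra-Poisson
  variation must be carried by the interaction and error terms.
- MSE magnitudes depend on the map, the expected counts and the replicate
  count; only the quantile-vs-mean *direction* is a stable desk-scale
  quantity.
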