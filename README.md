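# quantrisk

Bayesian spatiotemporal **quantile** modelling of disease relative risk for
areal count data, with exceedence-probability cluster / hot-spot detection.

## The problem

Disease-mapping studies usually model the *mean* relative risk of areal
counts. But upper or lower quantiles of risk can respond to structure the
mean misses, and mean regression is fragile under outliers and heavy
tails. Quantile regression for counts is awkward because the count's
distribution function is discrete; the common fix — jittering the counts
with uniform noise — badly distorts small counts typical of rare diseases.

`quantrisk` instead models a chosen quantile of the **relative risk**
μ_it > 0, which is continuous, using the log-Laplace (LL) distribution:

    y_it ~ Poisson(e_it μ_it)
    log μ_it = η_it + ε_it,    ε_it ~ AL(0, τ, σ)
    η_it = X_itᵀβ + u_i + v_i + λ_t + θ_it

with observed counts y_it, expected counts e_it (the offset from indirect
standardization), a BYM convolution of ICAR (u) and IID (v) spatial
effects, a first-order random-walk trend λ, and an IID space-time
interaction θ. Because the asymmetric Laplace error has its τ-quantile at
zero, exp(η_it) **is** the τ-quantile surface of relative risk,
Q_τ(μ_it). Standard-deviation parameters carry Unif(0, 10) priors; fitting
is adaptive Metropolis-within-Gibbs with multi-chain Gelman R-hat
diagnostics.

The package also provides:

- the conventional **mean-regression comparator** (Gaussian error, same
  priors), whose quantile estimates are read off its posterior draws;
- **exceedence probabilities** P(μ_it ≥ c) for adverse-risk detection,
  both as the Monte-Carlo fraction of posterior draws and via the
  threshold-quantile reformulation log c = log μ_it + ε_it with a
  Beta(1, 1) prior on the per-unit level τ_it (whose posterior mean equals
  P(c ≤ μ_it));
- a **synthetic-data generator** (ICAR + IID + RW1 + interaction effects,
  heavy-tailed unit-variance t errors with df tied to the expected count,
  Poisson observation layer) with closed-form true quantile surfaces, plus
  endemic-window expected-rate standardization;
- **evaluation** utilities: quantile-surface MSE comparisons and the
  classic Gelman potential scale reduction factor.

See `docs/methods.md` for the model, sampler and design details.

## Worked example

Simulate a 4×4-county map for 5 years under heavy-tailed non-Laplace
errors, fit the median-risk model, and flag elevated areas:

```python
import numpy as np
from quantrisk import (
    QuantileRiskModel, SimulationConfig, classify_adverse,
    make_lattice_graph, simulate_counts,
)

graph = make_lattice_graph(4, 4)
e = np.exp(np.random.default_rng(1).uniform(np.log(50), np.log(500), 16))
cfg = SimulationConfig(graph=graph, n_times=5, expected_counts=e,
                       n_replicates=1, seed=42)
panels, truth = simulate_counts(cfg)

model = QuantileRiskModel(panels[0], graph, tau=0.5)
res = model.fit(chains=2, iterations=8000, burn_in=4000, seed=7)

print(res.summary().round(3).head(6))
q50 = res.quantile_surface()            # point estimate of Q_0.5(mu_it)
corr = np.corrcoef(q50.ravel(), np.exp(truth.eta).ravel())[0, 1]
print(f"corr(fitted Q0.5, true exp(eta)) = {corr:.3f}")
surf = res.exceedence(c=1.0)            # P(mu_it >= 1) per county-year
print(f"flagged at 0.95: {classify_adverse(surf, 0.95).sum()} of {surf.prob.size}")
```

```
              mean     sd  median   q2.5  q97.5   rhat
parameter
sigma_u      1.140  0.483   1.122  0.242  2.164  1.002
sigma_v      0.488  0.335   0.450  0.016  1.211  1.005
sigma_lam    1.243  0.696   1.081  0.466  3.021  1.000
sigma_theta  0.753  0.299   0.803  0.133  1.208  1.021
sigma_eps    0.244  0.125   0.256  0.022  0.459  1.019
lam[0]       1.439  0.343   1.447  0.720  2.087  1.000
corr(fitted Q0.5, true exp(eta)) = 0.697
flagged at 0.95: 60 of 80
```

`sigma_u … sigma_eps` are the posterior spreads of the spatial, temporal,
interaction and error scales (the generator used component standard
deviations 1.0/0.45/0.45/0.45 on the log scale and unit-variance errors);
all R-hat values are below 1.1, so the two chains agree. A single
replicate identifies the median surface only up to the irreducible
error/interaction confounding — averaging the fitted surface over
replicates, as the evaluation module does, pushes the correlation above
0.9. The 60 flagged county-years are those whose posterior probability of
elevated risk (μ ≥ 1) exceeds 0.95 — many, because this particular
replicate drew a high temporal trend (`lam[0]` ≈ 1.4), so much of the map
genuinely sits above the null risk.

The same pipeline is scriptable from the shell:

```sh
quantrisk simulate --rows 4 --cols 4 --times 5 --replicates 1 --seed 42 --out sim/
quantrisk fit --panel sim/panel_000.csv --adjacency sim/graph.edges \
    --model quantile --tau 0.5 --seed 7 --out fit/
quantrisk detect --panel sim/panel_000.csv --c 1 --seed 7 --out detect/
quantrisk evaluate --rows 4 --cols 4 --replicates 3 --seed 1 --out eval/
quantrisk diagnose --samples fit/samples.csv
```

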