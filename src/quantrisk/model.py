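"""Hierarchical spatiotemporal quantile and mean regression for areal counts.

The quantile model treats the relative risk ``mu_it`` of area ``i`` at time
``t`` as log-Laplace distributed so that a chosen quantile is modeled
directly:

    y_it ~ Poisson(e_it * mu_it)
    log(mu_it) = eta_it + eps_it,   eps_it ~ AL(0, tau, sigma)
    eta_it = X_it' beta + u_i + v_i + lambda_t + theta_it

``exp(eta_it)`` is then exactly the ``tau``-quantile of ``mu_it``.  The
random effects follow the usual disease-mapping priors: ``u`` is an
intrinsic CAR (BYM convolution with the IID effect ``v``), ``lambda`` is a
first-order random walk and ``theta`` an IID space-time interaction; all
standard deviations have Unif(0, ``sd_prior_upper``) priors.

The mean-regression comparator replaces the asymmetric-Laplace error with a
zero-mean Gaussian, keeping likelihood and random-effect priors identical;
its ``tau``-quantile estimates are read off the posterior draws of ``mu_it``.

Both are exposed statsmodels-style: a model object built from
:class:`~quantrisk.data.PanelData` and a :class:`~quantrisk.graph.RegionGraph`
whose ``fit()`` returns a results object carrying the retained draws,
convergence diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import _sampler
from .data import PanelData
from .graph import RegionGraph
from .loglaplace import check_loss

__all__ = [
    "QuantileModelConfig",
    "PosteriorSamples",
    "QuantileRiskModel",
    "MeanRiskModel",
    "QuantileRiskResults",
    "MeanRiskResults",
    "ConvergenceWarning",
    "linear_predictor",
    "log_joint_quantile",
    "fit_quantile_model",
    "fit_mean_model",
    "estimate_quantile_surface",
    "mean_model_quantiles",
]

RHAT_THRESHOLD = 1.1


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when the Gelman diagnostic exceeds its threshold."""


@dataclass
class QuantileModelConfig:
    """Quantile level, prior bound and MCMC settings.

    Defaults (2 chains, 4,000 burn-in + 4,000 retained) are desk-scale
    settings; production analyses historically used far longer chains.
    """

    tau: float = 0.5
    sd_prior_upper: float = 10.0
    chains: int = 2
    iterations: int = 8000
    burn_in: int = 4000
    thin: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must lie in (0, 1), got {self.tau}")
        if not self.sd_prior_upper > 0:
            raise ValueError("sd_prior_upper must be positive")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for the R-hat diagnostic")
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, indexed chain x draw (x parameter dimensions)."""

    draws: dict  # name -> array (chains, n_keep, ...)
    region_ids: list
    times: list

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        return self.draws[name]

    def pooled(self, name: str) -> np.ndarray:
        """Draws with the chain axis folded into the draw axis."""
        a = self.draws[name]
        return a.reshape((-1,) + a.shape[2:])

    def scalar_names(self, params=None):
        """Flattened scalar labels, e.g. ``u[3]`` or ``theta[2,4]``."""
        params = params or list(self.draws)
        out = []
        for p in params:
            shape = self.draws[p].shape[2:]
            if not shape:
                out.append((p, ()))
            else:
                for idx in np.ndindex(shape):
                    out.append((p, idx))
        return out

    def to_dataframe(self, params=None) -> pd.DataFrame:
        """Columnar layout: one row per retained draw, one column per scalar."""
        cols = {}
        for p, idx in self.scalar_names(params):
            label = p if not idx else f"{p}[{','.join(map(str, idx))}]"
            a = self.pooled(p)
            cols[label] = a[(slice(None),) + idx]
        df = pd.DataFrame(cols)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_draws))
        df.insert(1, "draw", np.tile(np.arange(self.n_draws), self.n_chains))
        return df


# ----------------------------------------------------------------------
# reference log joint (used for testing and by power users; the sampler
# evaluates the same terms incrementally)
# ----------------------------------------------------------------------
def linear_predictor(beta, X, u, v, lam, theta) -> np.ndarray:
    """``eta_it = X_it' beta + u_i + v_i + lambda_t + theta_it``."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    lam = np.asarray(lam, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n, T = theta.shape
    if u.shape != (n,) or v.shape != (n,) or lam.shape != (T,):
        raise ValueError("component dimensions do not conform")
    eta = u[:, None] + v[:, None] + lam[None, :] + theta
    if X is not None:
        beta = np.asarray(beta, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[:2] != (n, T) or X.shape[2] != beta.shape[0]:
            raise ValueError("covariate dimensions do not conform")
        eta = eta + X @ beta
    return eta


def log_joint_quantile(
    state: dict, data: PanelData, graph: RegionGraph, config: QuantileModelConfig
) -> float:
    """Log posterior density of the quantile model, up to a constant.

    ``state`` holds ``z`` (= log mu), ``u``, ``v``, ``lam``, ``theta``,
    optional ``beta``, and the scales ``sigma_u, sigma_v, sigma_lam,
    sigma_theta, sigma_eps``.  States outside the support return ``-inf``
    (never raise), so samplers can use it for hard rejection.  The relative
    risk prior is expressed as the asymmetric-Laplace density of
    ``z = log(mu)`` centered at ``eta`` (the same measure as the log-Laplace
    prior on ``mu`` up to the change-of-variables Jacobian).
    """
    scales = [state[k] for k in ("sigma_u", "sigma_v", "sigma_lam", "sigma_theta", "sigma_eps")]
    if any((not np.isfinite(s)) or s <= 0 or s >= config.sd_prior_upper for s in scales):
        return -np.inf
    s_u, s_v, s_lam, s_th, s_eps = (float(s) for s in scales)
    z = np.asarray(state["z"], dtype=float)
    u = np.asarray(state["u"], dtype=float)
    v = np.asarray(state["v"], dtype=float)
    lam = np.asarray(state["lam"], dtype=float)
    theta = np.asarray(state["theta"], dtype=float)
    beta = state.get("beta")
    if not np.all(np.isfinite(z)):
        return -np.inf
    eta = linear_predictor(beta, data.X, u, v, lam, theta)
    tau = config.tau
    n, T = data.y.shape

    mu_mean = data.e * np.exp(z)
    lp = float(np.sum(data.y * np.log(mu_mean) - mu_mean - gammaln(data.y + 1.0)))

    r = z - eta
    lp += float(
        np.sum(np.log(tau * (1.0 - tau) / s_eps) - check_loss(r, tau) / s_eps)
    )

    edges = graph.edges()
    if len(edges):
        diffs = u[edges[:, 0]] - u[edges[:, 1]]
        lp += -(n - 1) * np.log(s_u) - float(diffs @ diffs) / (2.0 * s_u * s_u)
    lp += float(np.sum(-0.5 * np.log(2 * np.pi) - np.log(s_v) - v * v / (2 * s_v * s_v)))
    lam_ext = np.concatenate(([0.0], lam))
    incr = np.diff(lam_ext)
    lp += float(
        np.sum(-0.5 * np.log(2 * np.pi) - np.log(s_lam) - incr * incr / (2 * s_lam * s_lam))
    )
    lp += float(
        np.sum(
            -0.5 * np.log(2 * np.pi) - np.log(s_th) - theta * theta / (2 * s_th * s_th)
        )
    )
    if beta is not None:
        b = np.asarray(beta, dtype=float)
        sd = _sampler.BETA_PRIOR_SD
        lp += float(np.sum(-0.5 * np.log(2 * np.pi) - np.log(sd) - b * b / (2 * sd * sd)))
    return lp


# ----------------------------------------------------------------------
# models
# ----------------------------------------------------------------------
class _BaseRiskModel:
    _error: str

    def __init__(
        self,
        data: PanelData,
        graph: RegionGraph,
        tau: float = 0.5,
        sd_prior_upper: float = 10.0,
    ):
        if list(data.region_ids) != list(graph.region_ids):
            raise ValueError("panel regions and graph regions must match in order")
        if not graph.is_connected():
            raise ValueError(
                "the region graph must be connected: islands have no agreed ICAR "
                "convention; split the analysis or connect the graph explicitly"
            )
        # validates tau / upper
        QuantileModelConfig(tau=tau, sd_prior_upper=sd_prior_upper)
        self.data = data
        self.graph = graph
        self.tau = float(tau)
        self.sd_prior_upper = float(sd_prior_upper)

    def fit(self, chains=2, iterations=8000, burn_in=4000, thin=1, seed=None):
        config = QuantileModelConfig(
            tau=self.tau,
            sd_prior_upper=self.sd_prior_upper,
            chains=chains,
            iterations=iterations,
            burn_in=burn_in,
            thin=thin,
            seed=seed,
        )
        root = np.random.SeedSequence(seed)
        stores = [
            _sampler.run_hier_chain(
                self.data.y,
                self.data.e,
                self.data.X,
                self.graph,
                self._error,
                self.tau,
                self.sd_prior_upper,
                iterations,
                burn_in,
                thin,
                child,
            )
            for child in root.spawn(chains)
        ]
        draws = {
            k: np.stack([s[k] for s in stores], axis=0) for k in stores[0]
        }
        samples = PosteriorSamples(
            draws=draws, region_ids=list(self.data.region_ids), times=list(self.data.times)
        )
        return self._results_cls(self, samples, config)

    @property
    def _results_cls(self):
        raise NotImplementedError


class QuantileRiskModel(_BaseRiskModel):
    """Spatiotemporal quantile regression for relative risk (log-Laplace)."""

    _error = "al"

    @classmethod
    def from_files(cls, panel_path, adjacency_path, **kwargs):
        from .data import read_panel
        from .graph import read_adjacency

        return cls(read_panel(panel_path), read_adjacency(adjacency_path), **kwargs)

    @property
    def _results_cls(self):
        return QuantileRiskResults


class MeanRiskModel(_BaseRiskModel):
    """Conventional mean regression comparator (Gaussian log-scale error).

    ``tau`` is kept on the model only so that posterior quantile extraction
    has a default level; it does not enter the likelihood.
    """

    _error = "gaussian"

    @property
    def _results_cls(self):
        return MeanRiskResults


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------
class _BaseResults:
    #: parameters whose scalars enter the convergence check
    _monitored = ("sigma_u", "sigma_v", "sigma_lam", "sigma_theta", "sigma_eps", "z")

    def __init__(self, model, samples: PosteriorSamples, config: QuantileModelConfig):
        self.model = model
        self.samples = samples
        self.config = config
        self._rhat_cache: dict = {}
        self._check_convergence()

    # -- diagnostics ---------------------------------------------------
    def rhat(self, param: str) -> np.ndarray:
        """Gelman potential scale reduction factor per scalar of ``param``."""
        if param not in self._rhat_cache:
            from .evaluate import gelman_rhat

            a = self.samples.get(param)  # (chains, draws, ...)
            shape = a.shape[2:]
            if not shape:
                out = gelman_rhat(a)
            else:
                out = np.empty(shape)
                for idx in np.ndindex(shape):
                    out[idx] = gelman_rhat(a[(slice(None), slice(None)) + idx])
            self._rhat_cache[param] = out
        return self._rhat_cache[param]

    def max_rhat(self) -> float:
        return max(float(np.max(self.rhat(p))) for p in self._monitored)

    @property
    def converged(self) -> bool:
        return self.max_rhat() < RHAT_THRESHOLD

    def _check_convergence(self):
        worst = self.max_rhat()
        if worst >= RHAT_THRESHOLD:
            warnings.warn(
                f"MCMC may not have converged: max R-hat over monitored scalars "
                f"is {worst:.3f} (threshold {RHAT_THRESHOLD}); consider longer "
                f"chains or more burn-in",
                ConvergenceWarning,
                stacklevel=3,
            )

    # -- posterior summaries -------------------------------------------
    @property
    def mu_draws(self) -> np.ndarray:
        """Relative-risk draws, pooled over chains: (draws, n, T)."""
        return np.exp(self.samples.pooled("z"))

    def posterior_mean_risk(self) -> np.ndarray:
        return self.mu_draws.mean(axis=0)

    def exceedence(self, c: float):
        """Monte-Carlo exceedence probability surface P(mu_it >= c)."""
        from .detection import exceedence_mc

        return exceedence_mc(self, c)

    def credible_interval(self, param: str, level: float = 0.95):
        a = self.samples.pooled(param)
        alpha = (1.0 - level) / 2.0
        return np.quantile(a, [alpha, 1.0 - alpha], axis=0)

    def summary(self, params=None) -> pd.DataFrame:
        """Posterior summary table (mean, sd, median, 95% interval, R-hat)."""
        default = ["sigma_u", "sigma_v", "sigma_lam", "sigma_theta", "sigma_eps", "lam"]
        if "beta" in self.samples.draws:
            default.insert(0, "beta")
        params = params or default
        rows = []
        for p in params:
            pooled = self.samples.pooled(p)
            rh = np.atleast_1d(self.rhat(p))
            flat = pooled.reshape(pooled.shape[0], -1)
            shape = pooled.shape[1:]
            labels = (
                [p]
                if not shape
                else [
                    f"{p}[{','.join(map(str, idx))}]" for idx in np.ndindex(shape)
                ]
            )
            for k, label in enumerate(labels):
                col = flat[:, k]
                rows.append(
                    {
                        "parameter": label,
                        "mean": col.mean(),
                        "sd": col.std(ddof=1),
                        "median": np.median(col),
                        "q2.5": np.quantile(col, 0.025),
                        "q97.5": np.quantile(col, 0.975),
                        "rhat": float(rh.ravel()[k] if rh.size > 1 else rh.ravel()[0]),
                    }
                )
        return pd.DataFrame(rows).set_index("parameter")

    def to_csv(self, path, params=None) -> None:
        """Write retained draws as a columnar delimited file."""
        self.samples.to_dataframe(params).to_csv(path, index=False)

    def plot_trace(self, param: str, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        a = self.samples.get(param)
        flat = a.reshape(a.shape[0], a.shape[1], -1)
        for c in range(flat.shape[0]):
            ax.plot(flat[c, :, 0], lw=0.5, label=f"chain {c}")
        ax.set_xlabel("retained draw")
        ax.set_ylabel(param)
        ax.legend()
        return ax


class QuantileRiskResults(_BaseResults):
    """Posterior of the log-Laplace quantile model."""

    def quantile_surface(self, point: str = "mean") -> np.ndarray:
        """``Q_tau(mu_it)`` point estimate: ``exp`` of the posterior point
        estimate of ``eta_it`` (mean by default, median available)."""
        eta = self.samples.pooled("eta")
        if point == "mean":
            est = eta.mean(axis=0)
        elif point == "median":
            est = np.median(eta, axis=0)
        else:
            raise ValueError("point must be 'mean' or 'median'")
        return np.exp(est)


class MeanRiskResults(_BaseResults):
    """Posterior of the mean-regression comparator."""

    def quantile_surface(self, tau: float | None = None) -> np.ndarray:
        """Empirical ``tau``-quantile of the posterior ``mu_it`` draws
        (linear interpolation of order statistics, the 'type 7' rule)."""
        tau = self.model.tau if tau is None else tau
        if not 0.0 < tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")
        return np.quantile(self.mu_draws, tau, axis=0)


# ----------------------------------------------------------------------
# functional wrappers
# ----------------------------------------------------------------------
def fit_quantile_model(
    data: PanelData, graph: RegionGraph, config: QuantileModelConfig
) -> QuantileRiskResults:
    model = QuantileRiskModel(
        data, graph, tau=config.tau, sd_prior_upper=config.sd_prior_upper
    )
    return model.fit(
        chains=config.chains,
        iterations=config.iterations,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=config.seed,
    )


def fit_mean_model(
    data: PanelData, graph: RegionGraph, config: QuantileModelConfig
) -> MeanRiskResults:
    model = MeanRiskModel(
        data, graph, tau=config.tau, sd_prior_upper=config.sd_prior_upper
    )
    return model.fit(
        chains=config.chains,
        iterations=config.iterations,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=config.seed,
    )


def estimate_quantile_surface(results: QuantileRiskResults, point="mean") -> np.ndarray:
    return results.quantile_surface(point=point)


def mean_model_quantiles(results: MeanRiskResults, tau: float) -> np.ndarray:
    return results.quantile_surface(tau=tau)
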