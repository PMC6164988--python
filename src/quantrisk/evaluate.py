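"""Model evaluation: quantile-surface MSE and the Gelman convergence diagnostic.

``compare_models`` reproduces the simulation-study protocol: fit the
quantile model at each requested level ``tau`` and the mean-regression
comparator once per replicate, extract each model's ``tau``-quantile
surface, and aggregate squared error against the known truth.  The MSE
aggregation rule (mean per cell, or summed over cells) is exposed because
published tables of this kind rarely state the scale; mean is the default.

``gelman_rhat`` is the classic two-stage potential scale reduction factor
(between/within chain variances), not the newer rank-normalized split
variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EvaluationReport", "mse_surface", "gelman_rhat", "compare_models"]


def mse_surface(estimate, truth, aggregation: str = "mean") -> float:
    """Squared error between two aligned surfaces, averaged or summed."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError(f"shape mismatch: {estimate.shape} vs {truth.shape}")
    sq = (estimate - truth) ** 2
    if aggregation == "mean":
        return float(sq.mean())
    if aggregation == "sum":
        return float(sq.sum())
    raise ValueError("aggregation must be 'mean' or 'sum'")


def gelman_rhat(chains) -> float:
    """Classic potential scale reduction factor.

    ``chains`` is (m, n) — m >= 2 chains of n >= 2 retained draws.  Returns
    ``sqrt(((n-1)/n * W + B/n) / W)``; the degenerate zero within-chain
    variance case returns 1.
    """
    a = np.asarray(chains, dtype=float)
    if a.ndim != 2:
        raise ValueError("chains must be a 2-D (m, n) array")
    m, n = a.shape
    if m < 2:
        raise ValueError("R-hat needs at least 2 chains; run more chains")
    if n < 2:
        raise ValueError("R-hat needs at least 2 draws per chain")
    means = a.mean(axis=1)
    W = a.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass
class EvaluationReport:
    """MSE comparison of the quantile and mean models over replicates."""

    tau_levels: tuple
    mse_quantile: dict  # tau -> float
    mse_mean: dict  # tau -> float
    per_replicate: pd.DataFrame
    n_replicates: int
    aggregation: str
    failures: list = field(default_factory=list)

    @property
    def mse_ratio(self) -> dict:
        """Mean-model MSE over quantile-model MSE per level (>1 favours the
        quantile model)."""
        return {
            t: (self.mse_mean[t] / self.mse_quantile[t])
            if self.mse_quantile[t] > 0
            else np.inf
            for t in self.tau_levels
        }

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "tau": t,
                "mse_quantile": self.mse_quantile[t],
                "mse_mean": self.mse_mean[t],
                "ratio_mean_over_quantile": self.mse_ratio[t],
            }
            for t in self.tau_levels
        ]
        return pd.DataFrame(rows).set_index("tau")


def compare_models(
    panels,
    truth,
    graph,
    tau_levels=(0.9, 0.5, 0.1),
    config=None,
    aggregation: str = "mean",
    progress: bool = False,
):
    """Fit both models to each replicate and aggregate quantile-surface MSE.

    ``panels`` and the shared ``truth`` come from
    :func:`quantrisk.simulate.simulate_counts`.  The mean model does not
    depend on ``tau``, so it is fitted once per replicate and its quantile
    surfaces are read off the same posterior at every requested level.
    Per-replicate fit failures are recorded, not fatal.  Seeds for the fits
    are derived deterministically from ``config.seed``.
    """
    import warnings

    from .model import (
        ConvergenceWarning,
        MeanRiskModel,
        QuantileModelConfig,
        QuantileRiskModel,
    )

    config = config or QuantileModelConfig()
    root = np.random.SeedSequence(config.seed)
    rows = []
    failures = []
    for rep, panel in enumerate(panels):
        seeds = root.spawn(1)[0].generate_state(len(tau_levels) + 1) % (2**31)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                mean_res = MeanRiskModel(
                    panel, graph, sd_prior_upper=config.sd_prior_upper
                ).fit(
                    chains=config.chains,
                    iterations=config.iterations,
                    burn_in=config.burn_in,
                    thin=config.thin,
                    seed=int(seeds[-1]),
                )
                for k, tau in enumerate(tau_levels):
                    q_res = QuantileRiskModel(
                        panel, graph, tau=tau, sd_prior_upper=config.sd_prior_upper
                    ).fit(
                        chains=config.chains,
                        iterations=config.iterations,
                        burn_in=config.burn_in,
                        thin=config.thin,
                        seed=int(seeds[k]),
                    )
                    truth_surface = truth.q_surfaces[tau]
                    rows.append(
                        {
                            "replicate": rep,
                            "tau": tau,
                            "mse_quantile": mse_surface(
                                q_res.quantile_surface(), truth_surface, aggregation
                            ),
                            "mse_mean": mse_surface(
                                mean_res.quantile_surface(tau), truth_surface, aggregation
                            ),
                        }
                    )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append((rep, repr(exc)))
            continue
        if progress:
            print(f"replicate {rep + 1}/{len(panels)} done")
    per_rep = pd.DataFrame(rows)
    mse_q = {
        t: float(per_rep.loc[per_rep["tau"] == t, "mse_quantile"].mean())
        for t in tau_levels
    }
    mse_m = {
        t: float(per_rep.loc[per_rep["tau"] == t, "mse_mean"].mean())
        for t in tau_levels
    }
    return EvaluationReport(
        tau_levels=tuple(tau_levels),
        mse_quantile=mse_q,
        mse_mean=mse_m,
        per_replicate=per_rep,
        n_replicates=len(panels),
        aggregation=aggregation,
        failures=failures,
    )
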