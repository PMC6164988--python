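"""Adverse-risk (cluster / hot-spot) detection via exceedence probabilities.

Two estimators of ``P(mu_it >= c)`` are provided:

* :func:`exceedence_mc` — the conventional Monte-Carlo estimator: the
  fraction of retained posterior draws of ``mu_it`` at or above the
  threshold ``c`` (inclusive inequality).

* :class:`ExceedenceQuantileModel` — the quantile-level reformulation: fit
  a model in which the ``tau_it``-quantile of the relative risk is pinned
  at ``c`` (``log c = log mu_it + eps`` with ``eps`` asymmetric-Laplace at
  level ``tau_it``), give each ``tau_it`` a flat Beta(1, 1) prior, and read
  the posterior point estimate of ``tau_it`` — which is exactly
  ``P(c <= mu_it)`` under the quantile constraint.  With the shared AL
  scale estimated, the level estimate adapts to the overall spread of the
  data; it tracks the Monte-Carlo estimator in rank order and approaches
  0/1 for units far below/above the threshold relative to that spread.

A surface is classified into adverse-risk flags by comparing against a
probability cut-off (conventionally 0.95, 0.975 or 0.99).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _sampler
from .data import PanelData
from .model import QuantileModelConfig, PosteriorSamples

__all__ = [
    "ExceedenceSurface",
    "exceedence_mc",
    "ExceedenceQuantileModel",
    "ExceedenceQuantileResults",
    "exceedence_quantile_level",
    "classify_adverse",
]


@dataclass
class ExceedenceSurface:
    """Per-(region, time) posterior probability that risk exceeds ``c``."""

    c: float
    prob: np.ndarray  # (n, T) in [0, 1]
    source: str  # "monte_carlo" | "quantile_level"
    region_ids: list
    times: list

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("threshold c must be positive")
        self.prob = np.asarray(self.prob, dtype=float)
        if np.any(self.prob < 0) or np.any(self.prob > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.source not in ("monte_carlo", "quantile_level"):
            raise ValueError(f"unknown source {self.source!r}")

    def to_dataframe(self, prob_threshold: float | None = None) -> pd.DataFrame:
        recs = []
        flags = (
            classify_adverse(self, prob_threshold) if prob_threshold is not None else None
        )
        for i, r in enumerate(self.region_ids):
            for t, tt in enumerate(self.times):
                rec = {
                    "region_id": r,
                    "time": tt,
                    "c": self.c,
                    "probability": self.prob[i, t],
                }
                if flags is not None:
                    rec["flag"] = bool(flags[i, t])
                recs.append(rec)
        return pd.DataFrame.from_records(recs)


def exceedence_mc(results, c: float) -> ExceedenceSurface:
    """Monte-Carlo exceedence: fraction of draws with ``mu_it >= c``.

    ``results`` is any fitted results object exposing ``mu_draws`` (pooled
    ``(G, n, T)`` relative-risk draws) plus region/time labels.
    """
    if not c > 0:
        raise ValueError("threshold c must be positive")
    draws = results.mu_draws
    if draws.shape[0] == 0:
        raise ValueError("no retained draws")
    prob = (draws >= c).mean(axis=0)
    return ExceedenceSurface(
        c=float(c),
        prob=prob,
        source="monte_carlo",
        region_ids=list(results.samples.region_ids),
        times=list(results.samples.times),
    )


class ExceedenceQuantileModel:
    """Threshold-quantile model: estimate the level ``tau_it`` at which the
    quantile of ``mu_it`` equals the threshold ``c``."""

    def __init__(
        self,
        data: PanelData,
        c: float,
        sd_prior_upper: float = 10.0,
        sigma: float | None = None,
    ):
        if not c > 0:
            raise ValueError("threshold c must be positive")
        self.data = data
        self.c = float(c)
        self.sd_prior_upper = float(sd_prior_upper)
        self.sigma = sigma  # optionally fix the AL scale

    def fit(self, chains=2, iterations=6000, burn_in=3000, thin=1, seed=None):
        config = QuantileModelConfig(
            sd_prior_upper=self.sd_prior_upper,
            chains=chains,
            iterations=iterations,
            burn_in=burn_in,
            thin=thin,
            seed=seed,
        )
        root = np.random.SeedSequence(seed)
        stores = [
            _sampler.run_detection_chain(
                self.data.y,
                self.data.e,
                np.log(self.c),
                self.sd_prior_upper,
                iterations,
                burn_in,
                thin,
                child,
                fix_sigma=self.sigma,
            )
            for child in root.spawn(chains)
        ]
        draws = {k: np.stack([s[k] for s in stores], axis=0) for k in stores[0]}
        samples = PosteriorSamples(
            draws=draws,
            region_ids=list(self.data.region_ids),
            times=list(self.data.times),
        )
        return ExceedenceQuantileResults(self, samples, config)


class ExceedenceQuantileResults:
    """Posterior of the threshold-quantile detection model."""

    _monitored = ("sigma_eps", "z")

    def __init__(self, model, samples: PosteriorSamples, config):
        self.model = model
        self.samples = samples
        self.config = config

    @property
    def mu_draws(self) -> np.ndarray:
        return np.exp(self.samples.pooled("z"))

    def tau_surface(self, point: str = "mean") -> np.ndarray:
        """Point estimate of ``tau_it = P(c <= mu_it)`` (posterior mean by
        default; median available)."""
        tau = self.samples.pooled("tau")
        if point == "mean":
            return tau.mean(axis=0)
        if point == "median":
            return np.median(tau, axis=0)
        raise ValueError("point must be 'mean' or 'median'")

    def exceedence(self, point: str = "mean") -> ExceedenceSurface:
        return ExceedenceSurface(
            c=self.model.c,
            prob=self.tau_surface(point=point),
            source="quantile_level",
            region_ids=list(self.samples.region_ids),
            times=list(self.samples.times),
        )

    def rhat(self, param: str) -> np.ndarray:
        from .evaluate import gelman_rhat

        a = self.samples.get(param)
        shape = a.shape[2:]
        if not shape:
            return gelman_rhat(a)
        out = np.empty(shape)
        for idx in np.ndindex(shape):
            out[idx] = gelman_rhat(a[(slice(None), slice(None)) + idx])
        return out


def exceedence_quantile_level(
    data: PanelData,
    c: float,
    config: QuantileModelConfig | None = None,
    sigma: float | None = None,
) -> ExceedenceSurface:
    """Fit the threshold-quantile model and return its exceedence surface."""
    config = config or QuantileModelConfig()
    model = ExceedenceQuantileModel(
        data, c, sd_prior_upper=config.sd_prior_upper, sigma=sigma
    )
    res = model.fit(
        chains=config.chains,
        iterations=config.iterations,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=config.seed,
    )
    return res.exceedence()


def classify_adverse(surface: ExceedenceSurface, prob_threshold: float) -> np.ndarray:
    """Flag units with exceedence probability at or above ``prob_threshold``."""
    if not 0.0 < prob_threshold < 1.0:
        raise ValueError("prob_threshold must lie in (0, 1)")
    return surface.prob >= prob_threshold
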