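"""The quantile-parameterized log-Laplace (LL) distribution.

The LL family is the distribution of ``exp(X)`` where ``X`` follows an
asymmetric Laplace (AL) law.  It is the natural prior for a disease
*relative risk* ``mu > 0`` when one wants to model a chosen quantile of the
risk directly: with location ``mu_tau`` (on the log scale), quantile level
``tau`` and scale ``sigma``, the value ``exp(mu_tau)`` is exactly the
``tau``-quantile of ``mu``.  Maximizing the LL log-likelihood in ``mu_tau``
is equivalent to minimizing the summed check (quantile) loss of
``log(mu) - mu_tau``, which is what ties the family to quantile regression.

Two parameterizations are supported and mapped bijectively:

* ``LogLaplaceParams(mu_tau, tau, sigma)`` — the quantile parameterization.
* ``ThreeParamLL(delta, a, b)`` — the classical three-parameter form with
  density ``(1/delta) * ab/(a+b) * (mu/delta)**(b-1)`` for ``0 < mu < delta``
  and ``(1/delta) * ab/(a+b) * (delta/mu)**(a+1)`` for ``mu >= delta``.

The map is ``delta = exp(mu_tau)``, ``a = tau/sigma``, ``b = (1-tau)/sigma``.
Substituting it into the three-parameter density and collecting terms gives
the quantile-form density

    f(mu) = (1/mu) * tau*(1-tau)/sigma * exp(-(1-tau)*|log mu - mu_tau|/sigma)
                                                        for log mu <  mu_tau
    f(mu) = (1/mu) * tau*(1-tau)/sigma * exp(-tau*|log mu - mu_tau|/sigma)
                                                        for log mu >= mu_tau

(the normalizing factor ``tau*(1-tau)/sigma`` follows from
``ab/(a+b) = (tau(1-tau)/sigma^2) / (1/sigma)``).  All density work is done
in log space; the linear-scale pdf is a thin wrapper.

Parameter validation is strict: invalid ``tau``/``sigma``/``mu`` raise,
they are never clamped, because silently repaired parameters corrupt the
quantile semantics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LogLaplaceParams",
    "ThreeParamLL",
    "ll_logpdf",
    "ll_pdf",
    "ll_pdf_three_param",
    "ll_cdf",
    "ll_quantile",
    "ll_sample",
    "check_loss",
]


@dataclass(frozen=True)
class LogLaplaceParams:
    """Quantile parameterization: location ``mu_tau`` (log scale), level
    ``tau`` in (0,1), scale ``sigma`` > 0 (log scale)."""

    mu_tau: float
    tau: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError(f"tau must lie in (0, 1), got {self.tau}")
        if not self.sigma > 0.0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not np.isfinite(self.mu_tau):
            raise ValueError(f"mu_tau must be finite, got {self.mu_tau}")

    def to_three_param(self) -> "ThreeParamLL":
        return ThreeParamLL(
            delta=float(np.exp(self.mu_tau)),
            a=self.tau / self.sigma,
            b=(1.0 - self.tau) / self.sigma,
        )


@dataclass(frozen=True)
class ThreeParamLL:
    """Classical three-parameter form: scale ``delta`` on the risk scale,
    upper-tail shape ``a``, lower-tail shape ``b`` (all > 0)."""

    delta: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("delta", "a", "b"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"{name} must be positive, got {v}")

    def to_quantile_param(self) -> LogLaplaceParams:
        # invert a = tau/sigma, b = (1-tau)/sigma: sigma = 1/(a+b)
        sigma = 1.0 / (self.a + self.b)
        return LogLaplaceParams(
            mu_tau=float(np.log(self.delta)), tau=self.a * sigma, sigma=sigma
        )


def _check_mu(mu) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0.0) or not np.all(np.isfinite(mu)):
        raise ValueError("mu must be strictly positive and finite")
    return mu


def ll_logpdf(mu, params: LogLaplaceParams):
    """Log of the LL density, stable at extreme ``mu``."""
    mu = _check_mu(mu)
    r = np.log(mu) - params.mu_tau
    tau, sigma = params.tau, params.sigma
    slope = np.where(r < 0.0, 1.0 - tau, tau)
    out = np.log(tau * (1.0 - tau) / sigma) - np.log(mu) - slope * np.abs(r) / sigma
    return out if out.ndim else float(out)


def ll_pdf(mu, params: LogLaplaceParams):
    """LL density in the quantile parameterization."""
    out = np.exp(ll_logpdf(mu, params))
    return out if np.ndim(out) else float(out)


def ll_pdf_three_param(mu, params: ThreeParamLL):
    """LL density in the three-parameter (delta, a, b) form."""
    mu = _check_mu(mu)
    delta, a, b = params.delta, params.a, params.b
    norm = a * b / (a + b) / delta
    with np.errstate(over="ignore"):
        lower = (mu / delta) ** (b - 1.0)
        upper = (delta / mu) ** (a + 1.0)
    out = norm * np.where(mu < delta, lower, upper)
    return out if out.ndim else float(out)


def ll_cdf(mu, params: LogLaplaceParams):
    """LL distribution function, closed form.

    ``F(exp(mu_tau)) = tau`` exactly — the defining quantile constraint.
    """
    mu = _check_mu(mu)
    r = np.log(mu) - params.mu_tau
    tau, sigma = params.tau, params.sigma
    lower = tau * np.exp((1.0 - tau) * np.minimum(r, 0.0) / sigma)
    upper = 1.0 - (1.0 - tau) * np.exp(-tau * np.maximum(r, 0.0) / sigma)
    # r == 0 goes to the lower branch so F(exp(mu_tau)) = tau exactly
    out = np.where(r <= 0.0, lower, upper)
    return out if out.ndim else float(out)


def ll_quantile(p, params: LogLaplaceParams):
    """Inverse of :func:`ll_cdf` on (0, 1); ``ll_quantile(tau) = exp(mu_tau)``."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("p must lie strictly inside (0, 1)")
    tau, sigma = params.tau, params.sigma
    with np.errstate(divide="ignore"):
        low = sigma * np.log(p / tau) / (1.0 - tau)
        high = -sigma * np.log((1.0 - p) / (1.0 - tau)) / tau
    logq = params.mu_tau + np.where(p < tau, low, high)
    out = np.exp(logq)
    return out if out.ndim else float(out)


def ll_sample(n: int, params: LogLaplaceParams, seed) -> np.ndarray:
    """``n`` i.i.d. LL draws by inverse-CDF; reproducible under a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    # uniform draws are in [0,1); nudge exact zeros off the boundary
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    return np.asarray(ll_quantile(u, params))


def check_loss(residual, tau: float):
    """Check (quantile) loss ``rho_tau(r) = r * (tau - 1{r < 0})``.

    Minimizing the summed check loss of ``log(mu) - mu_tau`` over ``mu_tau``
    is equivalent to maximizing the summed LL log-likelihood.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    r = np.asarray(residual, dtype=float)
    out = r * (tau - (r < 0.0))
    return out if out.ndim else float(out)
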