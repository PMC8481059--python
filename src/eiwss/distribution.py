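"""Exponentiated inverted Weibull (EIW) distribution primitives.

The EIW law on ``x > 0`` has distribution function ``F(x) = exp(-theta * x**-beta)``
with exponentiation parameter ``theta > 0`` (scale-type) and shape ``beta > 0``.
It generalises both the inverted Weibull (``theta = 1``) and the exponentiated
inverted exponential (``beta = 1``) distributions, and is a common lifetime
model for breaking-strength data.

For two independent EIW variables sharing the shape ``beta`` -- strength
``X ~ EIW(theta1, beta)`` and stress ``Y ~ EIW(theta2, beta)`` -- the
stress-strength reliability has the closed form

    R = P(Y < X) = theta1 / (theta1 + theta2),

which is what makes the common-shape model attractive: every estimator of the
scale pair immediately yields an estimator of R.

Everything here is exact and vectorised; estimation lives in
:mod:`eiwss.estimators`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EIWParams",
    "StressStrengthParams",
    "eiw_pdf",
    "eiw_logpdf",
    "eiw_cdf",
    "eiw_logcdf",
    "eiw_sf",
    "eiw_quantile",
    "eiw_rvs",
    "eiw_loglik",
    "reliability",
]


@dataclass(frozen=True)
class EIWParams:
    """Parameters of one EIW law.

    Parameters
    ----------
    theta : float
        Exponentiation ("scale-type") parameter, > 0.
    beta : float
        Shape parameter, > 0.
    """

    theta: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValueError(f"theta must be a positive finite real, got {self.theta!r}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be a positive finite real, got {self.beta!r}")


@dataclass(frozen=True)
class StressStrengthParams:
    """Joint parameters of the common-shape stress-strength model.

    ``theta1`` governs the strength sample X, ``theta2`` the stress sample Y;
    ``beta`` is the shape shared by both laws.
    """

    theta1: float
    theta2: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("theta1", "theta2", "beta"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite real, got {v!r}")

    @property
    def strength(self) -> EIWParams:
        return EIWParams(self.theta1, self.beta)

    @property
    def stress(self) -> EIWParams:
        return EIWParams(self.theta2, self.beta)


def _check_positive(x: np.ndarray, what: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError(f"{what} must be strictly positive and finite (support is x > 0)")
    return x


def eiw_logcdf(x, p: EIWParams):
    """log F(x) = -theta * x**-beta, evaluated in log space to avoid underflow."""
    x = _check_positive(x)
    return -p.theta * np.exp(-p.beta * np.log(x))


def eiw_cdf(x, p: EIWParams):
    """Distribution function F(x) = exp(-theta x**-beta) for x > 0."""
    return np.exp(eiw_logcdf(x, p))


def eiw_sf(x, p: EIWParams):
    """Survival function 1 - F(x), accurate in the upper tail."""
    return -np.expm1(eiw_logcdf(x, p))


def eiw_logpdf(x, p: EIWParams):
    x = _check_positive(x)
    lx = np.log(x)
    return np.log(p.theta) + np.log(p.beta) - (p.beta + 1.0) * lx - p.theta * np.exp(-p.beta * lx)


def eiw_pdf(x, p: EIWParams):
    """Density f(x) = theta beta x**-(beta+1) exp(-theta x**-beta) for x > 0."""
    return np.exp(eiw_logpdf(x, p))


def eiw_quantile(q, p: EIWParams):
    """Quantile function, the exact inverse of :func:`eiw_cdf`.

    ``x = (-ln(q) / theta) ** (-1/beta)`` for ``0 < q < 1``.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("q must lie strictly inside (0, 1)")
    return (-np.log(q) / p.theta) ** (-1.0 / p.beta)


def eiw_rvs(n: int, p: EIWParams, seed=None) -> np.ndarray:
    """Draw ``n`` variates by inverse-transform sampling.

    ``seed`` may be an int, a :class:`numpy.random.Generator`, or a
    :class:`numpy.random.SeedSequence`; a given seed always reproduces the
    same vector.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    # uniform(0,1) excludes 1.0 but may return 0.0; shift into the open interval
    u = rng.uniform(size=int(n))
    u = np.where(u == 0.0, np.nextafter(0.0, 1.0), u)
    return eiw_quantile(u, p)


def eiw_loglik(x, p: EIWParams) -> float:
    """Sample log-likelihood under one EIW law."""
    return float(np.sum(eiw_logpdf(x, p)))


def reliability(p: StressStrengthParams) -> float:
    """Stress-strength reliability R = P(Y < X) = theta1 / (theta1 + theta2)."""
    return p.theta1 / (p.theta1 + p.theta2)
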