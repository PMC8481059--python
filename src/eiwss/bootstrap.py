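"""Parametric bootstrap confidence intervals for the reliability R = P(Y < X).

The scheme resamples from the *fitted* EIW laws: the chosen estimator is fit
to the original data, each replicate draws n strengths from
EIW(theta1_hat, beta_hat) and k stresses from EIW(theta2_hat, beta_hat),
refits with the same estimator, and records R_hat. Two interval types are
built from the sorted replicate vector:

* percentile (Boot-P): order statistics at ranks ceil(B*gamma/2) and
  ceil(B*(1-gamma/2));
* bias-corrected percentile (Boot-BCP): the ranks are shifted through the
  normal CDF by twice the bias constant z0 = Phi^{-1}(fraction of replicates
  below the original estimate).

No acceleration constant is used (this is BC, not BCa), and there is no
nonparametric mode. Per-replicate seeds are spawned from the master seed so
runs are reproducible and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .distribution import EIWParams, eiw_rvs
from .estimators import ConvergenceError, TwoSampleData, fit_joint

__all__ = [
    "BootstrapResult",
    "bootstrap_replicates",
    "boot_p_interval",
    "boot_bcp_interval",
    "bootstrap_ci",
    "bootstrap_se",
]


@dataclass(frozen=True)
class BootstrapResult:
    """One interval computed from a replicate cloud."""

    r_hat: float
    replicates: np.ndarray  # sorted ascending, length B
    B: int
    gamma: float
    method: str  # "boot_p" or "boot_bcp"
    lower: float
    upper: float
    z0: float | None = None  # bias-correction constant (boot_bcp only)

    @property
    def length(self) -> float:
        return self.upper - self.lower


def bootstrap_replicates(data: TwoSampleData, method: str, B: int, seed,
                         max_redraws: int = 10) -> tuple[np.ndarray, float]:
    """Draw B parametric-bootstrap replicates of R_hat.

    Returns ``(replicates, r_hat)`` where ``r_hat`` is the original-data
    estimate. Replicates whose refit fails are redrawn up to ``max_redraws``
    times each before aborting.
    """
    if B < 50:
        raise ValueError(f"B must be >= 50, got {B}")
    base_fit = fit_joint(data, method)
    px = EIWParams(base_fit.params.theta1, base_fit.params.beta)
    py = EIWParams(base_fit.params.theta2, base_fit.params.beta)
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    # spawn a generous pool so redraws have fresh, reproducible streams
    streams = master.spawn(B * (max_redraws + 1))
    reps = np.empty(B)
    for b in range(B):
        last_err = None
        for attempt in range(max_redraws):
            rng = np.random.default_rng(streams[b * (max_redraws + 1) + attempt])
            xb = eiw_rvs(data.n, px, rng)
            yb = eiw_rvs(data.k, py, rng)
            try:
                reps[b] = fit_joint(TwoSampleData(xb, yb), method).r_hat
                break
            except ConvergenceError as err:  # pragma: no cover - rare
                last_err = err
        else:  # pragma: no cover
            raise ConvergenceError(
                f"bootstrap replicate {b} failed {max_redraws} redraws",
                {"method": method, "last_error": str(last_err)},
            )
    return np.sort(reps), base_fit.r_hat


def _rank(B: int, p: float) -> int:
    """ceil(B*p) as a 1-based order-statistic rank, clamped to [1, B]."""
    return min(max(int(math.ceil(B * p)), 1), B)


def boot_p_interval(replicates: np.ndarray, gamma: float) -> tuple[float, float]:
    """Percentile interval at confidence level 1 - gamma."""
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    reps = np.sort(np.asarray(replicates, dtype=float))
    B = reps.size
    return float(reps[_rank(B, gamma / 2) - 1]), float(reps[_rank(B, 1 - gamma / 2) - 1])


def boot_bcp_interval(replicates: np.ndarray, r_hat: float,
                      gamma: float) -> tuple[float, float, float]:
    """Bias-corrected percentile interval; returns (lower, upper, z0).

    Replicates tied with ``r_hat`` count as below with weight 1/2; the
    below-fraction is clamped to [1/(2B), 1 - 1/(2B)] so z0 stays finite.
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    reps = np.sort(np.asarray(replicates, dtype=float))
    B = reps.size
    frac = (np.sum(reps < r_hat) + 0.5 * np.sum(reps == r_hat)) / B
    frac = min(max(frac, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = float(norm.ppf(frac))
    d1 = float(norm.cdf(2 * z0 + norm.ppf(gamma / 2)))
    d2 = float(norm.cdf(2 * z0 + norm.ppf(1 - gamma / 2)))
    return float(reps[_rank(B, d1) - 1]), float(reps[_rank(B, d2) - 1]), z0


def bootstrap_ci(data: TwoSampleData, method: str = "MLE", B: int = 1000,
                 gammas=(0.10, 0.05, 0.01), seed=0) -> dict:
    """Convenience wrapper: replicates once, both interval kinds per level.

    Returns ``{1-gamma: {"boot_p": BootstrapResult, "boot_bcp": BootstrapResult}}``.
    """
    reps, r_hat = bootstrap_replicates(data, method, B, seed)
    out = {}
    for g in gammas:
        lo, hi = boot_p_interval(reps, g)
        blo, bhi, z0 = boot_bcp_interval(reps, r_hat, g)
        out[round(1 - g, 10)] = {
            "boot_p": BootstrapResult(r_hat, reps, B, g, "boot_p", lo, hi),
            "boot_bcp": BootstrapResult(r_hat, reps, B, g, "boot_bcp", blo, bhi, z0),
        }
    return out


def bootstrap_se(data: TwoSampleData, method: str, B: int = 500, seed=0) -> dict:
    """Bootstrap standard errors of (theta1, theta2, beta, R) for any estimator.

    This is a parametric-bootstrap stand-in offered for the non-MLE methods,
    whose sampling variances have no closed form here; it is *not* an
    observed-information SE.
    """
    base = fit_joint(data, method)
    px = EIWParams(base.params.theta1, base.params.beta)
    py = EIWParams(base.params.theta2, base.params.beta)
    streams = np.random.SeedSequence(seed).spawn(B)
    vals = np.empty((B, 4))
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        fit = fit_joint(TwoSampleData(eiw_rvs(data.n, px, rng),
                                      eiw_rvs(data.k, py, rng)), method)
        vals[b] = (fit.params.theta1, fit.params.theta2, fit.params.beta, fit.r_hat)
    sd = vals.std(axis=0, ddof=1)
    return {"theta1": sd[0], "theta2": sd[1], "beta": sd[2], "R": sd[3]}
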