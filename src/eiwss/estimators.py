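"""Point estimation of (theta1, theta2, beta) and R for the common-shape EIW model.

Eight estimators are provided, all operating on a strength sample
``x_1..x_n ~ EIW(theta1, beta)`` and a stress sample ``y_1..y_k ~ EIW(theta2, beta)``:

``MLE``
    Maximum likelihood. The scale parameters profile out analytically,
    ``theta_1(beta) = n / sum(x_i**-beta)`` (and analogously for theta_2), so the
    fit reduces to one root-find of the profile score in beta.
``MPSE``
    Maximum product of spacings (Cheng-Amin): maximises the mean log CDF
    increment between consecutive order statistics, with boundary spacings
    ``F(x_(1))`` and ``1 - F(x_(n))`` included.
``MSADE`` / ``MSALDE``
    Minimum spacing absolute distance / absolute-log distance: drive the
    spacings toward the uniform target ``1/(n+1)`` in L1, on the natural or
    the log scale. Both objectives are nonsmooth.
``LSE`` / ``WLSE``
    (Weighted) least squares of the fitted CDF against the plotting positions
    ``i/(n+1)``, with the classical variance-inverse weights
    ``(n+1)^2 (n+2) / (i (n-i+1))`` in the weighted version.
``CME``
    Cramer-von Mises minimum distance with positions ``(2i-1)/(2n)``.
``ADE``
    Anderson-Darling minimum distance, sum of the two samples' A^2 statistics.

Every objective splits into an x-term depending on ``(theta1, beta)`` plus a
y-term depending on ``(theta2, beta)``. The minimum-distance fits exploit this:
a coarse profile search over beta (with two independent 1-D scale
minimisations per grid point) locates the global basin, and a Nelder-Mead
polish plus jittered restarts refines it. This is considerably more reliable
than a single 3-D descent on the multimodal WLSE/CME surfaces.

All R estimates are ``theta1_hat / (theta1_hat + theta2_hat)`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar

from .distribution import EIWParams, StressStrengthParams, reliability

__all__ = [
    "METHODS",
    "TwoSampleData",
    "JointFit",
    "SingleFit",
    "ConvergenceError",
    "fit_joint",
    "fit_mle_joint",
    "fit_mle_single",
    "fit_mpse_joint",
    "fit_msade_joint",
    "fit_msalde_joint",
    "fit_lse_joint",
    "fit_wlse_joint",
    "fit_cme_joint",
    "fit_ade_joint",
    "mle_standard_errors",
    "uniform_spacings",
    "wls_weights",
]

#: canonical estimator tags, in the order the tables print them
METHODS = ("MLE", "MPSE", "MSADE", "MSALDE", "LSE", "WLSE", "CME", "ADE")

# floor for CDF spacings inside log/ratio objectives (ties would give -inf)
_SPACING_FLOOR = 1e-10
# clamp for CDF values inside Anderson-Darling logs
_CDF_CLAMP = 1e-12
# fixed sub-seed for the multiplicative jitter of optimizer restarts
_JITTER_SEED = 20210921


class ConvergenceError(RuntimeError):
    """Raised when an estimator fails to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class TwoSampleData:
    """Paired strength/stress samples, validated and stored as float arrays."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        for name in ("x", "y"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1 or v.size < 2:
                raise ValueError(f"{name} must be a 1-D sample with at least 2 observations")
            if np.any(~np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"{name} must contain strictly positive finite values")
            object.__setattr__(self, name, v)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def k(self) -> int:
        return self.y.size

    def swapped(self) -> "TwoSampleData":
        """Exchange the strength and stress roles."""
        return TwoSampleData(self.y.copy(), self.x.copy())


@dataclass(frozen=True)
class JointFit:
    """Result of one joint two-sample fit."""

    params: StressStrengthParams
    r_hat: float
    method: str
    objective_value: float
    converged: bool
    n_restarts_used: int = 0
    se: tuple | None = None  # (se_theta1, se_theta2, se_beta) when available

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "theta1": self.params.theta1,
            "theta2": self.params.theta2,
            "beta": self.params.beta,
            "R": self.r_hat,
            "objective": self.objective_value,
            "converged": self.converged,
            "restarts": self.n_restarts_used,
        }
        if self.se is not None:
            d["se"] = {"theta1": self.se[0], "theta2": self.se[1], "beta": self.se[2]}
        return d


@dataclass(frozen=True)
class SingleFit:
    """Two-parameter single-sample MLE with observed-information SEs."""

    params: EIWParams
    se: tuple  # (se_theta, se_beta)
    loglik: float


# ---------------------------------------------------------------------------
# order-statistic helpers


def uniform_spacings(sorted_sample: np.ndarray, theta: float, beta: float,
                     floor: float | None = None) -> np.ndarray:
    """CDF increments between consecutive order statistics.

    Returns the n+1 spacings ``F(x_(i)) - F(x_(i-1))`` with the conventions
    ``F(x_(0)) = 0`` and ``F(x_(n+1)) = 1``; they sum to 1 by construction.
    ``floor`` (if given) clips each spacing from below, for use inside
    logarithmic objectives where a tie would produce ``-inf``.
    """
    F = np.empty(sorted_sample.size + 2)
    F[0] = 0.0
    F[1:-1] = np.exp(-theta * sorted_sample ** -beta)
    F[-1] = 1.0
    d = np.diff(F)
    if floor is not None:
        d = np.clip(d, floor, None)
    return d


def wls_weights(n: int) -> np.ndarray:
    """Classical WLS weights ``(n+1)^2 (n+2) / (i (n-i+1))``, i = 1..n."""
    i = np.arange(1, n + 1, dtype=float)
    return (n + 1) ** 2 * (n + 2) / (i * (n - i + 1.0))


# ---------------------------------------------------------------------------
# maximum likelihood


def _softmax_weighted_mean(logs: np.ndarray, beta: float) -> float:
    """Mean of log x_i weighted by x_i**-beta, computed without underflow."""
    z = -beta * logs
    z = z - z.max()
    w = np.exp(z)
    return float((w * logs).sum() / w.sum())


def _profile_score(beta: float, lx: np.ndarray, ly: np.ndarray | None) -> float:
    """Derivative of the profile log-likelihood in beta (zero at the MLE)."""
    n = lx.size
    s = n / beta - lx.sum() + n * _softmax_weighted_mean(lx, beta)
    if ly is not None:
        k = ly.size
        s += k / beta - ly.sum() + k * _softmax_weighted_mean(ly, beta)
    return s


def _theta_of_beta(sample: np.ndarray, beta: float) -> float:
    """Profile scale estimate theta(beta) = n / sum(x**-beta), stable for large beta."""
    lx = np.log(sample)
    z = -beta * lx
    zmax = z.max()
    return sample.size * math.exp(-zmax - math.log(np.exp(z - zmax).sum()))


def _solve_profile_beta(lx: np.ndarray, ly: np.ndarray | None,
                        lo: float = 1e-3, hi: float = 1e3) -> float:
    """Bracket and solve the profile score, expanding geometrically if needed."""
    f = lambda b: _profile_score(b, lx, ly)
    a, b = lo, hi
    fa, fb = f(a), f(b)
    for _ in range(60):
        if np.isfinite(fa) and np.isfinite(fb) and fa * fb < 0:
            return brentq(f, a, b, xtol=1e-10, rtol=8.9e-16)
        a, b = a / 2.0, b * 2.0
        fa, fb = f(a), f(b)
    raise ConvergenceError(
        "could not bracket a root of the profile score",
        {"interval": (a, b), "score_lo": fa, "score_hi": fb},
    )


def fit_mle_joint(data: TwoSampleData, compute_se: bool = False) -> JointFit:
    """Joint common-shape MLE via the 1-D profile likelihood in beta."""
    lx, ly = np.log(data.x), np.log(data.y)
    beta = _solve_profile_beta(lx, ly)
    theta1 = _theta_of_beta(data.x, beta)
    theta2 = _theta_of_beta(data.y, beta)
    params = StressStrengthParams(theta1, theta2, beta)
    fit = JointFit(
        params=params,
        r_hat=reliability(params),
        method="MLE",
        objective_value=_joint_loglik(data, params),
        converged=True,
    )
    if compute_se:
        se = mle_standard_errors(data, fit)
        fit = JointFit(**{**fit.__dict__, "se": se})
    return fit


def _joint_loglik(data: TwoSampleData, p: StressStrengthParams) -> float:
    lx, ly = np.log(data.x), np.log(data.y)
    n, k = data.n, data.k
    return float(
        (n + k) * math.log(p.beta)
        + n * math.log(p.theta1)
        + k * math.log(p.theta2)
        - (p.beta + 1.0) * (lx.sum() + ly.sum())
        - p.theta1 * np.exp(-p.beta * lx).sum()
        - p.theta2 * np.exp(-p.beta * ly).sum()
    )


def fit_mle_single(sample) -> SingleFit:
    """Two-parameter MLE of one EIW sample, with observed-information SEs."""
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 1 or sample.size < 2:
        raise ValueError("sample must be 1-D with at least 2 observations")
    if np.any(~np.isfinite(sample)) or np.any(sample <= 0):
        raise ValueError("sample values must be strictly positive and finite")
    lx = np.log(sample)
    beta = _solve_profile_beta(lx, None)
    theta = _theta_of_beta(sample, beta)

    def nll(p):
        th, b = p
        return -(
            sample.size * (math.log(th) + math.log(b))
            - (b + 1.0) * lx.sum()
            - th * np.exp(-b * lx).sum()
        )

    H = _numerical_hessian(nll, np.array([theta, beta]))
    se = _se_from_information(H)
    return SingleFit(
        params=EIWParams(theta, beta),
        se=(se[0], se[1]),
        loglik=-nll((theta, beta)),
    )


def _numerical_hessian(f, p0: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with steps scaled to parameter magnitude."""
    m = p0.size
    h = np.maximum(np.abs(p0), 1e-8) * (np.finfo(float).eps ** 0.25)
    H = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(p0 + ei + ej) - f(p0 + ei - ej) - f(p0 - ei + ej) + f(p0 - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _se_from_information(info: np.ndarray) -> np.ndarray:
    """SEs from the inverse observed information; NaN if not positive definite."""
    try:
        eig = np.linalg.eigvalsh(info)
        if eig.min() <= 0:
            raise np.linalg.LinAlgError("observed information not positive definite")
        cov = np.linalg.inv(info)
        return np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("observed information matrix is not positive definite; "
                      "standard errors undefined", stacklevel=2)
        return np.full(info.shape[0], np.nan)


def mle_standard_errors(data: TwoSampleData, fit: JointFit) -> tuple:
    """SEs of (theta1, theta2, beta) from the inverse observed information."""
    if fit.method != "MLE":
        raise ValueError("observed-information SEs are defined for the MLE fit only")
    p0 = np.array([fit.params.theta1, fit.params.theta2, fit.params.beta])

    def nll(p):
        return -_joint_loglik(data, StressStrengthParams(*p))

    se = _se_from_information(_numerical_hessian(nll, p0))
    return tuple(se)


# ---------------------------------------------------------------------------
# minimum-distance objectives (per-sample terms; joint = x-term + y-term)


def _sample_term(method: str, sorted_sample: np.ndarray, cme_positions: str = "standard",
                 wlse_unit: bool = False):
    """Return f(theta, beta) -> objective contribution of one sample."""
    s = sorted_sample
    n = s.size
    i = np.arange(1, n + 1, dtype=float)
    target = 1.0 / (n + 1)

    if method == "MPSE":
        # negated mean log spacing, so that all methods minimise
        def term(th, b):
            return -np.log(uniform_spacings(s, th, b, floor=_SPACING_FLOOR)).sum() / (n + 1)
    elif method == "MSADE":
        def term(th, b):
            return np.abs(uniform_spacings(s, th, b) - target).sum()
    elif method == "MSALDE":
        log_target = math.log(target)
        def term(th, b):
            return np.abs(np.log(uniform_spacings(s, th, b, floor=_SPACING_FLOOR))
                          - log_target).sum()
    elif method in ("LSE", "WLSE"):
        pp = i / (n + 1)
        w = wls_weights(n) if (method == "WLSE" and not wlse_unit) else np.ones(n)
        def term(th, b):
            return (w * (np.exp(-th * s ** -b) - pp) ** 2).sum()
    elif method == "CME":
        if cme_positions == "standard":
            pp = (2 * i - 1) / (2 * n)
        elif cme_positions == "as_printed":
            pp = (2 * (n - i) + 1) / (2 * n)
        else:
            raise ValueError(f"unknown cme_positions {cme_positions!r}")
        def term(th, b):
            return 1.0 / (12 * n) + ((np.exp(-th * s ** -b) - pp) ** 2).sum()
    elif method == "ADE":
        coef = 2 * i - 1
        def term(th, b):
            F = np.clip(np.exp(-th * s ** -b), _CDF_CLAMP, 1.0 - _CDF_CLAMP)
            return -n - (coef * (np.log(F) + np.log(1.0 - F[::-1]))).sum() / n
    else:
        raise ValueError(f"unknown method {method!r}")
    return term


def _minimize_theta(term, sample: np.ndarray, beta: float) -> tuple[float, float]:
    """1-D minimisation of one sample term over log theta at fixed beta."""
    center = math.log(_theta_of_beta(sample, beta))
    res = minimize_scalar(
        lambda lt: term(math.exp(lt), beta),
        bounds=(center - 9.0, center + 9.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return math.exp(res.x), res.fun


def _fit_min_distance(data: TwoSampleData, method: str, *,
                      cme_positions: str = "standard",
                      n_beta_grid: int = 25,
                      n_restarts: int = 4,
                      wlse_unit: bool = False) -> JointFit:
    xs, ys = np.sort(data.x), np.sort(data.y)
    term_x = _sample_term(method, xs, cme_positions, wlse_unit)
    term_y = _sample_term(method, ys, cme_positions, wlse_unit)

    def objective(logp):
        th1, th2, b = np.exp(logp)
        return term_x(th1, b) + term_y(th2, b)

    # stage 1: profile search over a geometric beta grid around the MLE shape
    beta0 = _solve_profile_beta(np.log(data.x), np.log(data.y))
    best = None
    for b in beta0 * np.logspace(-0.8, 0.8, n_beta_grid):
        th1, fx = _minimize_theta(term_x, xs, b)
        th2, fy = _minimize_theta(term_y, ys, b)
        if best is None or fx + fy < best[0]:
            best = (fx + fy, np.log([th1, th2, b]))

    # stage 2: Nelder-Mead polish + jittered restarts (fixed sub-seed)
    rng = np.random.default_rng(_JITTER_SEED)
    starts = [best[1]]
    starts += [best[1] + rng.normal(0.0, 0.25, size=3) for _ in range(n_restarts)]
    result, n_used, any_ok = None, 0, False
    for idx, start in enumerate(starts):
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-11})
        any_ok = any_ok or res.success
        if result is None or res.fun < result.fun:
            result, n_used = res, idx
    if result is None or not np.all(np.isfinite(result.x)):
        raise ConvergenceError(f"{method} optimisation failed",
                               {"method": method, "starts": len(starts)})
    th1, th2, b = np.exp(result.x)
    params = StressStrengthParams(th1, th2, b)
    return JointFit(
        params=params,
        r_hat=reliability(params),
        method=method,
        objective_value=float(result.fun),
        converged=bool(any_ok),
        n_restarts_used=n_used,
    )


def fit_mpse_joint(data: TwoSampleData, **kw) -> JointFit:
    """Maximum product of spacings fit (objective reported as negated mean log spacing)."""
    return _fit_min_distance(data, "MPSE", **kw)


def fit_msade_joint(data: TwoSampleData, **kw) -> JointFit:
    """Minimum spacing absolute distance fit."""
    return _fit_min_distance(data, "MSADE", **kw)


def fit_msalde_joint(data: TwoSampleData, **kw) -> JointFit:
    """Minimum spacing absolute-log distance fit."""
    return _fit_min_distance(data, "MSALDE", **kw)


def fit_lse_joint(data: TwoSampleData, **kw) -> JointFit:
    """Ordinary least squares fit of the CDF against i/(n+1) plotting positions."""
    return _fit_min_distance(data, "LSE", **kw)


def fit_wlse_joint(data: TwoSampleData, unit_weights: bool = False, **kw) -> JointFit:
    """Weighted least squares fit with variance-inverse plotting-position weights.

    ``unit_weights=True`` replaces every weight by 1, reducing the objective
    to the ordinary least-squares one (useful as a consistency check).
    """
    return _fit_min_distance(data, "WLSE", wlse_unit=unit_weights, **kw)


def fit_cme_joint(data: TwoSampleData, cme_positions: str = "standard", **kw) -> JointFit:
    """Cramer-von Mises minimum distance fit.

    ``cme_positions='standard'`` uses (2i-1)/(2n); ``'as_printed'`` uses the
    reversed pairing (2(n-i)+1)/(2n), kept only for documentation -- it pairs
    the smallest order statistic with the largest probability and drives the
    fit to a degenerate point.
    """
    return _fit_min_distance(data, "CME", cme_positions=cme_positions, **kw)


def fit_ade_joint(data: TwoSampleData, **kw) -> JointFit:
    """Anderson-Darling minimum distance fit (sum of both samples' A^2)."""
    return _fit_min_distance(data, "ADE", **kw)


_FITTERS = {
    "MLE": fit_mle_joint,
    "MPSE": fit_mpse_joint,
    "MSADE": fit_msade_joint,
    "MSALDE": fit_msalde_joint,
    "LSE": fit_lse_joint,
    "WLSE": fit_wlse_joint,
    "CME": fit_cme_joint,
    "ADE": fit_ade_joint,
}


def fit_joint(data: TwoSampleData, method: str, **kw) -> JointFit:
    """Dispatch a joint fit by estimator tag (see :data:`METHODS`)."""
    try:
        fitter = _FITTERS[method.upper()]
    except KeyError:
        raise ValueError(f"unknown estimator {method!r}; choose from {METHODS}") from None
    return fitter(data, **kw)
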