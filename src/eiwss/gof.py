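"""Goodness-of-fit support: one-sample Kolmogorov-Smirnov test and P-P/CDF series.

The KS statistic is the sup-distance between the empirical CDF and the fitted
EIW CDF over the order statistics,

    D = max_i max( i/n - F(x_(i)),  F(x_(i)) - (i-1)/n ).

The default p-value uses the asymptotic Kolmogorov distribution evaluated at
sqrt(n) * D, ignoring the estimated-parameter correction (the conventional
plug-in report for fitted lifetime models); an exact finite-n p-value is
available with ``mode="exact"``. Plotting is left to the caller: this module
only exposes the (empirical, fitted) probability pairs and CDF overlay series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import kolmogorov
from scipy.stats import kstwo

from .distribution import EIWParams, eiw_cdf

__all__ = ["GofReport", "ks_test", "pp_series", "cdf_series"]


@dataclass(frozen=True)
class GofReport:
    ks_stat: float
    p_value: float
    n: int
    fitted: EIWParams
    pp_points: np.ndarray  # shape (n, 2): (empirical i/(n+1), fitted F(x_(i)))


def ks_test(sample, p: EIWParams, mode: str = "asymp") -> GofReport:
    """One-sample KS test of ``sample`` against EIW(p).

    ``mode="asymp"`` (default) evaluates the Kolmogorov limit distribution at
    sqrt(n)*D; ``mode="exact"`` uses the exact finite-n two-sided null
    distribution of D.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    F = eiw_cdf(x, p)
    i = np.arange(1, n + 1)
    d = float(max((i / n - F).max(), (F - (i - 1) / n).max()))
    if mode == "asymp":
        pval = float(kolmogorov(np.sqrt(n) * d))
    elif mode == "exact":
        pval = float(kstwo.sf(d, n))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GofReport(
        ks_stat=d,
        p_value=min(max(pval, 0.0), 1.0),
        n=n,
        fitted=p,
        pp_points=pp_series(x, p),
    )


def pp_series(sample, p: EIWParams) -> np.ndarray:
    """P-P pairs (i/(n+1), F(x_(i))) for probability-probability displays."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    return np.column_stack([np.arange(1, n + 1) / (n + 1), eiw_cdf(x, p)])


def cdf_series(sample, p: EIWParams, grid_size: int = 200):
    """Empirical-CDF step coordinates plus a fitted-CDF curve for overlays.

    Returns ``(ecdf_x, ecdf_y, grid, fitted)`` where the grid spans the sample
    range with a small margin.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    ecdf_y = np.arange(1, n + 1) / n
    grid = np.linspace(0.9 * x[0], 1.1 * x[-1], grid_size)
    grid = grid[grid > 0]
    return x, ecdf_y, grid, eiw_cdf(grid, p)
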