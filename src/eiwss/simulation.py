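"""Monte Carlo comparison of the eight estimators.

For each truth case (theta1, theta2, beta) and sample-size pair (n, k), the
study repeatedly draws x ~ EIW(theta1, beta) of size n and y ~ EIW(theta2,
beta) of size k by inverse transform, fits every requested estimator to the
same generated streams, and accumulates the mean and mean squared error of
each parameter estimate and of R_hat. Optionally it also averages parametric
bootstrap interval lengths (percentile and bias-corrected percentile) per
confidence level.

Replicates are sub-seeded from the master seed, so the study is deterministic
and every method sees identical data. Fit failures are excluded from the
affected method's cells (not redrawn) and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import boot_bcp_interval, boot_p_interval, bootstrap_replicates
from .distribution import EIWParams, eiw_rvs
from .estimators import METHODS, ConvergenceError, TwoSampleData, fit_joint

__all__ = ["SimConfig", "SimStudyResult", "run_study", "summarize_to_table"]

_PARAMS = ("theta1", "theta2", "beta", "R")


@dataclass(frozen=True)
class SimConfig:
    """Study design.

    ``cases`` are truth triples (theta1, theta2, beta); ``size_grid`` pairs
    (n, k). ``boot`` optionally activates interval-length accumulation:
    ``{"B": int, "levels": [0.90, ...], "kinds": ["boot_p", "boot_bcp"]}``.
    """

    cases: tuple
    size_grid: tuple
    reps: int = 2000
    methods: tuple = METHODS
    boot: dict | None = None
    master_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "cases", tuple(tuple(map(float, c)) for c in self.cases))
        object.__setattr__(self, "size_grid", tuple(tuple(map(int, s)) for s in self.size_grid))
        object.__setattr__(self, "methods", tuple(m.upper() for m in self.methods))
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not self.methods:
            raise ValueError("methods must be a nonempty subset of the eight tags")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        for c in self.cases:
            if len(c) != 3 or any(v <= 0 for v in c):
                raise ValueError(f"invalid truth triple {c}")
        if self.boot:
            for lv in self.boot.get("levels", ()):
                if not 0 < lv < 1:
                    raise ValueError(f"invalid confidence level {lv}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        # the stress-sample size is written m in parts of the literature
        sizes = []
        for pair in d["size_grid"]:
            if isinstance(pair, dict):
                sizes.append((int(pair["n"]), int(pair.get("k", pair.get("m")))))
            else:
                sizes.append((int(pair[0]), int(pair[1])))
        return cls(
            cases=tuple(tuple(c) for c in d["cases"]),
            size_grid=tuple(sizes),
            reps=int(d.get("reps", 2000)),
            methods=tuple(d.get("methods", METHODS)),
            boot=d.get("boot"),
            master_seed=int(d.get("master_seed", d.get("seed", 0))),
        )


@dataclass
class SimStudyResult:
    config: SimConfig
    # {(case, size, method): {"mean": {...}, "mse": {...}, "failures": int, "reps_used": int}}
    cells: dict = field(default_factory=dict)
    # {(case, size, method, level, kind): mean CI length}
    ci_lengths: dict = field(default_factory=dict)


def _simulate_once(case, size, rng):
    th1, th2, beta = case
    n, k = size
    x = eiw_rvs(n, EIWParams(th1, beta), rng)
    y = eiw_rvs(k, EIWParams(th2, beta), rng)
    return TwoSampleData(x, y)


def run_study(config: SimConfig) -> SimStudyResult:
    """Run the full design; deterministic given ``config.master_seed``."""
    result = SimStudyResult(config=config)
    master = np.random.SeedSequence(config.master_seed)
    n_scen = len(config.cases) * len(config.size_grid)
    scen_seeds = master.spawn(n_scen)
    scen = 0
    for case in config.cases:
        for size in config.size_grid:
            rep_seeds = scen_seeds[scen].spawn(config.reps)
            scen += 1
            acc = {m: [] for m in config.methods}
            boot_acc = {}
            for r in range(config.reps):
                rng = np.random.default_rng(rep_seeds[r])
                data = _simulate_once(case, size, rng)
                for m in config.methods:
                    try:
                        fit = fit_joint(data, m)
                    except ConvergenceError:
                        continue
                    acc[m].append((fit.params.theta1, fit.params.theta2,
                                   fit.params.beta, fit.r_hat))
                    if config.boot:
                        _accumulate_boot(boot_acc, data, m, config.boot,
                                         rep_seeds[r].spawn(1)[0])
            truth = case + (case[0] / (case[0] + case[1]),)
            for m in config.methods:
                vals = np.asarray(acc[m])
                used = vals.shape[0]
                cell = {"failures": config.reps - used, "reps_used": used,
                        "mean": {}, "mse": {}}
                if used:
                    for j, pname in enumerate(_PARAMS):
                        cell["mean"][pname] = float(vals[:, j].mean())
                        cell["mse"][pname] = float(((vals[:, j] - truth[j]) ** 2).mean())
                result.cells[(case, size, m)] = cell
                for key, lengths in boot_acc.items():
                    if key[0] == m:
                        result.ci_lengths[(case, size) + key] = float(np.mean(lengths))
    return result


def _accumulate_boot(boot_acc: dict, data: TwoSampleData, method: str,
                     boot: dict, seed) -> None:
    B = int(boot.get("B", 500))
    levels = boot.get("levels", (0.95,))
    kinds = boot.get("kinds", ("boot_p", "boot_bcp"))
    try:
        reps, r_hat = bootstrap_replicates(data, method, B, seed)
    except ConvergenceError:
        return
    for lv in levels:
        g = 1.0 - lv
        if "boot_p" in kinds:
            lo, hi = boot_p_interval(reps, g)
            boot_acc.setdefault((method, lv, "boot_p"), []).append(hi - lo)
        if "boot_bcp" in kinds:
            lo, hi, _ = boot_bcp_interval(reps, r_hat, g)
            boot_acc.setdefault((method, lv, "boot_bcp"), []).append(hi - lo)


def summarize_to_table(result: SimStudyResult, layout: str = "point") -> pd.DataFrame:
    """Tabulate the study in the journal-table shape.

    ``layout="point"``: rows (case, method, statistic in {Mean, MSE}),
    one column block (theta1, theta2, beta, R) per size pair.
    ``layout="ci_length"``: rows (case, size, method), one L column per
    (level, kind).
    """
    cfg = result.config
    if layout == "point":
        rows = []
        for case in cfg.cases:
            for m in cfg.methods:
                for stat in ("Mean", "MSE"):
                    row = {"theta1_true": case[0], "theta2_true": case[1],
                           "beta_true": case[2], "method": m, "statistic": stat}
                    for size in cfg.size_grid:
                        cell = result.cells[(case, size, m)]
                        src = cell["mean" if stat == "Mean" else "mse"]
                        for pname in _PARAMS:
                            row[f"n{size[0]}_k{size[1]}_{pname}"] = src.get(pname, np.nan)
                    rows.append(row)
        return pd.DataFrame(rows)
    if layout == "ci_length":
        rows = []
        for case in cfg.cases:
            for size in cfg.size_grid:
                for m in cfg.methods:
                    row = {"theta1_true": case[0], "theta2_true": case[1],
                           "beta_true": case[2], "n": size[0], "k": size[1],
                           "method": m}
                    any_col = False
                    for (c, s, meth, lv, kind), L in result.ci_lengths.items():
                        if c == case and s == size and meth == m:
                            row[f"L_{kind}_{int(round(lv * 100))}"] = L
                            any_col = True
                    if any_col:
                        rows.append(row)
        return pd.DataFrame(rows)
    raise ValueError(f"unknown layout {layout!r}")
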