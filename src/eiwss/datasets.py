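"""Bundled case-study datasets and synthetic fixtures.

Two classical breaking-strength datasets ship with the package as plain-text
resources (one value per line):

``jute``
    Breaking strengths of jute fibre at gauge lengths 10 mm (strength sample
    X, n = 30) and 20 mm (stress sample Y, k = 30), from Xia et al. (2009).
``carbon``
    Tensile strength (GPa) of single carbon fibres from Bader & Priest (1982):
    Data Set I (n = 63) as strength X and Data Set II (k = 69) as stress Y.
    Note the two sets are labelled by gauge length inconsistently in parts of
    the secondary literature; here X is always the 63-value (higher-strength)
    set and Y the 69-value set, which is the orientation under which
    R = P(Y < X) exceeds 1/2.

``make_fixture`` draws synthetic two-sample data from known EIW truths for
recovery tests and simulation smoke runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .distribution import EIWParams, eiw_rvs

__all__ = ["NamedDataset", "load_dataset", "make_fixture", "read_sample", "DATASET_NAMES"]

DATASET_NAMES = ("jute", "carbon")

_PROVENANCE = {
    "jute": "Breaking strengths of jute fibre at 10 mm (X) and 20 mm (Y) gauge "
            "length; Xia, Yu, Cheng, Liu & Wang (2009), J. Textile Inst.",
    "carbon": "Single carbon-fibre tensile strengths (GPa); Bader & Priest (1982). "
              "X = Data Set I (n=63), Y = Data Set II (k=69).",
}


@dataclass(frozen=True)
class NamedDataset:
    name: str
    x: np.ndarray
    y: np.ndarray
    provenance: str


def _read_resource(fname: str) -> np.ndarray:
    ref = resources.files("eiwss.data").joinpath(fname)
    return np.loadtxt(ref.read_text().splitlines(), dtype=float)


def load_dataset(name: str) -> NamedDataset:
    """Load a bundled dataset by name; returns fresh copies on every call."""
    if name not in DATASET_NAMES:
        raise KeyError(f"unknown dataset {name!r}; available: {DATASET_NAMES}")
    return NamedDataset(
        name=name,
        x=_read_resource(f"{name}_x.txt"),
        y=_read_resource(f"{name}_y.txt"),
        provenance=_PROVENANCE[name],
    )


def make_fixture(theta1: float, theta2: float, beta: float,
                 n: int, k: int, seed=0) -> NamedDataset:
    """Synthetic two-sample EIW dataset with the generating truth in its name."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sx, sy = ss.spawn(2)
    return NamedDataset(
        name=f"synthetic(theta1={theta1},theta2={theta2},beta={beta})",
        x=eiw_rvs(n, EIWParams(theta1, beta), sx),
        y=eiw_rvs(k, EIWParams(theta2, beta), sy),
        provenance="synthetic, generated by eiwss.datasets.make_fixture",
    )


def read_sample(path) -> np.ndarray:
    """Read one sample from a text file: one positive decimal per line, or a
    single-column CSV with an optional header line."""
    values = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip().rstrip(",")
            if not line:
                continue
            try:
                v = float(line)
            except ValueError:
                if lineno == 1:  # tolerate a header
                    continue
                raise ValueError(f"{path}:{lineno}: not a number: {line!r}") from None
            if not v > 0:
                raise ValueError(f"{path}:{lineno}: values must be positive, got {v}")
            values.append(v)
    if len(values) < 2:
        raise ValueError(f"{path}: need at least 2 positive values")
    return np.asarray(values, dtype=float)
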