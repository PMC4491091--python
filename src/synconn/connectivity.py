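"""Partial-correlation connectivity matrices.

The partial correlation between two regions is the Pearson correlation
of their residual series after regressing each on all remaining regions
(plus an intercept).  For a Gaussian graphical model this equals
``-w_ij / sqrt(w_ii * w_jj)`` on the precision matrix ``W``; the
regression route is the implementation here, the precision identity is
kept for tests as an independent oracle.

Subject matrices are Fisher-transformed (Z = atanh r) and averaged
element-wise across the subjects of a group on the Z scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import RegionCatalog


def fisher_z(r):
    """Fisher r-to-Z transformation, Z = atanh(r) = 0.5 ln((1+r)/(1-r))."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r[np.isfinite(r)]) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher transformation")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    """tanh, the inverse of the Fisher transformation."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region matrix of r or Z values; diagonal is NaN."""

    values: np.ndarray
    region_names: list[str]
    scale: str  # "r" or "Z"
    level: str  # "subject" or "group"
    n_subjects: int | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        if v.shape[0] != len(self.region_names):
            raise ValueError("region_names length does not match matrix size")
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.allclose(v[off], v.T[off], atol=1e-10, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if self.scale not in ("r", "Z"):
            raise ValueError("scale must be 'r' or 'Z'")
        np.fill_diagonal(v, np.nan)  # diagonal undefined by construction
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_names, columns=self.region_names)

    def to_z(self) -> "ConnectivityMatrix":
        if self.scale == "Z":
            return self
        z = np.full_like(self.values, np.nan)
        off = ~np.eye(self.n_regions, dtype=bool)
        z[off] = fisher_z(self.values[off])
        return ConnectivityMatrix(
            values=z,
            region_names=self.region_names,
            scale="Z",
            level=self.level,
            n_subjects=self.n_subjects,
            subject_id=self.subject_id,
        )

    def pair_value(self, name_a: str, name_b: str) -> float:
        i = self.region_names.index(name_a)
        j = self.region_names.index(name_b)
        return float(self.values[i, j])


def _residualize(y: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), regressors])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient regressor matrix (collinear columns)")
    return y - X @ coef


def partial_corr_pair(X: np.ndarray, i: int, j: int) -> float:
    """Partial correlation of columns i and j given all other columns.

    Both columns are regressed (OLS with intercept) on the remaining
    columns; the Pearson correlation of the two residual series is
    returned.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if i == j:
        raise ValueError("i and j must differ")
    if n <= p + 2:
        raise ValueError(f"need more than {p + 2} time points for {p} regions, got {n}")
    others = [k for k in range(p) if k not in (i, j)]
    Z = X[:, others]
    ri = _residualize(X[:, i], Z)
    rj = _residualize(X[:, j], Z)
    for col, res in ((i, ri), (j, rj)):
        scale = np.linalg.norm(X[:, col] - X[:, col].mean())
        if np.linalg.norm(res) <= 1e-8 * max(scale, 1.0):
            raise ValueError(
                f"column {col} is collinear with the other nodes (zero residual variance)"
            )
    denom = np.linalg.norm(ri) * np.linalg.norm(rj)
    # residuals are orthogonal to the intercept, so this is the Pearson r
    return float(np.dot(ri, rj) / denom)


def regress_out(X, regressors: np.ndarray):
    """Residualize every column of X on the given regressors (+intercept).

    Used by the optional ``remove_task_design`` path, which removes the
    task-evoked component before correlating.
    """
    data = np.asarray(X.to_numpy() if hasattr(X, "to_numpy") else X, dtype=float)
    R = np.atleast_2d(np.asarray(regressors, dtype=float))
    if R.shape[0] != data.shape[0]:
        R = R.T
    design = np.column_stack([np.ones(data.shape[0]), R])
    coef, *_ = np.linalg.lstsq(design, data, rcond=None)
    resid = data - design @ coef + data.mean(axis=0, keepdims=True)
    if hasattr(X, "to_numpy"):
        return pd.DataFrame(resid, columns=X.columns, index=X.index)
    return resid


def partial_corr_matrix(
    X: np.ndarray,
    region_names: Sequence[str] | None = None,
    subject_id: str | None = None,
) -> ConnectivityMatrix:
    """All-pairs partial correlation matrix of a time x region matrix."""
    X = np.asarray(X.to_numpy() if hasattr(X, "to_numpy") else X, dtype=float)
    p = X.shape[1]
    if region_names is None:
        region_names = [f"region_{k}" for k in range(p)]
    values = np.full((p, p), np.nan)
    for i, j in combinations(range(p), 2):
        r = partial_corr_pair(X, i, j)
        values[i, j] = values[j, i] = r
    return ConnectivityMatrix(
        values=values,
        region_names=list(region_names),
        scale="r",
        level="subject",
        subject_id=subject_id,
    )


def group_average(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean across subjects, computed on the Fisher-Z scale."""
    if not matrices:
        raise ValueError("need at least one subject matrix")
    names = matrices[0].region_names
    for m in matrices:
        if m.region_names != names:
            raise ValueError("matrices have mismatched region axes")
    zs = np.stack([m.to_z().values for m in matrices])
    return ConnectivityMatrix(
        values=zs.mean(axis=0),
        region_names=names,
        scale="Z",
        level="group",
        n_subjects=len(matrices),
    )


# ---------------------------------------------------------------------------
# Pair categories over the three-network partition

PAIR_CATEGORIES = (
    "within-I",
    "within-II",
    "within-III",
    "between-(I,II)",
    "between-(I,III)",
    "between-(II,III)",
)
WITHIN_CATEGORIES = PAIR_CATEGORIES[:3]
BETWEEN_CATEGORIES = PAIR_CATEGORIES[3:]


@dataclass(frozen=True)
class PairIndex:
    region_a: int
    region_b: int
    category: str


def pair_category(net_a: str, net_b: str) -> str:
    if net_a == net_b:
        return f"within-{net_a}"
    lo, hi = sorted([net_a, net_b], key=("I", "II", "III").index)
    return f"between-({lo},{hi})"


def pair_index(catalog: RegionCatalog) -> list[PairIndex]:
    """Every unordered region pair (a < b) with its network category."""
    nets = catalog.networks
    return [
        PairIndex(a, b, pair_category(nets[a], nets[b]))
        for a, b in combinations(range(len(catalog)), 2)
    ]


def category_pair_values(
    matrix: ConnectivityMatrix, catalog: RegionCatalog
) -> dict[str, np.ndarray]:
    """Off-diagonal values of a matrix grouped by pair category."""
    if matrix.region_names != catalog.names:
        raise ValueError("matrix axes do not match the catalog")
    out: dict[str, list[float]] = {c: [] for c in PAIR_CATEGORIES}
    for pair in pair_index(catalog):
        out[pair.category].append(matrix.values[pair.region_a, pair.region_b])
    return {c: np.asarray(v) for c, v in out.items()}
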