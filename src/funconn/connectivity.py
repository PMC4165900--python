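"""Pearson functional connectivity and sparsity-based binarization.

A subject's connectome is the symmetric matrix of Pearson correlations
between every pair of region time series. To obtain binary networks, the
weakest (most negative) correlations are pruned until only the K strongest
pairs remain, where K is set by the target sparsity — the fraction of the
N(N-1)/2 possible edges kept. Repeating this across an ascending grid of
sparsities yields a nested family of graphs over the small-world regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import BinaryGraph, round_half_up
from .timeseries import RoiTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "SparsityGrid",
    "correlation_matrix",
    "n_pairs",
    "binarize_at_sparsity",
    "sparsity_sweep",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N Pearson correlation structure with zero diagonal."""

    r_values: np.ndarray
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.r_values, dtype=np.float64)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("r_values must be square")
        if not np.allclose(r, r.T):
            raise ValueError("r_values must be symmetric")
        r = (r + r.T) / 2.0  # enforce exact symmetry
        np.fill_diagonal(r, 0.0)
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "r_values", np.clip(r, -1.0, 1.0))
        object.__setattr__(self, "region_names", tuple(self.region_names))
        if len(self.region_names) != r.shape[0]:
            raise ValueError("region_names length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.r_values.shape[0]


@dataclass(frozen=True)
class SparsityGrid:
    """Ascending arithmetic grid of sparsity values in (0, 1)."""

    s_min: float = 0.10
    s_max: float = 0.34
    step: float = 0.01
    values: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.s_min < self.s_max < 1):
            raise ValueError("require 0 < s_min < s_max < 1")
        if self.step <= 0:
            raise ValueError("step must be positive")
        n = int(np.floor((self.s_max - self.s_min) / self.step + 1e-9)) + 1
        vals = tuple(round(self.s_min + k * self.step, 10) for k in range(n))
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def midpoint(self) -> float:
        """The grid value closest to the middle of the regime."""
        vals = np.asarray(self.values)
        return float(vals[np.argmin(np.abs(vals - (self.s_min + self.s_max) / 2))])


def n_pairs(n_regions: int) -> int:
    """Number of unordered region pairs: n(n-1)/2. 90 regions -> 4005."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    return n_regions * (n_regions - 1) // 2


def correlation_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of all region time series.

    Raises if any region has zero variance (correlation undefined) or if
    fewer than 3 timepoints are available.
    """
    x = ts.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(ts.region_names[i] for i in bad)
        raise ValueError(f"zero-variance region(s): {names}")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r_values=r, region_names=ts.region_names)


def _ranked_pairs(conn: ConnectivityMatrix, absolute: bool = False) -> np.ndarray:
    """Pair indices sorted by descending r, ties broken by ascending (i, j)."""
    n = conn.n_regions
    iu = np.triu_indices(n, k=1)
    r = conn.r_values[iu]
    key = np.abs(r) if absolute else r
    # lexsort: last key is primary; -key descending, then i then j ascending
    order = np.lexsort((iu[1], iu[0], -key))
    return np.column_stack((iu[0][order], iu[1][order]))


def binarize_at_sparsity(
    conn: ConnectivityMatrix, sparsity: float, absolute: bool = False
) -> BinaryGraph:
    """Keep the K = round(sparsity * n_pairs) strongest pairs as edges.

    Ranking is by signed r by default (negative correlations are pruned
    first); ``absolute=True`` ranks by |r| instead. Ties at the cutoff are
    broken deterministically by ascending (i, j) pair order.
    """
    if not (0 < sparsity <= 1):
        raise ValueError("sparsity must be in (0, 1]")
    total = n_pairs(conn.n_regions)
    k = round_half_up(sparsity * total)
    if k == 0:
        raise ValueError(f"sparsity {sparsity} keeps zero edges")
    pairs = _ranked_pairs(conn, absolute=absolute)[:k]
    a = np.zeros((conn.n_regions, conn.n_regions), dtype=np.int8)
    a[pairs[:, 0], pairs[:, 1]] = 1
    a[pairs[:, 1], pairs[:, 0]] = 1
    return BinaryGraph(adjacency=a, sparsity=sparsity)


def sparsity_sweep(
    conn: ConnectivityMatrix, grid: SparsityGrid, absolute: bool = False
) -> list[BinaryGraph]:
    """One binary graph per grid value; edge sets are nested along the grid."""
    return [binarize_at_sparsity(conn, s, absolute=absolute) for s in grid.values]
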