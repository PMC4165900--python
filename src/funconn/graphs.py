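"""Binary undirected graph containers and sparsity-thresholded graph construction.

Functional brain networks are represented as undirected, unweighted graphs
obtained by keeping the strongest entries of a Pearson correlation matrix
until a target edge density ("sparsity") is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BinaryGraph:
    """An undirected, unweighted graph on N nodes.

    Parameters
    ----------
    adjacency : (N, N) ndarray of 0/1
        Symmetric with zero diagonal.
    sparsity : float
        Fraction of the N(N-1)/2 possible edges present, in (0, 1].
        Purely descriptive metadata; the adjacency is authoritative.
    """

    adjacency: np.ndarray
    sparsity: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1 (weighted graphs are rejected)")
        object.__setattr__(self, "adjacency", a.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degree(self) -> np.ndarray:
        """Per-node degree (row sums of the adjacency matrix)."""
        return self.adjacency.sum(axis=1).astype(np.int64)


def round_half_up(x: float) -> int:
    """Round to the nearest integer, with .5 rounding away from zero."""
    return int(np.floor(x + 0.5))
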