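"""Global and nodal metrics of binary undirected graphs.

All metrics are computed from scratch on the adjacency matrix: breadth-first
shortest paths, clustering, characteristic path length, global/local
efficiency, degree, nodal efficiency, and Brandes betweenness centrality.

Conventions for disconnected graphs
-----------------------------------
* Characteristic path length averages over *finite* pairs only, so it stays
  defined across an entire sparsity sweep where low-density graphs may
  fragment.
* Efficiencies use 1/inf = 0, which handles disconnection natively.
* Betweenness is normalized by (N-1)(N-2)/2 so values lie in [0, 1] and are
  comparable across parcellations of different size; raw counts are available
  via ``normalized=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import BinaryGraph

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "distance_matrix",
    "clustering",
    "char_path_length",
    "global_efficiency",
    "local_efficiency",
    "betweenness",
    "degree",
    "global_metrics",
    "nodal_metrics",
]


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-network summary: clustering Cp, path length Lp, efficiencies."""

    cp: float
    lp: float
    e_glob: float
    e_loc: float


@dataclass(frozen=True)
class NodalMetrics:
    """Per-region centrality: degree, nodal efficiency, betweenness."""

    degree: np.ndarray
    nodal_efficiency: np.ndarray
    betweenness: np.ndarray


def distance_matrix(g: BinaryGraph) -> np.ndarray:
    """All-pairs shortest-path hop counts via BFS; np.inf for unreachable pairs."""
    a = g.adjacency
    n = g.n_nodes
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    # frontier-at-a-time BFS, one source per column of a boolean workspace
    for s in range(n):
        visited = np.zeros(n, dtype=bool)
        visited[s] = True
        frontier = np.zeros(n, dtype=bool)
        frontier[s] = True
        d = 0
        while frontier.any():
            d += 1
            nxt = (a[frontier].any(axis=0)) & ~visited
            dist[s, nxt] = d
            visited |= nxt
            frontier = nxt
    return dist


def degree(g: BinaryGraph) -> np.ndarray:
    """Per-node degree."""
    return g.degree()


def clustering(g: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficient C_i and the network mean Cp.

    C_i = 2 t_i / (k_i (k_i - 1)) where t_i is the number of edges among the
    neighbors of i; nodes with degree < 2 have C_i = 0. Cp is the unweighted
    mean over all N nodes.
    """
    a = g.adjacency.astype(np.float64)
    k = a.sum(axis=1)
    # diag of A^3 counts closed triangles through each node (twice per triangle)
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # = 2 t_i
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c, float(c.mean())


def char_path_length(g: BinaryGraph, dist: np.ndarray | None = None) -> float:
    """Characteristic path length: mean hop count over finite unordered pairs.

    Pairs in different components are excluded from both numerator and
    denominator. Raises if no finite pair exists (edgeless graph).
    """
    if dist is None:
        dist = distance_matrix(g)
    iu = np.triu_indices(g.n_nodes, k=1)
    d = dist[iu]
    finite = np.isfinite(d)
    if not finite.any():
        raise ValueError("graph has no connected pair; Lp undefined")
    return float(d[finite].mean())


def global_efficiency(
    g: BinaryGraph, dist: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Global efficiency and per-node nodal efficiency.

    Nodal E_i = mean over j != i of 1/d(i, j) with 1/inf = 0; the global value
    is the mean of the nodal values (equivalently the pair form).
    """
    if dist is None:
        dist = distance_matrix(g)
    n = g.n_nodes
    if n < 2:
        return 0.0, np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    nodal = inv.sum(axis=1) / (n - 1)
    return float(nodal.mean()), nodal


def local_efficiency(g: BinaryGraph) -> tuple[float, np.ndarray]:
    """Mean local efficiency and per-node values.

    E_loc(i) is the global efficiency of the subgraph induced by i's
    neighbors; 0 when the node has fewer than 2 neighbors.
    """
    a = g.adjacency
    n = g.n_nodes
    vals = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = BinaryGraph(a[np.ix_(nbrs, nbrs)])
        vals[i], _ = global_efficiency(sub)
    return float(vals.mean()), vals


def betweenness(g: BinaryGraph, normalized: bool = True) -> np.ndarray:
    """Shortest-path betweenness centrality (Brandes' accumulation).

    Counts, for each node v, the fraction of shortest paths between other
    node pairs that pass through v, summed over unordered pairs. With
    ``normalized=True`` the sum is divided by (N-1)(N-2)/2.
    """
    a = g.adjacency
    n = g.n_nodes
    bc = np.zeros(n)
    neighbors = [np.flatnonzero(a[v]) for v in range(n)]
    for s in range(n):
        # single-source shortest paths with path counting
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        stack: list[int] = []
        queue = [s]
        while queue:
            nxt: list[int] = []
            for v in queue:
                stack.append(v)
                for w in neighbors[v]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
            queue = nxt
        delta = np.zeros(n)
        for w in reversed(stack):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # each unordered pair counted from both endpoints
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def global_metrics(g: BinaryGraph, dist: np.ndarray | None = None) -> GlobalMetrics:
    """Compute Cp, Lp, Eglob, Eloc in one pass (shares the distance matrix)."""
    if dist is None:
        dist = distance_matrix(g)
    _, cp = clustering(g)
    lp = char_path_length(g, dist)
    e_glob, _ = global_efficiency(g, dist)
    e_loc, _ = local_efficiency(g)
    return GlobalMetrics(cp=cp, lp=lp, e_glob=e_glob, e_loc=e_loc)


def nodal_metrics(g: BinaryGraph, dist: np.ndarray | None = None) -> NodalMetrics:
    """Compute the three nodal centralities (degree, efficiency, betweenness)."""
    if dist is None:
        dist = distance_matrix(g)
    _, nodal_eff = global_efficiency(g, dist)
    return NodalMetrics(
        degree=g.degree(),
        nodal_efficiency=nodal_eff,
        betweenness=betweenness(g),
    )
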