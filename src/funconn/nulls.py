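"""Degree-preserving random networks and normalized small-world parameters.

A network is called small-world when its clustering greatly exceeds that of
degree-matched random graphs (gamma = Cp/Cp_rand > 1) while its
characteristic path length stays comparable (lambda = Lp/Lp_rand ~ 1), so
that the small-world ratio sigma = gamma/lambda exceeds 1. The random
ensemble is built by repeated double-edge swaps, which preserve the node
count, edge count, and the full degree sequence of the observed graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import BinaryGraph
from .metrics import char_path_length, clustering, distance_matrix

__all__ = ["SmallWorldResult", "rewire_preserving_degree", "normalized_small_world"]


@dataclass(frozen=True)
class SmallWorldResult:
    """Normalized small-world parameters against a rewired null ensemble."""

    gamma: float
    lam: float
    sigma: float
    n_rand: int
    is_small_world: bool
    epsilon_lambda: float


def rewire_preserving_degree(
    g: BinaryGraph,
    n_swaps_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
) -> BinaryGraph:
    """Randomize a graph by double-edge swaps, preserving every degree.

    Repeatedly picks two edges (a, b), (c, d) and rewires them to (a, d),
    (c, b); a swap is skipped (and counted as failed) when it would create a
    self-loop or a duplicate edge. The target number of successful swaps is
    ``n_swaps_per_edge`` times the edge count, with an attempt cap of ten
    times that, so graphs with few legal swaps (e.g. a triangle) return
    unchanged rather than looping forever.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = g.adjacency.copy()
    iu = np.triu_indices(g.n_nodes, k=1)
    edges = [tuple(e) for e in np.column_stack(iu)[a[iu] == 1]]
    m = len(edges)
    if m < 2:
        return BinaryGraph(adjacency=a, sparsity=g.sparsity)
    target = n_swaps_per_edge * m
    attempts_cap = 10 * target
    done = attempts = 0
    while done < target and attempts < attempts_cap:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a1, b1 = edges[i]
        c1, d1 = edges[j]
        # randomly orient the second edge to reach both pairings
        if rng.integers(0, 2):
            c1, d1 = d1, c1
        if len({a1, b1, c1, d1}) < 4:
            continue  # would create a self-loop
        if a[a1, d1] or a[c1, b1]:
            continue  # would create a duplicate edge
        a[a1, b1] = a[b1, a1] = 0
        a[c1, d1] = a[d1, c1] = 0
        a[a1, d1] = a[d1, a1] = 1
        a[c1, b1] = a[b1, c1] = 1
        edges[i] = (min(a1, d1), max(a1, d1))
        edges[j] = (min(c1, b1), max(c1, b1))
        done += 1
    return BinaryGraph(adjacency=a, sparsity=g.sparsity)


def normalized_small_world(
    g: BinaryGraph,
    n_rand: int = 100,
    seed: int | np.random.Generator = 0,
    n_swaps_per_edge: int = 10,
    epsilon_lambda: float = 0.15,
) -> SmallWorldResult:
    """Gamma, lambda and sigma against ``n_rand`` degree-preserving surrogates.

    The classification rule is gamma > 1, |lambda - 1| <= epsilon_lambda,
    and sigma > 1; the raw values are always reported so callers can apply
    their own rule. Surrogates may be disconnected: Lp averages finite pairs
    only, so no connectivity repair is applied (enforcing connectivity would
    bias the null at low sparsity).
    """
    if g.n_edges < 1:
        raise ValueError("graph needs at least one edge")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _, cp = clustering(g)
    lp = char_path_length(g)
    cps = np.empty(n_rand)
    lps = np.empty(n_rand)
    for k in range(n_rand):
        surr = rewire_preserving_degree(g, n_swaps_per_edge=n_swaps_per_edge, seed=rng)
        _, cps[k] = clustering(surr)
        lps[k] = char_path_length(surr, distance_matrix(surr))
    if cps.mean() == 0:
        raise ValueError("degenerate null: surrogate ensemble has zero clustering")
    gamma = cp / cps.mean()
    lam = lp / lps.mean()
    sigma = gamma / lam
    return SmallWorldResult(
        gamma=float(gamma),
        lam=float(lam),
        sigma=float(sigma),
        n_rand=n_rand,
        is_small_world=bool(gamma > 1 and abs(lam - 1) <= epsilon_lambda and sigma > 1),
        epsilon_lambda=epsilon_lambda,
    )
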