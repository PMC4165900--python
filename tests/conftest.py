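import numpy as np
import pytest

from funconn.graphs import BinaryGraph
from funconn.studies import cohort_tables  # noqa: F401  (shared helper)
from funconn.synthetic import CohortConfig, make_cohort


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryGraph(a)


def complete_graph(n):
    a = np.ones((n, n), dtype=int)
    np.fill_diagonal(a, 0)
    return BinaryGraph(a)


def ring_lattice(n, k):
    """Each node linked to its k nearest neighbours (k even)."""
    a = np.zeros((n, n), dtype=int)
    for i in range(n):
        for d in range(1, k // 2 + 1):
            a[i, (i + d) % n] = a[(i + d) % n, i] = 1
    return BinaryGraph(a)


def random_graph(n, p, rng):
    upper = rng.random((n, n)) < p
    a = np.triu(upper, k=1).astype(int)
    return BinaryGraph(a + a.T)


@pytest.fixture(scope="session")
def small_null_cohort():
    """17 vs 16 subjects, 20 regions, no planted effects."""
    cfg = CohortConfig(
        n_group_a=17, n_group_b=16, n_regions=20, n_timepoints=210,
        module_sizes=(5, 5, 5, 5), seed=101,
    )
    return make_cohort(cfg)
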