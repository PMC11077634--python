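import numpy as np
import pytest

from perfnet import BinaryGraph, CorrelationNetwork, RegionalCBFMatrix, make_default_models


def graph_from_edges(n: int, edges, sparsity: float = 0.5) -> BinaryGraph:
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return BinaryGraph(adjacency=adj, sparsity=sparsity, region_ids=list(range(1, n + 1)))


def graph_from_adjacency(adj, sparsity: float = 0.5) -> BinaryGraph:
    adj = np.asarray(adj, dtype=bool)
    return BinaryGraph(adjacency=adj, sparsity=sparsity, region_ids=list(range(1, len(adj) + 1)))


def random_network(R: int, seed: int, n_subjects: int = 20, group: str = "G") -> CorrelationNetwork:
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_subjects, R))
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return CorrelationNetwork(r=r, n_subjects=n_subjects, group=group, region_ids=list(range(1, R + 1)))


def matrix_from_values(values, group: str = "G") -> RegionalCBFMatrix:
    values = np.asarray(values, dtype=float)
    return RegionalCBFMatrix(
        values=values,
        subject_ids=[f"{group}{i}" for i in range(values.shape[0])],
        region_ids=list(range(1, values.shape[1] + 1)),
        group=group,
    )


@pytest.fixture(scope="session")
def small_truth():
    """Three-group generative truth at 40 regions (fast variant of the default)."""
    return make_default_models(R=40, seed=3)


@pytest.fixture(scope="session")
def default_truth():
    """The full default 246-region generative truth."""
    return make_default_models(R=246, seed=1)
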