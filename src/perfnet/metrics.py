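"""Global and nodal topology of binary undirected brain graphs.

Covers the measures used to characterize CBF correlation networks: global
efficiency, mean clustering coefficient, characteristic path length, the
small-world coefficient sigma against degree-preserving random references,
betweenness centrality, and the hub rule (BC more than twice the mean).

Conventions for disconnected graphs follow the standard toolbox behavior:
efficiency uses 1/inf = 0 for disconnected pairs, and the characteristic
path length is averaged within the largest connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .network import BinaryGraph

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "HubSet",
    "global_efficiency",
    "clustering_coefficient",
    "characteristic_path_length",
    "betweenness_centrality",
    "random_reference",
    "small_world_sigma",
    "compute_global_metrics",
    "detect_hubs",
    "hub_bc_across_groups",
]


@dataclass
class GlobalMetrics:
    """Global topology summary of one thresholded group network."""

    global_efficiency: float
    clustering_coefficient: float
    characteristic_path_length: float
    small_world_sigma: float
    sparsity: float
    group: str = ""


@dataclass
class NodalMetrics:
    """Per-region betweenness centrality (unnormalized, fractional path counts)."""

    bc: np.ndarray
    region_ids: list[int]
    sparsity: float
    group: str = ""


@dataclass
class HubSet:
    """Regions whose BC strictly exceeds twice the mean BC."""

    region_ids: list[int]
    threshold: float
    group: str = ""


def _distance_matrix(adj: np.ndarray) -> np.ndarray:
    sp = csr_matrix(adj.astype(np.int8))
    return shortest_path(sp, method="D", directed=False, unweighted=True)


def global_efficiency(g: BinaryGraph) -> float:
    """Average inverse shortest-path length over ordered node pairs."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    d = _distance_matrix(g.adjacency)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def clustering_coefficient(g: BinaryGraph) -> tuple[np.ndarray, float]:
    """Fraction of closed triangles around each node, and the mean over nodes.

    Nodes of degree < 2 have clustering 0.
    """
    a = g.adjacency.astype(float)
    k = a.sum(axis=1)
    closed = np.diagonal(a @ a @ a)  # 2 * triangles through each node
    denom = k * (k - 1)
    nodal = np.zeros(g.n_nodes)
    ok = denom > 0
    nodal[ok] = closed[ok] / denom[ok]
    return nodal, float(nodal.mean())


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean shortest-path distance within the largest connected component."""
    if g.n_edges == 0:
        raise ValueError("no connected pairs: graph has no edges")
    adj = g.adjacency
    n_comp, labels = connected_components(csr_matrix(adj.astype(np.int8)), directed=False)
    sizes = np.bincount(labels)
    giant = np.argmax(sizes)
    idx = np.flatnonzero(labels == giant)
    d = _distance_matrix(adj[np.ix_(idx, idx)])
    m = idx.size
    if m < 2:
        raise ValueError("no connected pairs: largest component is a single node")
    off = ~np.eye(m, dtype=bool)
    return float(d[off].mean())


def betweenness_centrality(g: BinaryGraph) -> NodalMetrics:
    """Exact unnormalized betweenness (Brandes) with fractional shortest-path counts."""
    G = nx.from_numpy_array(g.adjacency.astype(np.int8))
    bc_dict = nx.betweenness_centrality(G, normalized=False)
    bc = np.array([bc_dict[i] for i in range(g.n_nodes)], dtype=float)
    return NodalMetrics(bc=bc, region_ids=list(g.region_ids), sparsity=g.sparsity, group=g.group)


# ---------------------------------------------------------------------------
# Degree-preserving randomization (Maslov-Sneppen double edge swaps)


def _swap_kernel_py(edges: np.ndarray, adj: np.ndarray, pick1: np.ndarray, pick2: np.ndarray, flip: np.ndarray) -> None:
    for t in range(pick1.shape[0]):
        i = pick1[t]
        j = pick2[t]
        if i == j:
            continue
        a, b = edges[i, 0], edges[i, 1]
        c, d = edges[j, 0], edges[j, 1]
        if flip[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        edges[i, 1] = d
        edges[j, 1] = b
        edges[j, 0] = c
        edges[i, 0] = a


try:  # numba keeps the 100-reference ensembles on 246-node graphs fast
    from numba import njit

    _swap_kernel = njit(cache=False)(_swap_kernel_py)
except Exception:  # pragma: no cover - exercised only without numba
    _swap_kernel = _swap_kernel_py


def random_reference(g: BinaryGraph, n_rewires: int | None = None, seed: int | np.random.Generator = 0) -> BinaryGraph:
    """Degree-preserving randomization by double edge swaps.

    Performs ``n_rewires`` swap attempts (default 10x the edge count); each
    successful swap replaces edges (a,b),(c,d) with (a,d),(c,b), preserving
    every node's degree and keeping the graph simple.
    """
    m = g.n_edges
    if m < 2:
        warnings.warn("graph too small to rewire; returning a copy", stacklevel=2)
        return BinaryGraph(adjacency=g.adjacency.copy(), sparsity=g.sparsity, region_ids=list(g.region_ids), group=g.group)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_attempts = 10 * m if n_rewires is None else int(n_rewires)
    iu, ju = np.nonzero(np.triu(g.adjacency, k=1))
    edges = np.stack([iu, ju], axis=1).astype(np.int64)
    adj = g.adjacency.copy()
    pick1 = rng.integers(0, m, size=n_attempts)
    pick2 = rng.integers(0, m, size=n_attempts)
    flip = rng.integers(0, 2, size=n_attempts).astype(np.bool_)
    _swap_kernel(edges, adj, pick1, pick2, flip)
    return BinaryGraph(adjacency=adj, sparsity=g.sparsity, region_ids=list(g.region_ids), group=g.group)


def small_world_sigma(
    g: BinaryGraph,
    n_refs: int = 100,
    seed: int = 0,
    return_parts: bool = False,
):
    """Small-world coefficient sigma = (C/C_rand) / (L/L_rand).

    ``C_rand`` and ``L_rand`` are averaged over ``n_refs`` degree-preserving
    random references; sigma > 1 indicates small-world organization.
    """
    _, c_obs = clustering_coefficient(g)
    l_obs = characteristic_path_length(g)
    ss = np.random.SeedSequence(seed)
    c_refs = np.empty(n_refs)
    l_refs = np.empty(n_refs)
    for k, child in enumerate(ss.spawn(n_refs)):
        ref = random_reference(g, seed=np.random.default_rng(child))
        _, c_refs[k] = clustering_coefficient(ref)
        l_refs[k] = characteristic_path_length(ref)
    c_rand = float(c_refs.mean())
    l_rand = float(l_refs.mean())
    if c_rand == 0 or l_rand == 0:
        raise ValueError("degenerate random references (zero clustering or path length)")
    sigma = (c_obs / c_rand) / (l_obs / l_rand)
    if return_parts:
        return sigma, {"C": c_obs, "L": l_obs, "C_rand": c_rand, "L_rand": l_rand}
    return sigma


def compute_global_metrics(g: BinaryGraph, n_refs: int = 100, seed: int = 0) -> GlobalMetrics:
    """All global measures of one thresholded network in a single record."""
    _, c_mean = clustering_coefficient(g)
    return GlobalMetrics(
        global_efficiency=global_efficiency(g),
        clustering_coefficient=c_mean,
        characteristic_path_length=characteristic_path_length(g),
        small_world_sigma=small_world_sigma(g, n_refs=n_refs, seed=seed),
        sparsity=g.sparsity,
        group=g.group,
    )


def detect_hubs(nm: NodalMetrics) -> HubSet:
    """Hub rule: regions whose BC strictly exceeds 2x the mean BC over all regions."""
    if nm.bc.size == 0:
        raise ValueError("empty nodal metrics")
    thr = 2.0 * float(nm.bc.mean())
    ids = [rid for rid, v in zip(nm.region_ids, nm.bc) if v > thr]
    return HubSet(region_ids=ids, threshold=thr, group=nm.group)


def hub_bc_across_groups(hubs: HubSet, nodal_by_group: dict[str, NodalMetrics]) -> dict[str, dict[int, float]]:
    """BC values of one group's hub regions looked up in every group, by region id."""
    out: dict[str, dict[int, float]] = {}
    for grp, nm in nodal_by_group.items():
        index = {rid: k for k, rid in enumerate(nm.region_ids)}
        out[grp] = {rid: float(nm.bc[index[rid]]) for rid in hubs.region_ids}
    return out
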