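"""Independent brute-force graph oracles for tiny graphs.

Pure-Python exhaustive enumeration (Floyd-Warshall distances, triangle
loops, shortest-path listing by pruned DFS).  Deliberately shares no code
with the package or networkx so it can serve as an oracle.
"""

from __future__ import annotations

import itertools
import math


def bf_distances(adj) -> list[list[float]]:
    n = len(adj)
    d = [[0 if i == j else (1 if adj[i][j] else math.inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def bf_global_efficiency(adj) -> float:
    n = len(adj)
    d = bf_distances(adj)
    total = sum(1.0 / d[i][j] for i in range(n) for j in range(n) if i != j and math.isfinite(d[i][j]))
    return total / (n * (n - 1))


def bf_clustering(adj) -> tuple[list[float], float]:
    n = len(adj)
    nodal = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            nodal.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a][b])
        nodal.append(2.0 * links / (k * (k - 1)))
    return nodal, sum(nodal) / n


def bf_path_length(adj) -> float:
    """Mean distance over ordered pairs within the largest connected component."""
    n = len(adj)
    d = bf_distances(adj)
    comps: list[set[int]] = []
    unseen = set(range(n))
    while unseen:
        s = unseen.pop()
        comp = {s} | {j for j in range(n) if math.isfinite(d[s][j])}
        unseen -= comp
        comps.append(comp)
    giant = max(comps, key=len)
    pairs = [(i, j) for i in giant for j in giant if i != j]
    if not pairs:
        raise ValueError("no connected pairs")
    return sum(d[i][j] for i, j in pairs) / len(pairs)


def _shortest_paths(adj, d, s, t) -> list[list[int]]:
    """All shortest s->t paths, by DFS pruned with exact distances."""
    if not math.isfinite(d[s][t]) or s == t:
        return []
    n = len(adj)
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        budget = d[s][t] - (len(path) - 1)
        for w in range(n):
            if adj[u][w] and w not in path and d[w][t] <= budget - 1:
                path.append(w)
                extend(path)
                path.pop()

    extend([s])
    return paths


def bf_betweenness(adj) -> list[float]:
    """Unnormalized betweenness over unordered pairs, fractional path counts."""
    n = len(adj)
    d = bf_distances(adj)
    bc = [0.0] * n
    for s, t in itertools.combinations(range(n), 2):
        paths = _shortest_paths(adj, d, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / sigma
    return bc
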