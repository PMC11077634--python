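"""Group comparison of CBF correlation networks.

Three inference procedures operate on the per-group regional CBF tables and
the networks derived from them:

* permutation tests for global graph metrics (and per-region betweenness),
  re-deriving each pseudo-group's correlation network within every
  permutation, as required for group-level covariance networks where each
  group yields a single graph;
* a Fisher-z statistic for the difference between two groups' correlation
  coefficients on each edge, with Benjamini-Hochberg FDR over the tested
  family;
* per-region Welch two-sample t-tests on mean CBF with BH FDR.

All p-values are two-sided.  Permutation p-values use the add-one estimator
(1 + #{|null| >= |observed|}) / (1 + n_perm), so a reported p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .metrics import betweenness_centrality, characteristic_path_length, clustering_coefficient, global_efficiency
from .network import BinaryGraph, CorrelationNetwork, SparsityGrid, normalize_regional_cbf, pearson_network, threshold_by_sparsity
from .parcellate import RegionalCBFMatrix

__all__ = [
    "PermutationResult",
    "NodalPermutationResult",
    "EdgeComparisonResult",
    "RegionalTestResult",
    "GLOBAL_METRICS",
    "permutation_test_global",
    "permutation_test_nodal",
    "edge_z_comparison",
    "bh_fdr",
    "regional_ttests",
]


@dataclass
class PermutationResult:
    metric_name: str
    sparsity: float
    observed_difference: float
    null_distribution: np.ndarray
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class NodalPermutationResult:
    """Per-region betweenness permutation test at one sparsity."""

    region_ids: list[int]
    sparsity: float
    observed_difference: np.ndarray  # group A - group B, per region
    p_values: np.ndarray
    n_permutations: int
    seed: int
    null_distribution: np.ndarray | None = None  # n_perm x regions


@dataclass
class EdgeComparisonResult:
    edges: list[tuple[int, int]]
    z_stat: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    surviving: list[tuple[int, int]] = field(default_factory=list)
    direction: dict[tuple[int, int], str] = field(default_factory=dict)
    alpha: float = 0.001


@dataclass
class RegionalTestResult:
    region_ids: list[int]
    t_stat: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05
    excluded_regions: list[int] = field(default_factory=list)


def _metric_value(name: str, g: BinaryGraph) -> float:
    if name == "global_efficiency":
        return global_efficiency(g)
    if name == "clustering_coefficient":
        return clustering_coefficient(g)[1]
    if name == "characteristic_path_length":
        return characteristic_path_length(g)
    raise ValueError(f"unknown metric {name!r}")


GLOBAL_METRICS = ("global_efficiency", "clustering_coefficient", "characteristic_path_length")


def _group_graph(values: np.ndarray, sparsity: float, normalize: str) -> BinaryGraph:
    mat = RegionalCBFMatrix(
        values=values,
        subject_ids=[f"s{i}" for i in range(values.shape[0])],
        region_ids=list(range(1, values.shape[1] + 1)),
        group="",
    )
    mat = normalize_regional_cbf(mat, mode=normalize)
    net = pearson_network(mat, min_subjects=3)
    return threshold_by_sparsity(net, sparsity)


def _check_compatible(matA: RegionalCBFMatrix, matB: RegionalCBFMatrix) -> None:
    if matA.region_ids != matB.region_ids:
        raise ValueError("group matrices have different region ids")


def permutation_test_global(
    matA: RegionalCBFMatrix,
    matB: RegionalCBFMatrix,
    metric: str,
    grid: SparsityGrid | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    normalize: str = "global-mean",
    min_perm: int = 100,
) -> list[PermutationResult]:
    """Permutation test of a global metric difference (A - B) per sparsity.

    Subjects are pooled and reassigned to pseudo-groups of the original
    sizes; each pseudo-group's correlation network is rebuilt and
    thresholded before the metric is evaluated, mirroring how the observed
    group networks were obtained.
    """
    _check_compatible(matA, matB)
    if metric not in GLOBAL_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if n_perm < min_perm:
        raise ValueError(f"need at least {min_perm} permutations, got {n_perm}")
    grid = grid or SparsityGrid()
    nA = matA.n_subjects
    pooled = np.vstack([matA.values, matB.values])
    n_total = pooled.shape[0]
    rng = np.random.default_rng(seed)

    observed = {}
    for s in grid:
        ga = _group_graph(matA.values, s, normalize)
        gb = _group_graph(matB.values, s, normalize)
        observed[s] = _metric_value(metric, ga) - _metric_value(metric, gb)

    nulls = {s: np.empty(n_perm) for s in grid}
    for k in range(n_perm):
        perm = rng.permutation(n_total)
        va = pooled[perm[:nA]]
        vb = pooled[perm[nA:]]
        for s in grid:
            ga = _group_graph(va, s, normalize)
            gb = _group_graph(vb, s, normalize)
            nulls[s][k] = _metric_value(metric, ga) - _metric_value(metric, gb)

    out = []
    for s in grid:
        null = nulls[s]
        p = (1.0 + np.sum(np.abs(null) >= abs(observed[s]))) / (1.0 + n_perm)
        out.append(
            PermutationResult(
                metric_name=metric,
                sparsity=s,
                observed_difference=float(observed[s]),
                null_distribution=null,
                p_value=float(p),
                n_permutations=n_perm,
                seed=seed,
            )
        )
    return out


def permutation_test_nodal(
    matA: RegionalCBFMatrix,
    matB: RegionalCBFMatrix,
    sparsity: float = 0.83,
    n_perm: int = 1000,
    seed: int = 0,
    normalize: str = "global-mean",
    keep_null: bool = False,
) -> NodalPermutationResult:
    """Per-region betweenness permutation test at one sparsity (default 0.83)."""
    _check_compatible(matA, matB)
    nA = matA.n_subjects
    pooled = np.vstack([matA.values, matB.values])
    rng = np.random.default_rng(seed)

    def bc_diff(va: np.ndarray, vb: np.ndarray) -> np.ndarray:
        bca = betweenness_centrality(_group_graph(va, sparsity, normalize)).bc
        bcb = betweenness_centrality(_group_graph(vb, sparsity, normalize)).bc
        return bca - bcb

    obs = bc_diff(matA.values, matB.values)
    null = np.empty((n_perm, obs.size))
    for k in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        null[k] = bc_diff(pooled[perm[:nA]], pooled[perm[nA:]])
    p = (1.0 + np.sum(np.abs(null) >= np.abs(obs)[None, :], axis=0)) / (1.0 + n_perm)
    return NodalPermutationResult(
        region_ids=list(matA.region_ids),
        sparsity=float(sparsity),
        observed_difference=obs,
        p_values=p,
        n_permutations=n_perm,
        seed=seed,
        null_distribution=null if keep_null else None,
    )


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and rejection flags at ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj < alpha


def edge_z_comparison(
    netA: CorrelationNetwork,
    netB: CorrelationNetwork,
    sparsity: float = 0.83,
    alpha: float = 0.001,
    family: str = "union",
) -> EdgeComparisonResult:
    """Fisher-z test of per-edge correlation differences between two groups.

    For each tested edge, Z = (atanh r_A - atanh r_B) / sqrt(1/(n_A-3) +
    1/(n_B-3)) with a two-sided normal p-value; BH FDR runs over the tested
    family, by default the union of edges retained by either group at
    ``sparsity`` (``family="all"`` tests every pair).
    """
    if netA.region_ids != netB.region_ids:
        raise ValueError("networks have different region ids")
    if netA.n_subjects < 4 or netB.n_subjects < 4:
        raise ValueError("Fisher-z comparison needs at least 4 subjects per group")
    R = netA.r.shape[0]
    iu, ju = np.triu_indices(R, k=1)
    if family == "union":
        adjA = threshold_by_sparsity(netA, sparsity).adjacency
        adjB = threshold_by_sparsity(netB, sparsity).adjacency
        tested = (adjA | adjB)[iu, ju]
    elif family == "all":
        tested = np.ones(iu.size, dtype=bool)
    else:
        raise ValueError(f"unknown edge family {family!r}")
    ii, jj = iu[tested], ju[tested]

    def ztrans(r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        clip = np.abs(r) >= 1.0
        if clip.any():
            import warnings

            warnings.warn(f"{int(clip.sum())} correlation(s) at |r|=1 clamped", stacklevel=3)
            r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        return np.arctanh(r)

    se = np.sqrt(1.0 / (netA.n_subjects - 3) + 1.0 / (netB.n_subjects - 3))
    z = (ztrans(netA.r[ii, jj]) - ztrans(netB.r[ii, jj])) / se
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    p_adj, flags = bh_fdr(p_raw, alpha=alpha)

    rids = netA.region_ids
    edges = [(rids[a], rids[b]) for a, b in zip(ii, jj)]
    surviving = [e for e, f in zip(edges, flags) if f]
    direction = {
        e: ("decreased" if zv > 0 else "increased")  # sign of A - B, relative to the second group
        for e, zv, f in zip(edges, z, flags)
        if f
    }
    return EdgeComparisonResult(
        edges=edges, z_stat=z, p_raw=p_raw, p_adjusted=p_adj,
        surviving=surviving, direction=direction, alpha=alpha,
    )


def regional_ttests(
    matA: RegionalCBFMatrix,
    matB: RegionalCBFMatrix,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> RegionalTestResult:
    """Per-region two-sample t-tests (Welch by default) on mean CBF with BH FDR.

    Regions with zero variance in both groups are excluded from the FDR
    family and reported separately.
    """
    _check_compatible(matA, matB)
    if matA.n_subjects < 2 or matB.n_subjects < 2:
        raise ValueError("need at least 2 subjects per group for t-tests")
    a, b = matA.values, matB.values
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    if degenerate.any():
        import warnings

        excluded = [matA.region_ids[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(f"regions with zero variance in both groups excluded from FDR: {excluded}", stacklevel=2)
    else:
        excluded = []
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    keep = ~degenerate
    p_adj = np.full(p.shape, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    if keep.any():
        p_adj[keep], sig[keep] = bh_fdr(p[keep], alpha=alpha)
    return RegionalTestResult(
        region_ids=list(matA.region_ids),
        t_stat=t,
        p_raw=p,
        p_adjusted=p_adj,
        significant=sig,
        alpha=alpha,
        excluded_regions=excluded,
    )
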