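"""Group-level CBF correlation networks and sparsity thresholding.

The network for one diagnostic group is the regions x regions matrix of
Pearson correlations of regional CBF across that group's subjects (this is
cross-subject structural covariance, not within-subject time-series
connectivity).  Networks are binarized over a sparsity grid; "sparsity" here
is the fraction of possible edges REMOVED, so the retained density is
1 - sparsity (17-35% over the default 0.65..0.83 grid).  The opposite
reading (sparsity = fraction kept) is available via ``density=sparsity``
should a different convention be needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parcellate import RegionalCBFMatrix

__all__ = [
    "CorrelationNetwork",
    "BinaryGraph",
    "SparsityGrid",
    "normalize_regional_cbf",
    "pearson_network",
    "threshold_by_sparsity",
]


@dataclass
class CorrelationNetwork:
    """Symmetric Pearson correlation matrix for one group, unit diagonal."""

    r: np.ndarray
    n_subjects: int
    group: str
    region_ids: list[int]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        R = len(self.region_ids)
        if self.r.shape != (R, R):
            raise ValueError("correlation matrix shape does not match region_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass
class BinaryGraph:
    """Undirected binary graph from thresholding one group's network."""

    adjacency: np.ndarray
    sparsity: float
    region_ids: list[int]
    group: str = ""

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if self.adjacency.shape != (len(self.region_ids),) * 2:
            raise ValueError("adjacency shape does not match region_ids")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must have an empty diagonal")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class SparsityGrid:
    """Ordered sparsity fractions; default 0.65 to 0.83 in steps of 0.02."""

    values: list[float] = field(default_factory=lambda: [round(0.65 + 0.02 * k, 2) for k in range(10)])

    def __post_init__(self) -> None:
        v = list(self.values)
        if not v or any(not (0 <= s < 1) for s in v):
            raise ValueError("sparsity values must lie in [0, 1)")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("sparsity values must be strictly increasing")
        self.values = v

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


def normalize_regional_cbf(matrix: RegionalCBFMatrix, mode: str = "global-mean") -> RegionalCBFMatrix:
    """Remove between-subject global perfusion offsets before correlation.

    ``global-mean`` divides each subject's row by its own mean so that
    correlations reflect the regional pattern rather than global CBF level;
    ``none`` is the identity.
    """
    if mode == "none":
        return matrix
    if mode != "global-mean":
        raise ValueError(f"unknown normalization mode {mode!r}")
    row_means = matrix.values.mean(axis=1)
    zero = np.flatnonzero(np.abs(row_means) < 1e-300)
    if zero.size:
        bad = [matrix.subject_ids[i] for i in zero]
        raise ValueError(f"zero global mean for subjects: {bad}")
    return RegionalCBFMatrix(
        values=matrix.values / row_means[:, None],
        subject_ids=list(matrix.subject_ids),
        region_ids=list(matrix.region_ids),
        group=matrix.group,
    )


def pearson_network(matrix: RegionalCBFMatrix, min_subjects: int = 4) -> CorrelationNetwork:
    """Pearson correlation of every pair of regions across subjects.

    ``min_subjects`` defaults to 4, the smallest group for which the
    downstream Fisher-z variance 1/(n-3) is defined; permutation procedures
    relax it to 3 (the minimum for a non-degenerate sample correlation).
    """
    n, R = matrix.values.shape
    if n < min_subjects:
        raise ValueError(f"need at least {min_subjects} subjects for a correlation network, got {n}")
    if not np.isfinite(matrix.values).all():
        raise ValueError("matrix contains missing values; drop incomplete regions first")
    sd = matrix.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance regions: {[matrix.region_ids[i] for i in dead]}")
    r = np.corrcoef(matrix.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationNetwork(r=r, n_subjects=n, group=matrix.group, region_ids=list(matrix.region_ids))


def threshold_by_sparsity(
    net: CorrelationNetwork,
    sparsity: float,
    use_absolute: bool = False,
) -> BinaryGraph:
    """Binarize a correlation network keeping the strongest edges.

    Retains exactly ``round((1 - sparsity) * R(R-1)/2)`` edges with the
    largest coefficients (signed r by default, |r| if ``use_absolute``).
    Ties at the cutoff break by ascending (i, j) index order, so the result
    is bit-reproducible.
    """
    if not (0 <= sparsity < 1):
        raise ValueError(f"sparsity must lie in [0, 1), got {sparsity}")
    R = net.r.shape[0]
    iu, ju = np.triu_indices(R, k=1)
    vals = net.r[iu, ju]
    if use_absolute:
        vals = np.abs(vals)
    m = vals.size
    keep = int(round((1.0 - sparsity) * m))
    adj = np.zeros((R, R), dtype=bool)
    if keep > 0:
        # stable sort on -value preserves lexicographic (i, j) order among ties
        order = np.argsort(-vals, kind="stable")[:keep]
        adj[iu[order], ju[order]] = True
        adj |= adj.T
    return BinaryGraph(adjacency=adj, sparsity=float(sparsity), region_ids=list(net.region_ids), group=net.group)
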