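"""Synthetic multi-group regional CBF data with known ground truth.

The generator emulates the statistical structure that group-level CBF
covariance analysis assumes: three diagnostic groups (sizes 53/43/30,
matching a CN/MCI/AD design), 246 gray-matter regions, block-modular
inter-regional correlation (8 anatomically named blocks, within-block
r ~ 0.6, between-block r ~ 0.1) whose thresholded networks are small-world,
plus two planted disease effects with recorded truth:

* regional hypoperfusion — multiplicative mean reductions in a designated
  temporal/parahippocampal block (10% in "MCI") and larger reductions (20%,
  extending into the hippocampus block) in "AD";
* edge decoupling — a designated set of strongly coupled region pairs
  touching the hippocampus and precuneus blocks (population r = 0.95 in
  CN/MCI, the scale seen for homotopic pairs in structural covariance)
  whose coupling is ablated to the background level in "AD".

Rows are drawn from a multivariate normal with the block covariance
(projected to the positive-semidefinite cone by eigenvalue clipping after
planting) and truncated at zero.  Regional standard deviations default to
15% of the regional mean, a plausible between-subject variability for
resting gray-matter CBF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .parcellate import LabelVolume, RegionalCBFMatrix
from .quantify import AcquisitionParams, CBFMap, VoxelVolume

__all__ = [
    "GroupModel",
    "SyntheticTruth",
    "BLOCK_NAMES",
    "make_default_models",
    "sample_regional_cbf",
    "synthesize_asl_volumes",
    "make_wedge_labels",
    "cbf_map_from_regional",
]

BLOCK_NAMES = [
    "frontal",
    "temporal_parahippocampal",
    "hippocampus",
    "precuneus",
    "parietal",
    "occipital",
    "cingulate",
    "subcortical",
]


@dataclass
class GroupModel:
    """Generative model for one diagnostic group."""

    group_name: str
    n_subjects: int
    regional_means: np.ndarray
    covariance: np.ndarray
    planted_hypoperfused_regions: dict[int, float] = field(default_factory=dict)
    planted_decoupled_edges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regional_means = np.asarray(self.regional_means, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        R = self.regional_means.size
        if self.covariance.shape != (R, R):
            raise ValueError("covariance shape does not match means")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.any(self.regional_means <= 0):
            raise ValueError("regional means must be positive")
        ids = set(range(1, R + 1))
        if not set(self.planted_hypoperfused_regions) <= ids:
            raise ValueError("planted regions outside region id range")
        for i, j in self.planted_decoupled_edges:
            if i not in ids or j not in ids or i == j:
                raise ValueError(f"invalid planted edge ({i}, {j})")

    @property
    def n_regions(self) -> int:
        return self.regional_means.size


@dataclass
class SyntheticTruth:
    """The three group models, the seed, and the expected effect directions."""

    models: dict[str, GroupModel]
    seed: int
    block_of_region: dict[int, str]
    expected_directions: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "block_of_region": {str(k): v for k, v in self.block_of_region.items()},
            "expected_directions": self.expected_directions,
            "models": {
                name: {
                    "group_name": m.group_name,
                    "n_subjects": m.n_subjects,
                    "regional_means": m.regional_means.tolist(),
                    "covariance": m.covariance.tolist(),
                    "planted_hypoperfused_regions": {str(k): v for k, v in m.planted_hypoperfused_regions.items()},
                    "planted_decoupled_edges": [list(e) for e in m.planted_decoupled_edges],
                }
                for name, m in self.models.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        models = {
            name: GroupModel(
                group_name=d["group_name"],
                n_subjects=d["n_subjects"],
                regional_means=np.array(d["regional_means"]),
                covariance=np.array(d["covariance"]),
                planted_hypoperfused_regions={int(k): v for k, v in d["planted_hypoperfused_regions"].items()},
                planted_decoupled_edges=[tuple(e) for e in d["planted_decoupled_edges"]],
            )
            for name, d in payload["models"].items()
        }
        return cls(
            models=models,
            seed=payload["seed"],
            block_of_region={int(k): v for k, v in payload["block_of_region"].items()},
            expected_directions=payload["expected_directions"],
        )


def _clip_psd(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone and restore a unit diagonal."""
    w, v = np.linalg.eigh(corr)
    w = np.maximum(w, floor)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    return (out + out.T) / 2.0


def make_default_models(
    R: int = 246,
    seed: int = 1,
    n_subjects: tuple[int, int, int] = (53, 43, 30),
    group_names: tuple[str, str, str] = ("CN", "MCI", "AD"),
    within_r: float = 0.6,
    between_r: float = 0.1,
    planted_edge_r: float = 0.95,
    mci_reduction: float = 0.10,
    ad_reduction: float = 0.20,
    cv: float = 0.15,
    n_decoupled: int = 12,
) -> SyntheticTruth:
    """Build the default three-group generative models.

    Regional means are drawn once (uniform 40-80 ml/100 g/min) and shared
    across groups before the planted reductions are applied, so every
    between-group mean difference is a planted effect.
    """
    if R < 20:
        raise ValueError("need at least 20 regions")
    for frac, name in ((mci_reduction, "mci_reduction"), (ad_reduction, "ad_reduction")):
        if not (0 <= frac < 1):
            raise ValueError(f"{name} must lie in [0, 1), got {frac}")
    if not (0 <= planted_edge_r < 1):
        raise ValueError("planted_edge_r must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    n_blocks = len(BLOCK_NAMES)
    blocks = np.array_split(np.arange(R), n_blocks)
    block_of_region = {int(r) + 1: BLOCK_NAMES[b] for b, idx in enumerate(blocks) for r in idx}
    block_index = {name: idx for name, idx in zip(BLOCK_NAMES, blocks)}

    means = rng.uniform(40.0, 80.0, size=R)

    corr = np.full((R, R), between_r)
    for idx in blocks:
        corr[np.ix_(idx, idx)] = within_r
    np.fill_diagonal(corr, 1.0)

    # Planted strongly coupled edges touching the hippocampus/precuneus
    # blocks.  The construction mirrors an explicit factor model so both
    # matrices are PSD exactly, with no projection step that would smear the
    # planted difference over other entries: every region loads sqrt(b) on a
    # global factor (b = between_r) and non-planted regions load
    # sqrt(within_r - between_r) on their block factor; each planted pair
    # shares a private factor of weight planted_edge_r - between_r instead
    # of a block loading.  Removing the pair factor in "AD" returns the pair
    # to the background correlation and changes nothing else.
    hip = block_index["hippocampus"]
    pre = block_index["precuneus"]
    if planted_edge_r <= between_r:
        raise ValueError("planted_edge_r must exceed between_r")
    # allocation shrinks gracefully when the blocks are small (few regions)
    n_within_pre = min(max(n_decoupled // 2, 1) if n_decoupled else 0, len(pre) // 2)
    n_within_hip = min((n_decoupled - n_within_pre) // 2, len(hip) // 2)
    n_cross = min(
        n_decoupled - n_within_pre - n_within_hip,
        len(pre) - 2 * n_within_pre,
        len(hip) - 2 * n_within_hip,
    )
    n_cross = max(n_cross, 0)
    pre_pool = list(rng.permutation(pre))
    hip_pool = list(rng.permutation(hip))
    decoupled_idx: list[tuple[int, int]] = []
    for _ in range(n_within_pre):
        a, b = int(pre_pool.pop()), int(pre_pool.pop())
        decoupled_idx.append((min(a, b), max(a, b)))
    for _ in range(n_within_hip):
        a, b = int(hip_pool.pop()), int(hip_pool.pop())
        decoupled_idx.append((min(a, b), max(a, b)))
    for _ in range(n_cross):
        a, b = int(hip_pool.pop()), int(pre_pool.pop())
        decoupled_idx.append((min(a, b), max(a, b)))
    decoupled_edges = [(i + 1, j + 1) for i, j in decoupled_idx]
    planted_members = sorted({k for pair in decoupled_idx for k in pair})

    corr_healthy = corr.copy()
    for k in planted_members:  # pair members couple to the rest only globally
        corr_healthy[k, :] = corr_healthy[:, k] = between_r
        corr_healthy[k, k] = 1.0
    corr_ad = corr_healthy.copy()
    for i, j in decoupled_idx:
        corr_healthy[i, j] = corr_healthy[j, i] = planted_edge_r
    corr_healthy = _clip_psd(corr_healthy)
    corr_ad = _clip_psd(corr_ad)

    tph = block_index["temporal_parahippocampal"]
    mci_regions = {int(r) + 1: mci_reduction for r in tph}
    ad_regions = {int(r) + 1: ad_reduction for r in np.concatenate([tph, hip])}

    def build(name: str, n: int, corr_mat: np.ndarray, reductions: dict[int, float], edges: list[tuple[int, int]]) -> GroupModel:
        mu = means.copy()
        for rid, frac in reductions.items():
            mu[rid - 1] *= 1.0 - frac
        sd = cv * mu
        cov = corr_mat * np.outer(sd, sd)
        return GroupModel(
            group_name=name,
            n_subjects=n,
            regional_means=mu,
            covariance=cov,
            planted_hypoperfused_regions=dict(reductions),
            planted_decoupled_edges=list(edges),
        )

    cn_name, mci_name, ad_name = group_names
    models = {
        cn_name: build(cn_name, n_subjects[0], corr_healthy, {}, []),
        mci_name: build(mci_name, n_subjects[1], corr_healthy, mci_regions, []),
        ad_name: build(ad_name, n_subjects[2], corr_ad, ad_regions, decoupled_edges),
    }
    return SyntheticTruth(
        models=models,
        seed=seed,
        block_of_region=block_of_region,
        expected_directions={
            "hypoperfusion": "decreased regional CBF relative to CN",
            "decoupling": "correlation ablated toward 0 in AD",
        },
    )


def sample_regional_cbf(model: GroupModel, seed: int = 0, truncate: bool = True) -> RegionalCBFMatrix:
    """Draw one subjects x regions matrix from a group model (reproducible per seed)."""
    rng = np.random.default_rng(seed)
    R = model.n_regions
    if np.allclose(model.covariance, 0):
        values = np.tile(model.regional_means, (model.n_subjects, 1))
    else:
        L = np.linalg.cholesky(model.covariance + 1e-10 * np.eye(R))
        z = rng.standard_normal((model.n_subjects, R))
        values = model.regional_means[None, :] + z @ L.T
    if truncate:
        values = np.maximum(values, 0.0)
    return RegionalCBFMatrix(
        values=values,
        subject_ids=[f"{model.group_name}_{i:03d}" for i in range(model.n_subjects)],
        region_ids=list(range(1, R + 1)),
        group=model.group_name,
    )


def synthesize_asl_volumes(
    cbf_truth: CBFMap,
    params: AcquisitionParams | None = None,
    pd_level: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[VoxelVolume, VoxelVolume, VoxelVolume]:
    """Invert the quantification model to produce control/label/PD volumes.

    The perfusion-weighted difference is solved from the single-compartment
    equation for each voxel's true CBF at the given PD level; independent
    Gaussian noise of ``noise_sd`` is added to every volume.  At zero noise,
    quantifying the synthesized volumes recovers ``cbf_truth`` exactly.
    """
    if pd_level <= 0:
        raise ValueError("pd_level must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    params = params or (cbf_truth.params if cbf_truth.params is not None else AcquisitionParams())
    rng = np.random.default_rng(seed)
    truth = np.nan_to_num(cbf_truth.data, nan=0.0)
    diff = truth * pd_level / params.scale
    base = np.full(truth.shape, pd_level)
    mask = cbf_truth.valid_mask

    def noisy(arr: np.ndarray) -> np.ndarray:
        if noise_sd == 0:
            return arr.copy()
        return arr + rng.normal(0.0, noise_sd, size=arr.shape)

    affine = cbf_truth.affine
    control = VoxelVolume(data=noisy(base + diff), affine=affine.copy(), mask=mask.copy())
    label = VoxelVolume(data=noisy(base), affine=affine.copy(), mask=mask.copy())
    pd = VoxelVolume(data=noisy(np.full(truth.shape, pd_level)), affine=affine.copy(), mask=mask.copy())
    return control, label, pd


def make_wedge_labels(shape: tuple[int, int, int] = (16, 16, 8), n_regions: int = 20) -> LabelVolume:
    """A synthetic label volume of ``n_regions`` angular sectors on a small grid.

    Voxels are ordered by in-plane angle around the grid center (radius and
    slice break ties) and split into equally sized contiguous sectors, so
    every region is nonempty.  This exists to exercise quantification and
    parcellation end to end, not to resemble anatomy.
    """
    if n_regions < 1 or n_regions > int(np.prod(shape)):
        raise ValueError("n_regions must be between 1 and the voxel count")
    xx, yy, zz = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    cx, cy = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    theta = np.arctan2(yy - cy, xx - cx).ravel()
    radius = np.hypot(xx - cx, yy - cy).ravel()
    order = np.lexsort((zz.ravel(), radius, theta))
    labels = np.zeros(int(np.prod(shape)), dtype=np.int64)
    for k, chunk in enumerate(np.array_split(order, n_regions)):
        labels[chunk] = k + 1
    return LabelVolume(data=labels.reshape(shape))


def cbf_map_from_regional(
    regional_values: np.ndarray,
    labels: LabelVolume,
    params: AcquisitionParams | None = None,
    affine: np.ndarray | None = None,
) -> CBFMap:
    """Paint regional CBF values onto a label volume to form a voxelwise truth map."""
    regional_values = np.asarray(regional_values, dtype=float)
    if regional_values.size != len(labels.region_ids):
        raise ValueError("one value per atlas region required")
    data = np.full(labels.data.shape, np.nan)
    for val, rid in zip(regional_values, labels.region_ids):
        data[labels.data == rid] = val
    return CBFMap(
        data=data,
        affine=np.eye(4) if affine is None else affine,
        params=params or AcquisitionParams(),
    )
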