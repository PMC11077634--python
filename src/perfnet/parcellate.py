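"""Atlas parcellation of CBF maps and assembly of subjects x regions tables.

A label volume following the 246-region whole-brain atlas convention (cortex
plus subcortex, integer labels, 0 = background) reduces each subject's CBF
map to a vector of regional means over valid voxels.  Per-group tables are
the interchange object for all network construction and statistics:
rows are subjects, columns are regions in ascending atlas-id order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .quantify import CBFMap

__all__ = [
    "LabelVolume",
    "RegionalCBFMatrix",
    "extract_regional_means",
    "assemble_group_matrices",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

N_ATLAS_REGIONS = 246


@dataclass
class LabelVolume:
    """Integer atlas labels on the CBF grid; 0 is background."""

    data: np.ndarray
    region_ids: list[int] = field(default_factory=list)
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.array_equal(rounded, self.data):
                raise ValueError("label volume must contain integers")
            self.data = rounded.astype(np.int64)
        if self.data.min() < 0:
            raise ValueError("label volume must be non-negative")
        if not self.region_ids:
            ids = np.unique(self.data)
            self.region_ids = [int(i) for i in ids if i > 0]
        if not self.region_ids:
            raise ValueError("label volume contains no positive labels")
        if sorted(set(self.region_ids)) != self.region_ids:
            raise ValueError("region_ids must be sorted ascending without duplicates")
        if self.region_names is not None and len(self.region_names) != len(self.region_ids):
            raise ValueError("region_names must parallel region_ids")

    @classmethod
    def from_nifti(cls, path: str | Path, lut: str | Path | None = None) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        names = None
        ids: list[int] = []
        if lut is not None:
            table = pd.read_csv(lut, sep="\t", header=None, names=["id", "name"])
            table = table.sort_values("id")
            ids = [int(i) for i in table["id"]]
            names = [str(n) for n in table["name"]]
        return cls(data=data, region_ids=ids, region_names=names)


@dataclass
class RegionalCBFMatrix:
    """Subjects x regions table of mean regional CBF (ml/100 g/min) for one group."""

    values: np.ndarray
    subject_ids: list[str]
    region_ids: list[int]
    group: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D subjects x regions array")
        if self.values.shape != (len(self.subject_ids), len(self.region_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.region_ids)} regions"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[str(r) for r in self.region_ids])
        df.insert(0, "group", self.group)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def extract_regional_means(cbf: CBFMap, labels: LabelVolume) -> np.ndarray:
    """Mean CBF over valid voxels for each atlas region.

    Returns a vector aligned with ``labels.region_ids``; regions with no
    valid voxel are NaN.
    """
    if labels.data.shape != cbf.data.shape:
        raise ValueError(
            f"label volume shape {labels.data.shape} does not match CBF shape {cbf.data.shape}"
        )
    lab = labels.data.ravel()
    val = cbf.data.ravel()
    ok = np.isfinite(val) & (lab > 0)
    n = int(lab.max()) + 1
    sums = np.bincount(lab[ok], weights=val[ok], minlength=n)
    counts = np.bincount(lab[ok], minlength=n)
    means = np.full(len(labels.region_ids), np.nan)
    for k, rid in enumerate(labels.region_ids):
        if rid < n and counts[rid] > 0:
            means[k] = sums[rid] / counts[rid]
    return means


def assemble_group_matrices(
    per_subject_vectors: list[tuple[str, str, np.ndarray]],
    region_ids: list[int] | None = None,
) -> dict[str, RegionalCBFMatrix]:
    """Stack (subject_id, group, regional-mean vector) triples into per-group matrices.

    Row order within each group follows input order.  All vectors must share
    one length (one atlas ordering); offenders are reported by subject id.
    """
    if not per_subject_vectors:
        raise ValueError("no subjects supplied")
    length = len(per_subject_vectors[0][2])
    bad = [sid for sid, _, vec in per_subject_vectors if len(vec) != length]
    if bad:
        raise ValueError(f"inconsistent regional vector lengths for subjects: {bad}")
    if region_ids is None:
        region_ids = list(range(1, length + 1))
    groups: dict[str, list[tuple[str, np.ndarray]]] = {}
    for sid, grp, vec in per_subject_vectors:
        groups.setdefault(grp, []).append((sid, np.asarray(vec, dtype=float)))
    return {
        grp: RegionalCBFMatrix(
            values=np.vstack([v for _, v in rows]),
            subject_ids=[s for s, _ in rows],
            region_ids=list(region_ids),
            group=grp,
        )
        for grp, rows in groups.items()
    }


def write_matrix_tsv(matrices: dict[str, RegionalCBFMatrix] | RegionalCBFMatrix, path: str | Path) -> None:
    """Write one or several group matrices to the interchange TSV.

    Columns: subject_id, group, then one column per region id.
    """
    if isinstance(matrices, RegionalCBFMatrix):
        matrices = {matrices.group: matrices}
    frames = [m.to_frame() for m in matrices.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> dict[str, RegionalCBFMatrix]:
    """Read the interchange TSV back into per-group matrices."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "subject_id" or df.columns[1] != "group":
        raise ValueError("matrix TSV must start with subject_id and group columns")
    region_ids = [int(c) for c in df.columns[2:]]
    out: dict[str, RegionalCBFMatrix] = {}
    for grp, sub in df.groupby("group", sort=False):
        out[str(grp)] = RegionalCBFMatrix(
            values=sub.iloc[:, 2:].to_numpy(dtype=float),
            subject_ids=[str(s) for s in sub["subject_id"]],
            region_ids=region_ids,
            group=str(grp),
        )
    return out
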