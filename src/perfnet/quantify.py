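"""Voxelwise CBF quantification from pseudo-continuous ASL.

Implements the single-compartment quantification model for 3D PCASL with a
proton-density-weighted (PDWI) calibration image:

    CBF = 6000 * lam * (SI_control - SI_label) * exp(PLD / T1_blood)
          -----------------------------------------------------------
          2 * alpha * T1_blood * SI_PD * (1 - exp(-tau / T1_blood))

in ml/100 g/min.  The factor 6000 converts ml/g/s to ml/100 g/min and is a
fixed unit conversion, not a tunable parameter.  Voxels with a non-positive
PD signal, or outside the brain mask, are flagged with NaN and excluded from
all downstream statistics (regional means skip them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionParams",
    "VoxelVolume",
    "CBFMap",
    "compute_cbf_map",
    "apply_mask",
    "load_volume",
    "save_cbf_map",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Constants of the PCASL quantification equation.

    Parameters
    ----------
    t1_blood : float
        Longitudinal relaxation time of arterial blood, seconds.
    tau : float
        Label duration, seconds.
    lam : float
        Brain/blood partition coefficient, ml/g.
    pld : float
        Post-labeling delay, seconds.
    alpha : float
        Labeling efficiency, dimensionless fraction in (0, 1].
    """

    t1_blood: float = 1.4
    tau: float = 1.5
    lam: float = 0.9
    pld: float = 2.025
    alpha: float = 0.8

    def __post_init__(self) -> None:
        for name in ("t1_blood", "tau", "lam", "pld", "alpha"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"acquisition parameter {name!r} must be strictly positive, got {v}")
        if self.alpha > 1:
            raise ValueError(f"labeling efficiency alpha must be in (0, 1], got {self.alpha}")

    @property
    def scale(self) -> float:
        """Scalar multiplying (SI_control - SI_label)/SI_PD in the model."""
        return (
            6000.0
            * self.lam
            * math.exp(self.pld / self.t1_blood)
            / (2.0 * self.alpha * self.t1_blood * (1.0 - math.exp(-self.tau / self.t1_blood)))
        )


@dataclass
class VoxelVolume:
    """A 3D intensity volume with spatial metadata and an optional validity mask."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"volume data must be 3D (or a 4D pair series), got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid_shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match volume shape {self.grid_shape}"
                )

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]

    def valid_count(self) -> int:
        if self.mask is None:
            return int(np.prod(self.grid_shape))
        return int(self.mask.sum())


@dataclass
class CBFMap:
    """Voxel grid of cerebral blood flow in ml/100 g/min.

    Invalid voxels (outside the mask or with SI_PD <= 0) carry NaN.
    """

    data: np.ndarray
    affine: np.ndarray
    params: AcquisitionParams

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data)


def _check_geometry(name: str, vol: VoxelVolume, ref: VoxelVolume) -> None:
    if vol.grid_shape != ref.grid_shape:
        raise ValueError(
            f"{name} volume shape {vol.grid_shape} does not match control shape {ref.grid_shape}"
        )
    if not np.allclose(vol.affine, ref.affine, atol=1e-6):
        raise ValueError(f"{name} volume affine does not match control affine")


def _collapse_pairs(data: np.ndarray) -> np.ndarray:
    """Average a 4D series over its last axis; pass 3D volumes through."""
    if data.ndim == 4:
        return data.mean(axis=3)
    return data


def compute_cbf_map(
    control: VoxelVolume,
    label: VoxelVolume,
    pd: VoxelVolume,
    params: AcquisitionParams | None = None,
) -> CBFMap:
    """Quantify CBF voxelwise from control/label ASL and a PD calibration image.

    If control/label are 4D series of repeated pairs, the perfusion-weighted
    difference is averaged across pairs before scaling.  Output is linear in
    (SI_control - SI_label); negative CBF values are retained.
    """
    params = params or AcquisitionParams()
    _check_geometry("label", label, control)
    _check_geometry("pd", pd, control)
    if control.data.shape != label.data.shape:
        raise ValueError("control and label series have different numbers of pairs")

    diff = _collapse_pairs(control.data - label.data)
    pd_data = _collapse_pairs(pd.data)

    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = params.scale * diff / pd_data
    invalid = pd_data <= 0
    for vol in (control, label, pd):
        if vol.mask is not None:
            invalid |= ~vol.mask
    cbf = np.where(invalid, np.nan, cbf)
    return CBFMap(data=cbf, affine=control.affine.copy(), params=params)


def apply_mask(volume: VoxelVolume, mask: np.ndarray) -> VoxelVolume:
    """Restrict a volume's valid voxels to ``mask`` (intersected with any existing mask)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.grid_shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume shape {volume.grid_shape}")
    combined = mask if volume.mask is None else (mask & volume.mask)
    return VoxelVolume(data=volume.data.copy(), affine=volume.affine.copy(), mask=combined)


def load_volume(path: str | Path, mask: np.ndarray | None = None) -> VoxelVolume:
    """Read a NIfTI-1 volume from disk."""
    img = nib.load(str(path))
    return VoxelVolume(data=np.asanyarray(img.dataobj, dtype=float), affine=img.affine, mask=mask)


def save_cbf_map(cbf: CBFMap, path: str | Path) -> None:
    """Write a CBF map as NIfTI-1, preserving the source affine."""
    nib.save(nib.Nifti1Image(cbf.data.astype(np.float32), cbf.affine), str(path))
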