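"""Whole-organ volume and fat-fraction quantification from label masks.

Volumes are exact: the voxel count of a label times the voxel volume from
the image geometry (mm^3, reported in cm^3); no resampling or smoothing is
involved, so volumes are additive over disjoint masks.  Liver fat
percentage is the unweighted arithmetic mean of the fat-fraction map over
the liver mask.  Masks can be confined to an axial slice range, mirroring
the anatomical confinement of adipose-tissue masks between the ninth
thoracic vertebra and the femoral head.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "LABEL_CODES",
    "VoxelGeometry",
    "LabelVolume",
    "FatFractionVolume",
    "mask_volume",
    "mean_fat_fraction",
    "axial_confine",
    "load_label_volume",
    "load_fat_fraction",
    "save_nifti",
]

#: Declared label code set.
LABEL_CODES = {"background": 0, "liver": 1, "sat": 2, "vat": 3}

MM3_PER_CM3 = 1000.0


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel size (mm along x, y, z) and grid shape in voxels."""

    voxel_size: tuple
    shape: tuple

    def __post_init__(self):
        if len(self.voxel_size) != 3 or len(self.shape) != 3:
            raise ValueError("geometry is 3-D")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.voxel_size
        return float(sx * sy * sz)

    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size) + [1.0])


@dataclass
class LabelVolume:
    """3-D integer label grid with its voxel geometry."""

    data: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label grid must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label grid must be integer")
        if tuple(self.data.shape) != tuple(self.geometry.shape):
            raise ValueError("grid shape does not match geometry")


@dataclass
class FatFractionVolume:
    """3-D fat-fraction grid in percent; values clipped to [0, 100]."""

    data: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self):
        self.data = np.clip(np.asarray(self.data, dtype=float), 0.0, 100.0)
        if self.data.ndim != 3:
            raise ValueError("fat-fraction grid must be 3-D")
        if tuple(self.data.shape) != tuple(self.geometry.shape):
            raise ValueError("grid shape does not match geometry")


def _label_code(label) -> int:
    code = LABEL_CODES.get(label, label) if isinstance(label, str) else label
    if not isinstance(code, (int, np.integer)):
        raise KeyError(f"unknown label {label!r}")
    return int(code)


def mask_volume(mask: LabelVolume, label) -> float:
    """Volume of one label in cm^3: voxel count x voxel volume, exactly."""
    code = _label_code(label)
    if isinstance(label, str) and label not in LABEL_CODES:
        raise KeyError(f"unknown label {label!r}")
    count = int(np.count_nonzero(mask.data == code))
    return count * mask.geometry.voxel_volume_mm3 / MM3_PER_CM3


def mean_fat_fraction(ff: FatFractionVolume, mask: LabelVolume, label) -> float:
    """Unweighted mean fat fraction (percent) over the voxels of ``label``."""
    if ff.geometry != mask.geometry:
        raise ValueError("fat-fraction and mask geometries differ")
    code = _label_code(label)
    sel = mask.data == code
    if not sel.any():
        raise ValueError(f"label {label!r} selects no voxels; mean undefined")
    return float(ff.data[sel].mean())


def axial_confine(mask: LabelVolume, z_low: int, z_high: int) -> LabelVolume:
    """Keep only slices in the half-open axial range [z_low, z_high).

    Voxels outside the range are set to background; inside they are
    unchanged.  Mirrors the anatomical confinement of SAT/VAT masks.
    """
    nz = mask.data.shape[2]
    if not (0 <= z_low <= z_high <= nz):
        raise ValueError(f"invalid slice range [{z_low}, {z_high}) for {nz} slices")
    out = np.zeros_like(mask.data)
    out[:, :, z_low:z_high] = mask.data[:, :, z_low:z_high]
    return LabelVolume(out, mask.geometry)


# -- NIfTI I/O -----------------------------------------------------------


def _geometry_from_img(img) -> VoxelGeometry:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGeometry(voxel_size=zooms, shape=tuple(int(s) for s in img.shape[:3]))


def load_label_volume(path) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: label image has non-integer values")
    return LabelVolume(np.round(data).astype(np.int16), _geometry_from_img(img))


def load_fat_fraction(path) -> FatFractionVolume:
    img = nib.load(str(path))
    return FatFractionVolume(np.asarray(img.dataobj, dtype=float), _geometry_from_img(img))


def save_nifti(volume: LabelVolume | FatFractionVolume, path) -> None:
    data = volume.data
    if isinstance(volume, LabelVolume):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, affine=volume.geometry.affine())
    img.header.set_zooms(volume.geometry.voxel_size)
    nib.save(img, str(path))
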