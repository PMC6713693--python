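"""Synthetic abdominal phantoms: label masks plus fat-fraction volumes.

A phantom is an ellipsoidal liver, a subcutaneous fat shell (the region
between an outer and an inner body ellipse, extruded axially) and a set of
visceral fat blobs inside the body cavity, voxelized on a regular grid.
The returned ground truth is computed from the emitted masks themselves
(voxel count x voxel volume), so quantification can be checked exactly;
voxelized volumes converge to the analytic shape volumes as the voxel size
shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quantify import FatFractionVolume, LabelVolume, LABEL_CODES, VoxelGeometry, mask_volume, mean_fat_fraction

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "sphere_mask"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry (mm) and composition of a synthetic abdomen."""

    shape: tuple = (96, 96, 72)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    #: liver ellipsoid: center (mm, grid coordinates) and semi-axes (mm)
    liver_center: tuple = (60.0, 80.0, 72.0)
    liver_axes: tuple = (45.0, 35.0, 40.0)
    liver_ff: float = 13.0
    #: axial body cross-section: outer and inner ellipse semi-axes (mm)
    body_axes: tuple = (90.0, 85.0)
    inner_axes: tuple = (70.0, 65.0)
    sat_ff: float = 90.0
    n_vat_blobs: int = 6
    vat_blob_radius: tuple = (8.0, 16.0)  # min, max (mm)
    vat_ff: float = 88.0
    background_ff: float = 1.0
    #: SD of voxelwise fat-fraction noise added inside organs (percent)
    ff_noise_sd: float = 0.0


@dataclass
class PhantomTruth:
    """Ground truth of an emitted phantom, exact by construction."""

    volumes_cm3: dict = field(default_factory=dict)
    mean_ff: dict = field(default_factory=dict)


def _grid_mm(geom: VoxelGeometry):
    """Voxel-center coordinates (mm) along each axis."""
    return [
        (np.arange(n) + 0.5) * s
        for n, s in zip(geom.shape, geom.voxel_size)
    ]


def sphere_mask(geom: VoxelGeometry, center_mm, radius_mm: float) -> np.ndarray:
    """Boolean voxelization of a sphere (voxel-center inclusion rule)."""
    xs, ys, zs = _grid_mm(geom)
    dx = (xs - center_mm[0])[:, None, None]
    dy = (ys - center_mm[1])[None, :, None]
    dz = (zs - center_mm[2])[None, None, :]
    return dx**2 + dy**2 + dz**2 <= radius_mm**2


def _ellipsoid_mask(geom, center, axes) -> np.ndarray:
    xs, ys, zs = _grid_mm(geom)
    dx = ((xs - center[0]) / axes[0])[:, None, None]
    dy = ((ys - center[1]) / axes[1])[None, :, None]
    dz = ((zs - center[2]) / axes[2])[None, None, :]
    return dx**2 + dy**2 + dz**2 <= 1.0


def _elliptic_cylinder(geom, axes) -> np.ndarray:
    """Axial extrusion of an ellipse centred in the grid cross-section."""
    xs, ys, _ = _grid_mm(geom)
    cx = geom.shape[0] * geom.voxel_size[0] / 2.0
    cy = geom.shape[1] * geom.voxel_size[1] / 2.0
    dx = ((xs - cx) / axes[0])[:, None]
    dy = ((ys - cy) / axes[1])[None, :]
    return np.broadcast_to(
        (dx**2 + dy**2 <= 1.0)[:, :, None], geom.shape
    ).copy()


def make_phantom(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[LabelVolume, FatFractionVolume, PhantomTruth]:
    """Voxelize a phantom and return (labels, fat fraction, ground truth).

    Raises ValueError if a requested organ does not fit inside the grid.
    """
    geom = VoxelGeometry(voxel_size=tuple(spec.voxel_size), shape=tuple(spec.shape))
    extent = [n * s for n, s in zip(geom.shape, geom.voxel_size)]

    for dim in range(3):
        lo = spec.liver_center[dim] - spec.liver_axes[dim]
        hi = spec.liver_center[dim] + spec.liver_axes[dim]
        if lo < 0 or hi > extent[dim]:
            raise ValueError("liver ellipsoid extends outside the grid")
    if spec.body_axes[0] * 2 > extent[0] or spec.body_axes[1] * 2 > extent[1]:
        raise ValueError("body ellipse extends outside the grid")

    labels = np.zeros(geom.shape, dtype=np.int16)

    body = _elliptic_cylinder(geom, spec.body_axes)
    inner = _elliptic_cylinder(geom, spec.inner_axes)
    labels[body & ~inner] = LABEL_CODES["sat"]

    liver = _ellipsoid_mask(geom, spec.liver_center, spec.liver_axes)
    labels[liver] = LABEL_CODES["liver"]

    # visceral blobs inside the cavity, never overwriting liver
    r_lo, r_hi = spec.vat_blob_radius
    for _ in range(spec.n_vat_blobs):
        r = rng.uniform(r_lo, r_hi)
        cx = rng.uniform(r, extent[0] - r)
        cy = rng.uniform(r, extent[1] - r)
        cz = rng.uniform(r, extent[2] - r)
        blob = sphere_mask(geom, (cx, cy, cz), r)
        labels[blob & inner & (labels == 0)] = LABEL_CODES["vat"]

    ff = np.full(geom.shape, spec.background_ff, dtype=float)
    for name, val in (("liver", spec.liver_ff), ("sat", spec.sat_ff), ("vat", spec.vat_ff)):
        sel = labels == LABEL_CODES[name]
        ff[sel] = val
        if spec.ff_noise_sd > 0:
            ff[sel] += spec.ff_noise_sd * rng.standard_normal(int(sel.sum()))

    label_vol = LabelVolume(labels, geom)
    ff_vol = FatFractionVolume(ff, geom)

    truth = PhantomTruth()
    for name in ("liver", "sat", "vat"):
        truth.volumes_cm3[name] = mask_volume(label_vol, name)
        if (labels == LABEL_CODES[name]).any():
            truth.mean_ff[name] = mean_fat_fraction(ff_vol, label_vol, name)
    return label_vol, ff_vol, truth
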