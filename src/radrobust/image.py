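"""Image containers: CT volumes in Hounsfield units and aligned binary lesion masks.

Arrays are indexed ``(slice, row, column)`` — axis 0 is the scanner z axis
(slice direction), axes 1 and 2 span the axial plane.  ``spacing`` gives the
voxel edge length in millimetres for each array axis in the same order.
NIfTI files store data ``(x, y, z)``; the loaders transpose so that in-memory
arrays always follow the ``(z, y, x)`` convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["CtVolume", "LesionMask", "load_volume", "load_mask"]


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive lengths (mm), got {spacing!r}")
    return spacing


@dataclass(frozen=True)
class CtVolume:
    """A 3D grid of CT numbers (HU) with per-axis voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or values.size == 0:
            raise ValueError("CtVolume requires a non-empty 3D array")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def save(self, path: str) -> None:
        _save_nifti(self.values, self.spacing, path)


@dataclass(frozen=True)
class LesionMask:
    """A binary lesion segmentation aligned to a :class:`CtVolume` grid."""

    membership: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        membership = np.asarray(self.membership).astype(bool)
        if membership.ndim != 3 or membership.size == 0:
            raise ValueError("LesionMask requires a non-empty 3D array")
        object.__setattr__(self, "membership", membership)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing))

    def save(self, path: str) -> None:
        _save_nifti(self.membership.astype(np.uint8), self.spacing, path)


def check_aligned(volume: CtVolume, mask: LesionMask) -> None:
    """Raise if mask and volume do not share the same grid."""
    if volume.values.shape != mask.membership.shape:
        raise ValueError(
            f"mask grid {mask.membership.shape} does not match volume grid "
            f"{volume.values.shape}; no resampling is performed silently"
        )


def _save_nifti(data: np.ndarray, spacing: tuple[float, float, float], path: str) -> None:
    # (z, y, x) in memory -> (x, y, z) on disk with a diagonal mm affine
    xyz = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    nib.save(nib.Nifti1Image(xyz, affine), path)


def _load_nifti(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(path)
    data = np.transpose(np.asarray(img.dataobj), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return data, spacing


def load_volume(path: str) -> CtVolume:
    data, spacing = _load_nifti(path)
    return CtVolume(data.astype(float), spacing)


def load_mask(path: str) -> LesionMask:
    data, spacing = _load_nifti(path)
    return LesionMask(data > 0, spacing)
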