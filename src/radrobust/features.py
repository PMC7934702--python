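"""Delta-radiomics feature extraction on CT volume + lesion mask pairs.

Implements the six per-lesion descriptors used by the pipeline:

* ``tumor_mass`` — water-equivalent lesion mass in mg: sum over mask voxels of
  ``(HU + 1000)/1000`` (mg/mm^3) times the voxel volume.  A partial-solid
  lesion therefore weighs less than a solid lesion of the same volume.
* ``sigmoid_offset_mean`` — boundary-sharpness descriptor: HU profiles are
  sampled along outward surface normals and fitted with a sigmoid
  ``A / (1 + exp((t - offset)/slope)) + B``; the feature is the mean fitted
  offset (mm) over surface points.
* ``gabor_energy`` — mean squared response of a zero-mean 2D Gabor bank
  (4 orientations x 2 wavelengths) applied slice-wise, a line-like-pattern /
  texture descriptor.
* ``dwt_energy`` — mean squared detail coefficient of a separable 3D discrete
  wavelet transform of the lesion bounding box, an intratumoral-heterogeneity
  descriptor.
* ``volume`` (mm^3) and ``largest_diameter`` (mm, axial-plane convention).

Delta features are baseline minus follow-up, per feature name.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist
from skimage.filters import gabor_kernel

from .image import CtVolume, LesionMask, check_aligned

__all__ = [
    "EmptyLesionError",
    "UnstableFitError",
    "FEATURE_NAMES",
    "compute_tumor_mass",
    "compute_sigmoid_offset_mean",
    "compute_gabor_energy",
    "compute_dwt_energy",
    "compute_size",
    "extract_features",
    "delta_features",
]

FEATURE_NAMES = (
    "tumor_mass",
    "sigmoid_offset_mean",
    "gabor_energy",
    "dwt_energy",
    "volume",
    "largest_diameter",
)


class EmptyLesionError(ValueError):
    """The mask has no foreground voxels (or too few for the operation)."""


class UnstableFitError(RuntimeError):
    """Too many boundary-profile fits failed to produce a reliable mean."""


def _require_lesion(volume: CtVolume, mask: LesionMask, min_voxels: int = 1) -> None:
    check_aligned(volume, mask)
    if mask.n_voxels < min_voxels:
        raise EmptyLesionError(
            f"mask has {mask.n_voxels} foreground voxels; at least {min_voxels} required"
        )


def compute_tumor_mass(volume: CtVolume, mask: LesionMask) -> float:
    """Water-equivalent lesion mass in mg.

    HU is converted to physical density with the standard water-equivalent
    mapping ``(HU + 1000)/1000`` mg/mm^3 (air = 0, water = 1), floored at 0.
    """
    _require_lesion(volume, mask)
    density = np.clip((volume.values[mask.membership] + 1000.0) / 1000.0, 0.0, None)
    return float(density.sum() * volume.voxel_volume)


def compute_size(
    volume: CtVolume, mask: LesionMask, diameter_plane: str = "axial"
) -> tuple[float, float]:
    """Lesion volume (mm^3) and largest diameter (mm).

    The diameter is the maximum pairwise distance between boundary voxel
    centres, by default measured within axial slices (RECIST-style);
    ``diameter_plane="3d"`` measures it over the full 3D boundary.
    """
    _require_lesion(volume, mask)
    m = mask.membership
    boundary = m & ~ndimage.binary_erosion(m)
    spacing = np.asarray(volume.spacing)
    diameter = 0.0
    if diameter_plane == "axial":
        for z in range(m.shape[0]):
            pts = np.argwhere(boundary[z]) * spacing[1:]
            if len(pts) >= 2:
                diameter = max(diameter, float(pdist(pts).max()))
    elif diameter_plane == "3d":
        pts = np.argwhere(boundary) * spacing
        if len(pts) >= 2:
            diameter = float(pdist(pts).max())
    else:
        raise ValueError(f"diameter_plane must be 'axial' or '3d', got {diameter_plane!r}")
    return mask.n_voxels * volume.voxel_volume, diameter


# --- boundary sharpness ---------------------------------------------------


def _sigmoid(t: np.ndarray, amplitude: float, offset: float, slope: float, base: float) -> np.ndarray:
    return amplitude / (1.0 + np.exp(np.clip((t - offset) / slope, -500, 500))) + base


def _surface_points_and_normals(
    mask: LesionMask, smooth_mm: float = 1.0, max_points: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Surface voxel centres (mm) and outward normals from the smoothed mask gradient."""
    m = mask.membership
    surface = m & ~ndimage.binary_erosion(m)
    idx = np.argwhere(surface)
    if len(idx) == 0:
        raise EmptyLesionError("mask has no surface voxels")
    spacing = np.asarray(mask.spacing)
    smoothed = ndimage.gaussian_filter(m.astype(float), sigma=smooth_mm / spacing)
    grads = np.gradient(smoothed, *spacing)
    g = np.stack([grad[tuple(idx.T)] for grad in grads], axis=1)
    norms = np.linalg.norm(g, axis=1)
    ok = norms > 1e-12
    if not ok.any():
        raise EmptyLesionError("no surface normals could be defined (degenerate mask)")
    idx, g, norms = idx[ok], g[ok], norms[ok]
    normals = -g / norms[:, None]  # gradient points inward on an inside-high mask
    if len(idx) > max_points:
        # deterministic even subsample of surface points
        pick = np.linspace(0, len(idx) - 1, max_points).round().astype(int)
        idx, normals = idx[pick], normals[pick]
    return idx * spacing, normals


def compute_sigmoid_offset_mean(
    volume: CtVolume,
    mask: LesionMask,
    profile_length: float = 6.0,
    step: float = 0.35,
    max_points: int = 200,
) -> float:
    """Mean sigmoid offset (mm) of boundary HU profiles.

    For each surface point an HU profile is sampled by trilinear interpolation
    along the outward normal over ``[-profile_length, +profile_length]`` mm and
    fitted with ``A / (1 + exp((t - offset)/slope)) + B``.  An offset of 0
    means the density transition sits exactly at the mask surface; positive
    offsets push it outward.  Lower values correspond to sharper, earlier
    transitions relative to lesions with outward-shifted boundaries.

    Raises :class:`UnstableFitError` when more than half of the profiles fail
    to fit, and :class:`EmptyLesionError` for masks without a usable surface
    (e.g. a single voxel).
    """
    _require_lesion(volume, mask, min_voxels=2)
    points, normals = _surface_points_and_normals(mask, max_points=max_points)
    spacing = np.asarray(volume.spacing)
    t = np.arange(-profile_length, profile_length + step / 2, step)
    offsets = []
    n_failed = 0
    for p, n in zip(points, normals):
        sample_mm = p[None, :] + t[:, None] * n[None, :]
        coords = (sample_mm / spacing).T
        profile = ndimage.map_coordinates(volume.values, coords, order=1, mode="nearest")
        amp0 = profile[0] - profile[-1]
        if abs(amp0) < 1e-9:
            n_failed += 1
            continue
        p0 = [amp0, 0.0, 1.0, profile[-1]]
        bounds = (
            [-np.inf, -profile_length, 1e-3, -np.inf],
            [np.inf, profile_length, profile_length, np.inf],
        )
        try:
            popt, _ = curve_fit(_sigmoid, t, profile, p0=p0, bounds=bounds, maxfev=2000)
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        offsets.append(popt[1])
    if n_failed > len(points) / 2 or not offsets:
        raise UnstableFitError(
            f"{n_failed}/{len(points)} boundary profiles failed to fit"
        )
    return float(np.mean(offsets))


# --- texture energies -----------------------------------------------------


def _gabor_bank(wavelengths_px: tuple[float, ...], orientations: tuple[float, ...]):
    bank = []
    for lam in wavelengths_px:
        for theta in orientations:
            kernel = np.real(gabor_kernel(frequency=1.0 / lam, theta=theta))
            bank.append(kernel - kernel.mean())  # enforce exactly zero-mean
    return bank


def compute_gabor_energy(
    volume: CtVolume,
    mask: LesionMask,
    wavelengths_px: tuple[float, ...] = (4.0, 8.0),
    orientations: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4),
) -> float:
    """Mean squared zero-mean Gabor-bank response over mask voxels.

    The bank (default 4 orientations x wavelengths of 4 and 8 in-plane voxels)
    is applied per axial slice — CT voxels are anisotropic, so 2D in-plane
    filtering is the natural convention.  Outside-mask voxels in each slice
    are replaced by the slice's in-mask mean before filtering so background
    structure cannot leak into the energy.  The energy scales quadratically
    with intensity scaling and is zero on constant images.
    """
    _require_lesion(volume, mask)
    bank = _gabor_bank(wavelengths_px, orientations)
    pad = max(max(k.shape) for k in bank)
    total = 0.0
    m = mask.membership
    for z in range(m.shape[0]):
        mz = m[z]
        if not mz.any():
            continue
        ys, xs = np.nonzero(mz)
        y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, mz.shape[0])
        x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, mz.shape[1])
        patch = volume.values[z, y0:y1, x0:x1].astype(float)
        sub = mz[y0:y1, x0:x1]
        fill = patch[sub].mean()
        patch = np.where(sub, patch, fill)
        for kernel in bank:
            response = ndimage.convolve(patch, kernel, mode="nearest")
            total += float((response[sub] ** 2).sum())
    return total / (mask.n_voxels * len(bank))


def compute_dwt_energy(
    volume: CtVolume,
    mask: LesionMask,
    wavelet: str = "db4",
    levels: int = 2,
) -> float:
    """Mean squared detail coefficient of a 3D separable DWT of the lesion box.

    The mask bounding box is extracted, outside-mask voxels are filled with
    the in-mask mean, axes shorter than ``2**levels`` are edge-padded, and the
    box is decomposed with a Daubechies-4 wavelet (symmetric extension, so a
    constant region has exactly zero detail energy).  The energy is the sum of
    squared detail coefficients over all levels and subbands divided by the
    mask voxel count; larger values mean more intratumoral heterogeneity.
    """
    _require_lesion(volume, mask)
    m = mask.membership
    slices = ndimage.find_objects(m.astype(np.uint8))[0]
    box = volume.values[slices].astype(float)
    sub = m[slices]
    fill = box[sub].mean()
    box = np.where(sub, box, fill)
    min_len = 2**levels
    pad = [(0, max(0, min_len - s)) for s in box.shape]
    if any(p[1] for p in pad):
        box = np.pad(box, pad, mode="edge")
    import warnings

    with warnings.catch_warnings():
        # boundary effects at small box sizes are acceptable for an energy sum
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedecn(box, wavelet, level=levels, mode="symmetric")
    energy = 0.0
    for level in coeffs[1:]:  # detail subbands only
        for arr in level.values():
            energy += float((arr**2).sum())
    return energy / mask.n_voxels


def extract_features(volume: CtVolume, mask: LesionMask) -> pd.Series:
    """Compute the full per-lesion feature vector."""
    volume_mm3, diameter = compute_size(volume, mask)
    return pd.Series(
        {
            "tumor_mass": compute_tumor_mass(volume, mask),
            "sigmoid_offset_mean": compute_sigmoid_offset_mean(volume, mask),
            "gabor_energy": compute_gabor_energy(volume, mask),
            "dwt_energy": compute_dwt_energy(volume, mask),
            "volume": volume_mm3,
            "largest_diameter": diameter,
        }
    )


def delta_features(baseline: pd.Series, followup: pd.Series) -> pd.Series:
    """Delta feature vector: baseline minus follow-up, matched by name.

    A negative delta means the feature value grew between baseline and
    follow-up.
    """
    if set(baseline.index) != set(followup.index):
        raise ValueError(
            f"feature name mismatch: baseline {sorted(baseline.index)} vs "
            f"follow-up {sorted(followup.index)}"
        )
    return baseline - followup.reindex(baseline.index)
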