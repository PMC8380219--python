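"""Resampling, HU-based mask cleaning, size gating and intensity discretization.

The preprocessing chain mirrors standard PET radiomics practice: volumes are
resampled to cubic 5.5 mm voxels with trilinear interpolation, the tumour
mask is cleaned by excluding voxels whose companion CT value falls outside a
soft-tissue Hounsfield window (default −300..200, inclusive), regions smaller
than 72 voxels are excluded (wavelet features on smaller regions are not
meaningful), and SUV values are discretized with a fixed bin size of
0.25 SUV anchored at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, ROIMask

__all__ = [
    "DiscretizedROI",
    "resample_volume",
    "resample_mask",
    "apply_hu_exclusion",
    "size_gate",
    "discretize",
    "MIN_VOXELS",
]

MIN_VOXELS = 72


@dataclass
class DiscretizedROI:
    """Grey-level bin indices for the voxels of a region of interest.

    ``grid`` holds the bin index (1..n_bins) for ROI voxels and 0 elsewhere,
    so texture matrices can be built on the full 3D lattice.
    """

    grid: np.ndarray            # int array, 0 outside ROI
    n_bins: int
    bin_size: float
    spacing_mm: tuple[float, float, float]

    def roi_values(self) -> np.ndarray:
        return self.grid[self.grid > 0]


def _target_grid(shape: tuple[int, ...], spacing: tuple[float, ...],
                 target: float) -> tuple[tuple[int, ...], list[np.ndarray]]:
    """New shape and per-axis fractional input coordinates for resampling.

    Output voxel centres are laid on the input voxel-centre lattice
    (``origin + j*target``) and never extrapolate beyond the last input
    centre, so trilinear interpolation is exact for linear fields.
    """
    new_shape = []
    coords = []
    for n, s in zip(shape, spacing):
        extent = (n - 1) * s
        m = int(np.floor(extent / target + 1e-9)) + 1
        new_shape.append(m)
        coords.append(np.arange(m) * target / s)
    return tuple(new_shape), coords


def resample_volume(vol: ImageVolume, target_spacing_mm: float = 5.5) -> ImageVolume:
    """Resample to cubic voxels at ``target_spacing_mm`` by trilinear interpolation."""
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    if np.allclose(vol.spacing_mm, target_spacing_mm):
        return vol.copy_with(vol.values)
    new_shape, axes = _target_grid(vol.shape, vol.spacing_mm, target_spacing_mm)
    grid = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(vol.values, np.stack(grid), order=1, mode="nearest")
    return ImageVolume(out.reshape(new_shape), (target_spacing_mm,) * 3,
                       vol.origin_mm, vol.modality)


def resample_mask(mask: ROIMask, target_spacing_mm: float = 5.5,
                  method: str = "linear") -> ROIMask:
    """Resample a binary mask to cubic voxels.

    The 0/1 indicator is interpolated (trilinear by default, approximately
    volume preserving) and re-binarized at 0.5; ``method="nearest"`` is
    available as an alternative.  An empty result is flagged with a warning
    rather than silently returned.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    if np.allclose(mask.spacing_mm, target_spacing_mm):
        out = mask.values.copy()
    else:
        new_shape, axes = _target_grid(mask.shape, mask.spacing_mm, target_spacing_mm)
        grid = np.meshgrid(*axes, indexing="ij")
        order = 1 if method == "linear" else 0
        vals = ndimage.map_coordinates(mask.values.astype(float), np.stack(grid),
                                       order=order, mode="nearest")
        out = vals.reshape(new_shape) >= 0.5
    result = ROIMask(out, (target_spacing_mm,) * 3, mask.origin_mm)
    if result.voxel_count() == 0:
        warnings.warn("mask is empty after resampling", stacklevel=2)
    return result


def apply_hu_exclusion(mask: ROIMask, ct: ImageVolume,
                       hu_min: float = -300.0, hu_max: float = 200.0) -> ROIMask:
    """Remove mask voxels whose CT value lies outside [hu_min, hu_max] (inclusive)."""
    if not mask.same_geometry(ct):
        raise ValueError("CT volume and mask are not on the same grid")
    keep = (ct.values >= hu_min) & (ct.values <= hu_max)
    return mask.copy_with(mask.values & keep)


def size_gate(mask: ROIMask, min_voxels: int = MIN_VOXELS) -> bool:
    """True iff the (post-exclusion, post-resampling) ROI has >= min_voxels voxels."""
    return mask.voxel_count() >= min_voxels


def discretize(vol: ImageVolume, mask: ROIMask, bin_size: float = 0.25,
               shift_to_min: bool = False) -> DiscretizedROI:
    """Fixed-bin-size discretization of the ROI voxels.

    Bins are anchored at 0 with left-closed intervals, i.e. index
    ``floor(v / bin_size) + 1``, so a common SUV scale maps identically
    across patients.  With ``shift_to_min`` the ROI minimum is subtracted
    first — used for wavelet subbands, whose coefficients may be negative.
    Negative values inside the ROI (possible only for SUV inputs through
    interpolation) are clamped to bin 1 with a warning.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    if not mask.same_geometry(vol):
        raise ValueError("volume and mask are not on the same grid")
    if mask.voxel_count() == 0:
        raise ValueError("cannot discretize an empty ROI")
    vals = vol.values[mask.values]
    if shift_to_min:
        vals = vals - vals.min()
    if np.any(vals < 0):
        warnings.warn("negative values inside ROI clamped to bin 1", stacklevel=2)
    idx = np.floor(np.maximum(vals, 0.0) / bin_size).astype(int) + 1
    grid = np.zeros(vol.shape, dtype=int)
    grid[mask.values] = idx
    return DiscretizedROI(grid=grid, n_bins=int(idx.max()), bin_size=float(bin_size),
                          spacing_mm=vol.spacing_mm)
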