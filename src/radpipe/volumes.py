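"""In-memory containers for 3D scalar volumes and binary regions of interest.

The package works on voxel grids with physical spacing (mm).  Array axis
order is (x, y, z); voxel ``(i, j, k)`` is centred at
``origin + (i, j, k) * spacing``.  Values are SUV for PET, HU for CT, and
wavelet coefficients for filtered volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "ROIMask", "read_volume", "read_mask"]


@dataclass
class ImageVolume:
    """A 3D scalar field on a regular grid.

    Parameters
    ----------
    values
        3D array of voxel values.
    spacing_mm
        Physical voxel size along (x, y, z), strictly positive.
    origin_mm
        Physical position of the centre of voxel (0, 0, 0).
    modality
        One of ``"SUV"``, ``"HU"``, ``"WAVELET"``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "SUV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def copy_with(self, values: np.ndarray, modality: str | None = None) -> "ImageVolume":
        return replace(self, values=np.asarray(values, dtype=float),
                       modality=self.modality if modality is None else modality)

    def same_geometry(self, other: "ImageVolume | ROIMask") -> bool:
        return (self.shape == other.values.shape
                and np.allclose(self.spacing_mm, other.spacing_mm)
                and np.allclose(self.origin_mm, other.origin_mm))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def to_nifti(self, path: str) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine())
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, path)


@dataclass
class ROIMask:
    """A binary region aligned to an :class:`ImageVolume` grid."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_count(self) -> int:
        return int(self.values.sum())

    def volume_mm3(self) -> float:
        return self.voxel_count() * float(np.prod(self.spacing_mm))

    def copy_with(self, values: np.ndarray) -> "ROIMask":
        return replace(self, values=np.asarray(values).astype(bool))

    def same_geometry(self, other: "ImageVolume | ROIMask") -> bool:
        return (self.shape == other.values.shape
                and np.allclose(self.spacing_mm, other.spacing_mm)
                and np.allclose(self.origin_mm, other.origin_mm))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def to_nifti(self, path: str) -> None:
        img = nib.Nifti1Image(self.values.astype(np.uint8), self.affine())
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, path)


def _geometry_from_nifti(img: nib.Nifti1Image) -> tuple[tuple, tuple]:
    aff = img.affine
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in aff[:3, 3])
    return spacing, origin


def read_volume(path: str, modality: str = "SUV") -> ImageVolume:
    img = nib.load(path)
    spacing, origin = _geometry_from_nifti(img)
    return ImageVolume(np.asanyarray(img.dataobj, dtype=float), spacing, origin, modality)


def read_mask(path: str) -> ROIMask:
    img = nib.load(path)
    spacing, origin = _geometry_from_nifti(img)
    return ROIMask(np.asanyarray(img.dataobj) > 0.5, spacing, origin)
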