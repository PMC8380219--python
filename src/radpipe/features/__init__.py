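"""Radiomic feature extraction: 1404 features per (PET, CT, mask) triplet.

The feature vector concatenates, in fixed normative order:

* 18 shape features of the final ROI mask,
* 17 first-order intensity features of the SUV values in the ROI,
* 137 texture features on the fixed-bin-size discretized SUV ROI,
* for each of the 8 undecimated Haar subbands, the same 17 intensity and
  137 texture features on the subband coefficients (8 x 154 = 1232),

for a total of 1404 named values.  Names follow the schema
``family/...``: ``shape/<f>``, ``intensity/<f>``, ``texture/<matrix>/<f>``
and ``wavelet/<subband>/(intensity|texture/<matrix>)/<f>``.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..preprocessing import (MIN_VOXELS, apply_hu_exclusion, discretize,
                             resample_mask, resample_volume, size_gate)
from ..volumes import ImageVolume, ROIMask
from .intensity import INTENSITY_FEATURES, intensity_features
from .shape import SHAPE_FEATURES, shape_features
from .texture import TEXTURE_FEATURE_NAMES, texture_features
from .wavelet import SUBBANDS, wavelet_decompose

__all__ = [
    "ExtractionConfig",
    "FeatureExtraction",
    "extract_all",
    "extract_cohort",
    "feature_names",
    "family_of",
    "FAMILY_COUNTS",
]

FAMILY_COUNTS = {"shape": 18, "intensity": 17, "texture": 137, "wavelet": 1232}


@dataclass
class ExtractionConfig:
    """Tunable parameters of the preprocessing + extraction chain."""

    target_spacing_mm: float = 5.5
    bin_size_suv: float = 0.25
    hu_range: tuple[float, float] = (-300.0, 200.0)
    min_voxels: int = MIN_VOXELS
    mask_interp: str = "linear"
    wavelet_mode: str = "reflect"

    def to_dict(self) -> dict:
        return {
            "target_spacing_mm": self.target_spacing_mm,
            "bin_size_suv": self.bin_size_suv,
            "hu_range": list(self.hu_range),
            "min_voxels": self.min_voxels,
            "mask_interp": self.mask_interp,
            "wavelet_mode": self.wavelet_mode,
        }


@dataclass
class FeatureExtraction:
    """Result of :func:`extract_all`: a feature vector or an exclusion record."""

    features: pd.Series | None
    excluded: bool = False
    message: str = ""


def feature_names() -> tuple[str, ...]:
    """The normative, ordered 1404-feature roster."""
    names: list[str] = [f"shape/{f}" for f in SHAPE_FEATURES]
    names += [f"intensity/{f}" for f in INTENSITY_FEATURES]
    names += [f"texture/{t}" for t in TEXTURE_FEATURE_NAMES]
    for band in SUBBANDS:
        names += [f"wavelet/{band}/intensity/{f}" for f in INTENSITY_FEATURES]
        names += [f"wavelet/{band}/texture/{t}" for t in TEXTURE_FEATURE_NAMES]
    return tuple(names)


FEATURE_NAMES = feature_names()
assert len(FEATURE_NAMES) == 1404


def family_of(name: str) -> str:
    """Feature family ('shape', 'intensity', 'texture', 'wavelet') of a feature name."""
    fam = name.split("/", 1)[0]
    if fam not in FAMILY_COUNTS:
        raise ValueError(f"unknown feature family in name {name!r}")
    return fam


def extract_all(pet: ImageVolume, ct: ImageVolume | None, mask: ROIMask,
                config: ExtractionConfig | None = None) -> FeatureExtraction:
    """Run the full preprocessing + extraction chain on one patient.

    The inputs are assumed co-registered on a common native grid.  They are
    resampled to cubic voxels, the mask is cleaned with the CT Hounsfield
    window (when a CT is given), the 72-voxel gate is applied, and the
    1404-feature vector is computed.  A gated-out tumour yields an
    exclusion record instead of a crash.
    """
    cfg = config or ExtractionConfig()
    pet_r = resample_volume(pet, cfg.target_spacing_mm)
    roi = resample_mask(mask, cfg.target_spacing_mm, method=cfg.mask_interp)
    if ct is not None:
        ct_r = resample_volume(ct, cfg.target_spacing_mm)
        if not ct_r.same_geometry(pet_r):
            raise ValueError("CT and PET do not share a grid after resampling")
        roi = apply_hu_exclusion(roi, ct_r, *cfg.hu_range)
    if not size_gate(roi, cfg.min_voxels):
        n = roi.voxel_count()
        return FeatureExtraction(None, excluded=True,
                                 message=f"excluded: {n} voxels < {cfg.min_voxels}")

    out: OrderedDict[str, float] = OrderedDict()
    for f, v in shape_features(roi).items():
        out[f"shape/{f}"] = v
    for f, v in intensity_features(pet_r.values[roi.values], cfg.bin_size_suv).items():
        out[f"intensity/{f}"] = v
    disc = discretize(pet_r, roi, cfg.bin_size_suv)
    for f, v in texture_features(disc).items():
        out[f"texture/{f}"] = v

    for band, sub in wavelet_decompose(pet_r, mode=cfg.wavelet_mode).items():
        vals = sub.values[roi.values]
        for f, v in intensity_features(vals, cfg.bin_size_suv, shift_to_min=True).items():
            out[f"wavelet/{band}/intensity/{f}"] = v
        disc_b = discretize(sub, roi, cfg.bin_size_suv, shift_to_min=True)
        for f, v in texture_features(disc_b).items():
            out[f"wavelet/{band}/texture/{f}"] = v

    series = pd.Series(out, dtype=float)
    assert tuple(series.index) == FEATURE_NAMES
    return FeatureExtraction(series)


def extract_cohort(items, config: ExtractionConfig | None = None
                   ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Extract features for ``(patient_id, pet, ct, mask)`` items.

    Returns the patients x features table and a list of
    ``(patient_id, reason)`` exclusion records for gated-out tumours.
    """
    rows, excluded = {}, []
    for pid, pet, ct, mask in items:
        res = extract_all(pet, ct, mask, config)
        if res.excluded:
            excluded.append((pid, res.message))
        else:
            rows[pid] = res.features
    table = pd.DataFrame(rows).T
    if not table.empty:
        table = table[list(FEATURE_NAMES)]
    return table, excluded
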