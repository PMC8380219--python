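"""One-level undecimated separable 3D Haar decomposition.

Each axis is filtered with a two-tap low-pass or high-pass Haar kernel,
yielding 8 subbands on the *same* grid as the input (undecimated), so the
ROI mask can be reused unchanged.  Subband labels give the per-axis filter
in axis order (x, y, z): "HHL" means high-pass along x and y, low-pass
along z.

The low-pass is normalised to unit gain (taps 0.5, 0.5), so the LLL band
of a constant volume is that constant and all H-containing bands of a
constant volume vanish.  With this normalisation and periodic boundary
handling the 8-band bank conserves total energy exactly:
``sum_b ||W_b x||^2 == ||x||^2``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..volumes import ImageVolume

__all__ = ["SUBBANDS", "wavelet_decompose"]

SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

_LOW = np.array([0.5, 0.5])
_HIGH = np.array([0.5, -0.5])


def _filter_axis(x: np.ndarray, kernel: np.ndarray, axis: int, mode: str) -> np.ndarray:
    # two-tap kernel pairs voxel i with i+1; origin=-1 keeps the pair causal
    return ndimage.correlate1d(x, kernel, axis=axis, mode=mode, origin=-1)


def wavelet_decompose(vol: ImageVolume, mode: str = "reflect") -> dict[str, ImageVolume]:
    """Decompose a volume into its 8 undecimated Haar subbands.

    Parameters
    ----------
    vol
        Input volume (typically the resampled SUV grid).
    mode
        Boundary handling passed to the separable filters; the default
        symmetric reflection suits volumes with arbitrary shape, while
        ``"wrap"`` makes the bank exactly energy conserving.
    """
    bands: dict[str, ImageVolume] = {}
    for label in SUBBANDS:
        out = vol.values
        for axis, letter in enumerate(label):
            kernel = _LOW if letter == "L" else _HIGH
            out = _filter_axis(out, kernel, axis, mode)
        bands[label] = ImageVolume(out, vol.spacing_mm, vol.origin_mm, "WAVELET")
    return bands
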