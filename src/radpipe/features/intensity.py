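"""First-order intensity statistics (17 features) on the ROI voxel values.

Entropy and uniformity are computed on the fixed-bin-size histogram used for
texture calculation (0.25 SUV by default), so they share the discretization
semantics of the texture features.  Degenerate inputs (constant ROI) define
skewness, kurtosis and coefficient of variation as 0 rather than NaN.
"""

from __future__ import annotations

import numpy as np

__all__ = ["INTENSITY_FEATURES", "intensity_features"]

INTENSITY_FEATURES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "maximum",
    "range",
    "percentile10",
    "percentile90",
    "interquartile_range",
    "energy",
    "root_mean_square",
    "mean_absolute_deviation",
    "entropy",
    "uniformity",
    "coefficient_of_variation",
)


def intensity_features(values: np.ndarray, bin_size: float = 0.25,
                       shift_to_min: bool = False) -> dict[str, float]:
    """Compute the 17 first-order features for a flat array of ROI values.

    ``shift_to_min`` applies the same min-shift used when discretizing
    wavelet subbands before the histogram-based entropy/uniformity.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("intensity features require a nonempty ROI")
    mu = float(x.mean())
    var = float(x.var())  # population variance, IBSI convention
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(np.mean((x - mu) ** 3) / sd**3)
        kurt = float(np.mean((x - mu) ** 4) / sd**4 - 3.0)  # excess kurtosis
        cov = sd / mu if mu != 0 else 0.0
    else:
        skew = kurt = cov = 0.0

    hist_vals = x - x.min() if shift_to_min else np.maximum(x, 0.0)
    idx = np.floor(hist_vals / bin_size).astype(int)
    p = np.bincount(idx).astype(float)
    p = p[p > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return {
        "mean": mu,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(q50),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "percentile10": float(np.percentile(x, 10)),
        "percentile90": float(np.percentile(x, 90)),
        "interquartile_range": float(q75 - q25),
        "energy": float((x**2).sum()),
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
        "mean_absolute_deviation": float(np.mean(np.abs(x - mu))),
        "entropy": entropy,
        "uniformity": uniformity,
        "coefficient_of_variation": float(cov),
    }
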