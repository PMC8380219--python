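"""Grey-level texture matrices and their features (137 named values).

All matrices are built on the discretized ROI over 3D 26-connected
neighbourhoods at distance 1 (13 unique direction offsets up to sign).
Co-occurrence and run-length features are reported under two aggregation
idioms: per-direction matrices with feature averaging (``*_avg``) and
direction-pooled matrices (``*_merged``).  Zone matrices (size, distance),
the neighbourhood grey-tone difference matrix and the neighbouring
grey-level dependence matrix are direction-free.

Roster (137): 25 GLCM x 2 aggregations, 16 GLRLM x 2, 16 GLSZM, 16 GLDZM,
5 NGTDM, 18 NGLDM.  Degenerate cases (single grey level, constant
neighbourhoods) return 0 rather than NaN, per the conventions documented
in the methods note.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
from scipy import ndimage

from ..preprocessing import DiscretizedROI

__all__ = [
    "DIRECTIONS_3D",
    "TEXTURE_FEATURE_NAMES",
    "texture_features",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "gldzm_matrix",
    "ngtdm_table",
    "ngldm_matrix",
]

# 13 unique offsets of the 26-neighbourhood (first nonzero component positive)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _pair_values(grid: np.ndarray, off: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Grey values of voxel pairs separated by ``off`` (both inside the ROI)."""
    sl_a, sl_b = [], []
    for d, n in zip(off, grid.shape):
        if d > 0:
            sl_a.append(slice(0, n - d)); sl_b.append(slice(d, n))
        elif d < 0:
            sl_a.append(slice(-d, n)); sl_b.append(slice(0, n + d))
        else:
            sl_a.append(slice(None)); sl_b.append(slice(None))
    a = grid[tuple(sl_a)].ravel()
    b = grid[tuple(sl_b)].ravel()
    keep = (a > 0) & (b > 0)
    return a[keep], b[keep]


# ---------------------------------------------------------------- GLCM

def glcm_matrix(grid: np.ndarray, n_levels: int, off: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction offset."""
    a, b = _pair_values(grid, off)
    m = np.bincount((a - 1) * n_levels + (b - 1), minlength=n_levels * n_levels)
    m = m.reshape(n_levels, n_levels).astype(float)
    return m + m.T


GLCM_FEATURES = (
    "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
    "difference_average", "difference_variance", "difference_entropy",
    "sum_average", "sum_variance", "sum_entropy",
    "angular_second_moment", "contrast", "dissimilarity",
    "inverse_difference", "inverse_difference_normalised",
    "inverse_difference_moment", "inverse_difference_moment_normalised",
    "inverse_variance", "correlation", "autocorrelation",
    "cluster_tendency", "cluster_shade", "cluster_prominence",
    "information_correlation_1", "information_correlation_2",
)


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    n = counts.shape[0]
    total = counts.sum()
    if total == 0:
        raise ValueError("empty matrix: GLCM has no voxel pairs")
    p = counts / total
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)

    mu = float((ii * p).sum())
    var = float(((ii - mu) ** 2 * p).sum())
    diff = np.abs(ii - jj)
    pd = np.bincount(diff.ravel(), weights=p.ravel(), minlength=n)
    k_d = np.arange(len(pd))
    ps = np.bincount((ii + jj).ravel(), weights=p.ravel())
    k_s = np.arange(len(ps))
    da = float((k_d * pd).sum())
    sa = float((k_s * ps).sum())

    hxy = float(-_xlog2(p).sum())
    hx = float(-_xlog2(pi).sum())
    pipj = np.outer(pi, pi)
    with np.errstate(divide="ignore"):
        log_pipj = np.where(pipj > 0, np.log2(np.where(pipj > 0, pipj, 1.0)), 0.0)
    hxy1 = float(-(p * log_pipj).sum())
    hxy2 = float(-(pipj * log_pipj).sum())

    offdiag = diff > 0
    inv_var = float((p[offdiag] / diff[offdiag] ** 2).sum()) if offdiag.any() else 0.0
    corr = float(((ii * jj * p).sum() - mu * mu) / var) if var > 0 else 0.0
    ic1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    ic2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return {
        "joint_maximum": float(p.max()),
        "joint_average": mu,
        "joint_variance": var,
        "joint_entropy": hxy,
        "difference_average": da,
        "difference_variance": float(((k_d - da) ** 2 * pd).sum()),
        "difference_entropy": float(-_xlog2(pd).sum()),
        "sum_average": sa,
        "sum_variance": float(((k_s - sa) ** 2 * ps).sum()),
        "sum_entropy": float(-_xlog2(ps).sum()),
        "angular_second_moment": float((p**2).sum()),
        "contrast": float((diff**2 * p).sum()),
        "dissimilarity": float((diff * p).sum()),
        "inverse_difference": float((p / (1.0 + diff)).sum()),
        "inverse_difference_normalised": float((p / (1.0 + diff / n)).sum()),
        "inverse_difference_moment": float((p / (1.0 + diff**2)).sum()),
        "inverse_difference_moment_normalised": float((p / (1.0 + diff**2 / n**2)).sum()),
        "inverse_variance": inv_var,
        "correlation": corr,
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "information_correlation_1": float(ic1),
        "information_correlation_2": ic2,
    }


# ---------------------------------------------------------------- GLRLM

def glrlm_matrix(grid: np.ndarray, n_levels: int, off: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts (levels x max_run) along one direction."""
    coords = np.argwhere(grid > 0)
    greys = grid[grid > 0]
    if coords.size == 0:
        raise ValueError("empty matrix: GLRLM has no ROI voxels")
    d = np.asarray(off)
    axis = int(np.nonzero(d)[0][0])
    c = coords[:, axis] * d[axis]  # advances by 1 per step along the line
    key = coords - c[:, None] * d[None, :]
    order = np.lexsort((c, key[:, 2], key[:, 1], key[:, 0]))
    ks, cs, gs = key[order], c[order], greys[order]
    new_run = np.ones(len(gs), dtype=bool)
    if len(gs) > 1:
        same_line = np.all(ks[1:] == ks[:-1], axis=1) & (np.diff(cs) == 1)
        new_run[1:] = ~(same_line & (gs[1:] == gs[:-1]))
    run_id = np.cumsum(new_run) - 1
    lengths = np.bincount(run_id)
    run_grey = gs[new_run]
    mat = np.zeros((n_levels, int(lengths.max())), dtype=float)
    np.add.at(mat, (run_grey - 1, lengths - 1), 1.0)
    return mat


def _grey_size_features(mat: np.ndarray, n_pot: float, names: dict[str, str]) -> dict[str, float]:
    """Shared feature body for grey-level x size matrices (runs, zones, distances).

    ``names`` maps the 16 generic keys to family-specific feature names;
    ``n_pot`` is the potential-count denominator of the percentage feature.
    """
    ns = mat.sum()
    if ns == 0:
        raise ValueError("empty matrix: no runs/zones")
    p = mat / ns
    g = np.arange(1, mat.shape[0] + 1, dtype=float)
    s = np.arange(1, mat.shape[1] + 1, dtype=float)
    gg, ss = np.meshgrid(g, s, indexing="ij")
    mg = mat.sum(axis=1)
    msz = mat.sum(axis=0)
    mu_g = float((gg * p).sum())
    mu_s = float((ss * p).sum())
    vals = {
        "small": float((mat / ss**2).sum() / ns),
        "large": float((mat * ss**2).sum() / ns),
        "low_grey": float((mat / gg**2).sum() / ns),
        "high_grey": float((mat * gg**2).sum() / ns),
        "small_low": float((mat / (gg**2 * ss**2)).sum() / ns),
        "small_high": float((mat * gg**2 / ss**2).sum() / ns),
        "large_low": float((mat * ss**2 / gg**2).sum() / ns),
        "large_high": float((mat * gg**2 * ss**2).sum() / ns),
        "glnu": float((mg**2).sum() / ns),
        "glnu_norm": float((mg**2).sum() / ns**2),
        "size_nu": float((msz**2).sum() / ns),
        "size_nu_norm": float((msz**2).sum() / ns**2),
        "percentage": float(ns / n_pot),
        "grey_variance": float(((gg - mu_g) ** 2 * p).sum()),
        "size_variance": float(((ss - mu_s) ** 2 * p).sum()),
        "entropy": float(-_xlog2(p).sum()),
    }
    return {names[k]: v for k, v in vals.items()}


GLRLM_NAMES = {
    "small": "short_run_emphasis", "large": "long_run_emphasis",
    "low_grey": "low_grey_level_run_emphasis", "high_grey": "high_grey_level_run_emphasis",
    "small_low": "short_run_low_grey_level_emphasis",
    "small_high": "short_run_high_grey_level_emphasis",
    "large_low": "long_run_low_grey_level_emphasis",
    "large_high": "long_run_high_grey_level_emphasis",
    "glnu": "grey_level_non_uniformity", "glnu_norm": "grey_level_non_uniformity_normalised",
    "size_nu": "run_length_non_uniformity", "size_nu_norm": "run_length_non_uniformity_normalised",
    "percentage": "run_percentage", "grey_variance": "grey_level_variance",
    "size_variance": "run_length_variance", "entropy": "run_entropy",
}
GLRLM_FEATURES = tuple(GLRLM_NAMES[k] for k in (
    "small", "large", "low_grey", "high_grey", "small_low", "small_high",
    "large_low", "large_high", "glnu", "glnu_norm", "size_nu", "size_nu_norm",
    "percentage", "grey_variance", "size_variance", "entropy"))

GLSZM_NAMES = {
    "small": "small_zone_emphasis", "large": "large_zone_emphasis",
    "low_grey": "low_grey_level_zone_emphasis", "high_grey": "high_grey_level_zone_emphasis",
    "small_low": "small_zone_low_grey_level_emphasis",
    "small_high": "small_zone_high_grey_level_emphasis",
    "large_low": "large_zone_low_grey_level_emphasis",
    "large_high": "large_zone_high_grey_level_emphasis",
    "glnu": "grey_level_non_uniformity", "glnu_norm": "grey_level_non_uniformity_normalised",
    "size_nu": "zone_size_non_uniformity", "size_nu_norm": "zone_size_non_uniformity_normalised",
    "percentage": "zone_percentage", "grey_variance": "grey_level_variance",
    "size_variance": "zone_size_variance", "entropy": "zone_size_entropy",
}
GLSZM_FEATURES = tuple(GLSZM_NAMES[k] for k in (
    "small", "large", "low_grey", "high_grey", "small_low", "small_high",
    "large_low", "large_high", "glnu", "glnu_norm", "size_nu", "size_nu_norm",
    "percentage", "grey_variance", "size_variance", "entropy"))

GLDZM_NAMES = {
    "small": "small_distance_emphasis", "large": "large_distance_emphasis",
    "low_grey": "low_grey_level_zone_emphasis", "high_grey": "high_grey_level_zone_emphasis",
    "small_low": "small_distance_low_grey_level_emphasis",
    "small_high": "small_distance_high_grey_level_emphasis",
    "large_low": "large_distance_low_grey_level_emphasis",
    "large_high": "large_distance_high_grey_level_emphasis",
    "glnu": "grey_level_non_uniformity", "glnu_norm": "grey_level_non_uniformity_normalised",
    "size_nu": "zone_distance_non_uniformity", "size_nu_norm": "zone_distance_non_uniformity_normalised",
    "percentage": "zone_percentage", "grey_variance": "grey_level_variance",
    "size_variance": "zone_distance_variance", "entropy": "zone_distance_entropy",
}
GLDZM_FEATURES = tuple(GLDZM_NAMES[k] for k in (
    "small", "large", "low_grey", "high_grey", "small_low", "small_high",
    "large_low", "large_high", "glnu", "glnu_norm", "size_nu", "size_nu_norm",
    "percentage", "grey_variance", "size_variance", "entropy"))

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------- zones

def _zones(grid: np.ndarray, n_levels: int):
    """Yield (grey, zone_voxel_index_array) for 26-connected same-grey zones."""
    for level in range(1, n_levels + 1):
        lab, n_zones = ndimage.label(grid == level, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        idx = ndimage.value_indices(lab)
        for z in range(1, n_zones + 1):
            yield level, idx[z]


def glszm_matrix(grid: np.ndarray, n_levels: int) -> np.ndarray:
    sizes = []
    for level, vox in _zones(grid, n_levels):
        sizes.append((level, len(vox[0])))
    if not sizes:
        raise ValueError("empty matrix: GLSZM has no zones")
    max_size = max(s for _, s in sizes)
    mat = np.zeros((n_levels, max_size), dtype=float)
    for level, s in sizes:
        mat[level - 1, s - 1] += 1.0
    return mat


def gldzm_matrix(grid: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts by grey level and city-block distance to the ROI edge.

    Edge voxels of the ROI (including those at the image border) have
    distance 1; a zone's distance is the minimum over its voxels.
    """
    roi = grid > 0
    dist = ndimage.distance_transform_cdt(np.pad(roi, 1), metric="taxicab")
    dist = dist[1:-1, 1:-1, 1:-1]
    entries = []
    for level, vox in _zones(grid, n_levels):
        entries.append((level, int(dist[vox].min())))
    if not entries:
        raise ValueError("empty matrix: GLDZM has no zones")
    max_d = max(d for _, d in entries)
    mat = np.zeros((n_levels, max_d), dtype=float)
    for level, d in entries:
        mat[level - 1, d - 1] += 1.0
    return mat


# ---------------------------------------------------------------- NGTDM

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")


def ngtdm_table(grid: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level (n_i, s_i): occupancy and summed deviation from the
    mean grey of the in-ROI 26-neighbourhood."""
    roi = grid > 0
    kernel = np.ones((3, 3, 3)); kernel[1, 1, 1] = 0
    nb_sum = ndimage.correlate(grid.astype(float) * roi, kernel, mode="constant")
    nb_cnt = ndimage.correlate(roi.astype(float), kernel, mode="constant")
    valid = roi & (nb_cnt > 0)
    g = grid[valid].astype(float)
    a = nb_sum[valid] / nb_cnt[valid]
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    np.add.at(n_i, grid[valid] - 1, 1.0)
    np.add.at(s_i, grid[valid] - 1, np.abs(g - a))
    return n_i, s_i


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    n_tot = n_i.sum()
    if n_tot == 0:
        raise ValueError("empty matrix: NGTDM has no valid voxels")
    p = n_i / n_tot
    i = np.arange(1, len(n_i) + 1, dtype=float)
    nz = p > 0
    n_g = int(nz.sum())

    coars_den = float((p * s_i).sum())
    coarseness = 1.0 / coars_den if coars_den > 0 else 1e6

    if n_g > 1:
        p_nz, s_nz, i_nz = p[nz], s_i[nz], i[nz]
        pi_pj = np.add.outer(p_nz, p_nz)
        di = np.subtract.outer(i_nz, i_nz)
        contrast = float((np.outer(p_nz, p_nz) * di**2).sum()
                         / (n_g * (n_g - 1)) * s_i.sum() / n_tot)
        ipi = i_nz * p_nz
        busy_den = float(np.abs(np.subtract.outer(ipi, ipi)).sum())
        busyness = coars_den / busy_den if busy_den > 0 else 0.0
        complexity = float((np.abs(di) * np.add.outer(p_nz * s_nz, p_nz * s_nz)
                            / pi_pj).sum() / n_tot)
        strength = (float((pi_pj * di**2).sum()) / s_i.sum()
                    if s_i.sum() > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ---------------------------------------------------------------- NGLDM

NGLDM_FEATURES = (
    "low_dependence_emphasis", "high_dependence_emphasis",
    "low_grey_level_count_emphasis", "high_grey_level_count_emphasis",
    "low_dependence_low_grey_level_emphasis", "low_dependence_high_grey_level_emphasis",
    "high_dependence_low_grey_level_emphasis", "high_dependence_high_grey_level_emphasis",
    "grey_level_non_uniformity", "grey_level_non_uniformity_normalised",
    "dependence_count_non_uniformity", "dependence_count_non_uniformity_normalised",
    "dependence_count_percentage", "grey_level_variance",
    "dependence_count_variance", "dependence_count_entropy",
    "dependence_count_energy", "dependence_count_mean",
)

_ALL_26 = [(dx, dy, dz)
           for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
           if (dx, dy, dz) != (0, 0, 0)]


def ngldm_matrix(grid: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Counts s(i, j): grey level i, j neighbours within +-alpha grey levels.

    Dependence is counted over the in-ROI 26-neighbourhood; the matrix
    column index used in features is k = j + 1 so that isolated voxels
    (j = 0) carry weight 1.
    """
    roi = grid > 0
    dep = np.zeros(grid.shape, dtype=int)
    for off in _ALL_26:
        sl_a, sl_b = [], []
        for d, n in zip(off, grid.shape):
            if d > 0:
                sl_a.append(slice(0, n - d)); sl_b.append(slice(d, n))
            elif d < 0:
                sl_a.append(slice(-d, n)); sl_b.append(slice(0, n + d))
            else:
                sl_a.append(slice(None)); sl_b.append(slice(None))
        ga, gb = grid[tuple(sl_a)], grid[tuple(sl_b)]
        hit = (ga > 0) & (gb > 0) & (np.abs(ga - gb) <= alpha)
        dep[tuple(sl_a)] += hit
    g = grid[roi] - 1
    j = dep[roi]
    mat = np.zeros((n_levels, int(j.max()) + 1), dtype=float)
    np.add.at(mat, (g, j), 1.0)
    return mat


def ngldm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    ns = mat.sum()
    if ns == 0:
        raise ValueError("empty matrix: NGLDM is empty")
    p = mat / ns
    g = np.arange(1, mat.shape[0] + 1, dtype=float)
    k = np.arange(1, mat.shape[1] + 1, dtype=float)  # dependence count + 1
    gg, kk = np.meshgrid(g, k, indexing="ij")
    mg = mat.sum(axis=1)
    mk = mat.sum(axis=0)
    mu_g = float((gg * p).sum())
    mu_k = float((kk * p).sum())
    return {
        "low_dependence_emphasis": float((mat / kk**2).sum() / ns),
        "high_dependence_emphasis": float((mat * kk**2).sum() / ns),
        "low_grey_level_count_emphasis": float((mat / gg**2).sum() / ns),
        "high_grey_level_count_emphasis": float((mat * gg**2).sum() / ns),
        "low_dependence_low_grey_level_emphasis": float((mat / (gg**2 * kk**2)).sum() / ns),
        "low_dependence_high_grey_level_emphasis": float((mat * gg**2 / kk**2).sum() / ns),
        "high_dependence_low_grey_level_emphasis": float((mat * kk**2 / gg**2).sum() / ns),
        "high_dependence_high_grey_level_emphasis": float((mat * gg**2 * kk**2).sum() / ns),
        "grey_level_non_uniformity": float((mg**2).sum() / ns),
        "grey_level_non_uniformity_normalised": float((mg**2).sum() / ns**2),
        "dependence_count_non_uniformity": float((mk**2).sum() / ns),
        "dependence_count_non_uniformity_normalised": float((mk**2).sum() / ns**2),
        "dependence_count_percentage": float(ns / n_voxels),
        "grey_level_variance": float(((gg - mu_g) ** 2 * p).sum()),
        "dependence_count_variance": float(((kk - mu_k) ** 2 * p).sum()),
        "dependence_count_entropy": float(-_xlog2(p).sum()),
        "dependence_count_energy": float((p**2).sum()),
        "dependence_count_mean": mu_k,
    }


# ---------------------------------------------------------------- roster

def _texture_names() -> tuple[str, ...]:
    names: list[str] = []
    names += [f"glcm_avg/{f}" for f in GLCM_FEATURES]
    names += [f"glcm_merged/{f}" for f in GLCM_FEATURES]
    names += [f"glrlm_avg/{f}" for f in GLRLM_FEATURES]
    names += [f"glrlm_merged/{f}" for f in GLRLM_FEATURES]
    names += [f"glszm/{f}" for f in GLSZM_FEATURES]
    names += [f"gldzm/{f}" for f in GLDZM_FEATURES]
    names += [f"ngtdm/{f}" for f in NGTDM_FEATURES]
    names += [f"ngldm/{f}" for f in NGLDM_FEATURES]
    return tuple(names)


TEXTURE_FEATURE_NAMES = _texture_names()
assert len(TEXTURE_FEATURE_NAMES) == 137


def texture_features(d: DiscretizedROI) -> "OrderedDict[str, float]":
    """All 137 texture features of a discretized ROI."""
    grid, n_levels = d.grid, d.n_bins
    n_vox = int((grid > 0).sum())
    out: OrderedDict[str, float] = OrderedDict()

    per_dir_glcm = []
    merged_glcm = np.zeros((n_levels, n_levels))
    per_dir_rl = {f: [] for f in GLRLM_FEATURES}
    merged_runs: list[np.ndarray] = []
    for off in DIRECTIONS_3D:
        cm = glcm_matrix(grid, n_levels, off)
        if cm.sum() > 0:
            per_dir_glcm.append(glcm_features(cm))
            merged_glcm += cm
        rl = glrlm_matrix(grid, n_levels, off)
        for k, v in _grey_size_features(rl, n_vox, GLRLM_NAMES).items():
            per_dir_rl[k].append(v)
        merged_runs.append(rl)
    if not per_dir_glcm:
        raise ValueError("empty matrix: GLCM has no voxel pairs in any direction")

    for f in GLCM_FEATURES:
        out[f"glcm_avg/{f}"] = float(np.mean([d_[f] for d_ in per_dir_glcm]))
    for f, v in glcm_features(merged_glcm).items():
        out[f"glcm_merged/{f}"] = v
    for f in GLRLM_FEATURES:
        out[f"glrlm_avg/{f}"] = float(np.mean(per_dir_rl[f]))
    max_len = max(m.shape[1] for m in merged_runs)
    pooled = np.zeros((n_levels, max_len))
    for m in merged_runs:
        pooled[:, : m.shape[1]] += m
    for f, v in _grey_size_features(pooled, n_vox * len(DIRECTIONS_3D), GLRLM_NAMES).items():
        out[f"glrlm_merged/{f}"] = v

    for f, v in _grey_size_features(glszm_matrix(grid, n_levels), n_vox, GLSZM_NAMES).items():
        out[f"glszm/{f}"] = v
    for f, v in _grey_size_features(gldzm_matrix(grid, n_levels), n_vox, GLDZM_NAMES).items():
        out[f"gldzm/{f}"] = v
    for f, v in ngtdm_features(*ngtdm_table(grid, n_levels)).items():
        out[f"ngtdm/{f}"] = v
    for f, v in ngldm_features(ngldm_matrix(grid, n_levels), n_vox).items():
        out[f"ngldm/{f}"] = v
    return out
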