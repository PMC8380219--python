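"""Synthetic phantoms, perturbation pairs and outcome-linked cohorts.

No public imaging accession backs this pipeline, so every downstream stage
is exercised on simulated data with known ground truth:

* ellipsoidal tumours with a Gaussian-random-field uptake pattern on a
  lung-like CT background (with a bone insert crossing the mask boundary,
  so the Hounsfield-window exclusion is exercised),
* three perturbation factors emulating the classic PET robustness studies:
  delineation variants (manual-like / threshold / gradient), a smooth
  multiplicative intensity bias standing in for a different attenuation
  correction, and anisotropic respiratory-style blur standing in for
  free-breathing versus gated acquisition,
* cohorts whose binary event-free / overall survival outcomes follow a
  logistic model on known image features, plus a fast tabular cohort
  generator with planted correlated factor blocks for model-recovery
  studies.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .features import FEATURE_NAMES, ExtractionConfig, extract_all
from .volumes import ImageVolume, ROIMask

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "GroundTruth",
    "DEFAULT_PHANTOM",
    "SMALL_PHANTOM",
    "generate_phantom",
    "delineation_variants",
    "attenuation_variant",
    "motion_variant",
    "generate_cohort",
    "simulate_feature_table",
    "pairwise_design_auc",
    "RECOVERY_BETA",
]

#: per-factor log-odds giving a closed-form design AUC of ~0.75 for three
#: independent standard-normal factors driving a logistic outcome
RECOVERY_BETA = 0.6125


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one simulated PET/CT tumour phantom."""

    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_spacing_mm: tuple[float, float, float] = (2.73, 2.73, 3.27)
    tumour_centre_mm: tuple[float, float, float] = (86.0, 86.0, 77.0)
    tumour_radii_mm: tuple[float, float, float] = (24.0, 21.0, 18.0)
    suv_background: float = 0.4
    suv_tumour_mean: float = 5.0
    heterogeneity_scale_mm: float = 12.0
    heterogeneity_amplitude: float = 1.5

    def __post_init__(self):
        if any(n <= 0 for n in self.grid_shape) or any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("grid shape and spacing must be positive")
        if any(r <= 0 for r in self.tumour_radii_mm):
            raise ValueError("tumour radii must be positive")
        if self.suv_background < 0 or self.suv_tumour_mean <= 0:
            raise ValueError("SUV levels must be nonnegative (tumour mean positive)")
        if self.heterogeneity_scale_mm <= 0 or self.heterogeneity_amplitude < 0:
            raise ValueError("heterogeneity parameters out of range")
        for c, r, n, s in zip(self.tumour_centre_mm, self.tumour_radii_mm,
                              self.grid_shape, self.voxel_spacing_mm):
            if c - r < 0 or c + r > (n - 1) * s:
                raise ValueError("tumour outside grid: ellipsoid exceeds the volume extent")


DEFAULT_PHANTOM = PhantomSpec()
#: below the 72-voxel gate after resampling to 5.5 mm
SMALL_PHANTOM = replace(DEFAULT_PHANTOM, tumour_radii_mm=(11.0, 10.0, 9.0))


@dataclass
class GroundTruth:
    """Known quantities of a simulated phantom or cohort."""

    tumour_volume_mm3: float | None = None
    true_mask: ROIMask | None = None
    linear_predictor: np.ndarray | None = None
    design_auc: float | None = None
    designed_robust: tuple[str, ...] = ()


def _coords_mm(spec: PhantomSpec) -> list[np.ndarray]:
    return [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.voxel_spacing_mm)]


def _smooth_field(shape, spacing, scale_mm, rng) -> np.ndarray:
    """Zero-mean, unit-std Gaussian random field with the given correlation length."""
    noise = rng.standard_normal(shape)
    sigma = [scale_mm / s for s in spacing]
    f = ndimage.gaussian_filter(noise, sigma, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, ImageVolume, ROIMask, GroundTruth]:
    """Simulate one PET/CT/mask triplet.

    The PET volume is a uniform background plus an ellipsoidal tumour whose
    interior uptake is a smoothed random field scaled to
    ``suv_tumour_mean +- heterogeneity_amplitude`` and clipped at 0.  The CT
    assigns lung-like HU outside the tumour (-700), soft tissue inside
    (+40), and a bone-like ball (+700) straddling the mask boundary.
    """
    rng = np.random.default_rng(spec.seed)
    x, y, z = np.meshgrid(*_coords_mm(spec), indexing="ij")
    cx, cy, cz = spec.tumour_centre_mm
    rx, ry, rz = spec.tumour_radii_mm
    ell = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
    mask_arr = ell <= 1.0

    pet = np.full(spec.grid_shape, spec.suv_background, dtype=float)
    if spec.heterogeneity_amplitude > 0:
        fld = _smooth_field(spec.grid_shape, spec.voxel_spacing_mm,
                            spec.heterogeneity_scale_mm, rng)
        tumour_vals = spec.suv_tumour_mean + spec.heterogeneity_amplitude * fld[mask_arr]
    else:
        rng.standard_normal(spec.grid_shape)  # keep the stream position stable
        tumour_vals = np.full(int(mask_arr.sum()), spec.suv_tumour_mean)
    pet[mask_arr] = np.clip(tumour_vals, 0.0, None)

    ct = np.full(spec.grid_shape, -700.0)
    ct[mask_arr] = 40.0
    # bone ball centred on the +x boundary point of the ellipsoid
    bx, by, bz = cx + rx, cy, cz
    bone = (x - bx) ** 2 + (y - by) ** 2 + (z - bz) ** 2 <= 9.0**2
    ct[bone] = 700.0

    spacing = spec.voxel_spacing_mm
    truth = GroundTruth(tumour_volume_mm3=float(mask_arr.sum() * np.prod(spacing)),
                        true_mask=ROIMask(mask_arr, spacing))
    return (ImageVolume(pet, spacing, modality="SUV"),
            ImageVolume(ct, spacing, modality="HU"),
            ROIMask(mask_arr, spacing), truth)


# ------------------------------------------------------- perturbations

def _centre_index(mask: ROIMask) -> tuple[int, int, int]:
    return tuple(int(round(c)) for c in np.argwhere(mask.values).mean(axis=0))


def delineation_variants(pet: ImageVolume, mask: ROIMask, threshold_pct: float = 0.34,
                         seed: int = 0) -> tuple[ROIMask, ROIMask, ROIMask]:
    """Three delineation proxies: manual-like, threshold-based, gradient-based.

    * manual-like: the true mask with a one-voxel dilation applied to a
      random half of its outer boundary (seeded),
    * threshold: the 26-connected region of voxels >= ``threshold_pct`` x
      SUVmax grown from the tumour centre (the clinically used range is
      27-41 % of SUVmax),
    * gradient-like: a sphere at the radial position where the mean SUV
      gradient magnitude peaks, seeded at the tumour centre.
    """
    if not 0.27 <= threshold_pct <= 0.41:
        raise ValueError("threshold_pct must lie in [0.27, 0.41]")
    if mask.voxel_count() == 0:
        raise ValueError("empty input mask")
    rng = np.random.default_rng(seed)
    struct = ndimage.generate_binary_structure(3, 3)

    boundary = ndimage.binary_dilation(mask.values, struct) & ~mask.values
    bidx = np.argwhere(boundary)
    take = rng.random(len(bidx)) < 0.5
    manual = mask.values.copy()
    manual[tuple(bidx[take].T)] = True

    suvmax = float(pet.values[mask.values].max())
    level = threshold_pct * suvmax
    above = pet.values >= level
    labels, _ = ndimage.label(above, structure=struct)
    centre = _centre_index(mask)
    lab = labels[centre]
    if lab == 0:
        # fall back to the above-threshold voxel closest to the centre
        cand = np.argwhere(above)
        if len(cand) == 0:
            raise ValueError(f"empty region at threshold {threshold_pct:.2f} x SUVmax")
        near = cand[np.argmin(((cand - np.array(centre)) ** 2).sum(axis=1))]
        lab = labels[tuple(near)]
    threshold_mask = labels == lab

    gx = np.gradient(pet.values, *pet.spacing_mm)
    gmag = np.sqrt(sum(g**2 for g in gx))
    coords = [np.arange(n) * s for n, s in zip(pet.shape, pet.spacing_mm)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cphys = [coords[a][centre[a]] for a in range(3)]
    dist = np.sqrt((xx - cphys[0]) ** 2 + (yy - cphys[1]) ** 2 + (zz - cphys[2]) ** 2)
    rmax = 2.0 * max(np.asarray(mask.spacing_mm) * mask.values.shape) / 2
    edges = np.arange(0.0, rmax, 2.0)
    shell = np.digitize(dist.ravel(), edges)
    sums = np.bincount(shell, weights=gmag.ravel())
    cnts = np.bincount(shell)
    prof = np.where(cnts > 0, sums / np.maximum(cnts, 1), 0.0)
    k = int(np.argmax(prof))  # shell k covers [edges[k-1], edges[k])
    r_star = edges[max(k - 1, 0)] + 1.0
    gradient_mask = dist <= r_star

    return (mask.copy_with(manual), mask.copy_with(threshold_mask),
            mask.copy_with(gradient_mask))


def attenuation_variant(pet: ImageVolume, bias_strength: float = 0.2, seed: int = 0,
                        roi: ROIMask | None = None, scale_mm: float = 25.0,
                        detail_strength: float | None = None,
                        detail_scale_mm: float = 6.0) -> ImageVolume:
    """Multiply the PET volume by a positive bias field (1 +- strength).

    Emulates the intensity shifts between CT- and MR-based attenuation
    correction: a smooth large-scale component (correlation length
    ``scale_mm``) plus a weaker fine-scale component (``detail_scale_mm``,
    amplitude ``detail_strength``, default half the main strength) standing
    in for the locally sharp errors MR-based correction makes near tissue
    boundaries.  When ``roi`` is given, the field is re-centred to mean
    zero over the ROI so the mean tumour uptake is preserved.
    """
    if not 0.0 <= bias_strength <= 0.5:
        raise ValueError("bias_strength must lie in [0, 0.5]")
    if bias_strength == 0.0:
        return pet.copy_with(pet.values.copy())
    if detail_strength is None:
        detail_strength = bias_strength / 2.0
    rng = np.random.default_rng(seed)
    fld = _smooth_field(pet.shape, pet.spacing_mm, scale_mm, rng)
    fld = bias_strength * fld / np.abs(fld).max()
    if detail_strength > 0:
        fine = _smooth_field(pet.shape, pet.spacing_mm, detail_scale_mm, rng)
        fld = fld + detail_strength * fine / np.abs(fine).max()
    if roi is not None:
        fld = fld - fld[roi.values].mean()
    factor = np.clip(1.0 + fld, 0.05, None)
    return pet.copy_with(pet.values * factor)


def motion_variant(pet: ImageVolume, blur_fwhm_mm: tuple[float, float, float]) -> ImageVolume:
    """Anisotropic Gaussian blur emulating respiratory averaging.

    The smoothing is linear and mass preserving (total activity is
    conserved up to truncation at the grid boundary); the unblurred volume
    plays the role of the gated acquisition.
    """
    fwhm = np.asarray(blur_fwhm_mm, dtype=float)
    if np.any(fwhm < 0):
        raise ValueError("blur FWHM must be nonnegative")
    if np.all(fwhm == 0):
        return pet.copy_with(pet.values.copy())
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / np.asarray(pet.spacing_mm)
    out = ndimage.gaussian_filter(pet.values, sigma, mode="constant", cval=0.0)
    return pet.copy_with(out)


# ------------------------------------------------------- cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Design of an outcome-linked synthetic cohort."""

    n_patients: int = 40
    seed: int = 0
    outcome_feature_names: tuple[str, ...] = ("wavelet/HHH/intensity/variance",)
    outcome_coefficients: tuple[float, ...] = (1.0,)
    intercept: float = 0.0
    censoring_rate: float = 0.1
    horizon_months: float = 12.0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if len(self.outcome_feature_names) != len(self.outcome_coefficients):
            raise ValueError("one coefficient per outcome feature required")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must lie in [0, 1]")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")


def pairwise_design_auc(lp: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a case's linear predictor exceeds a control's (ties 1/2)."""
    lp = np.asarray(lp, dtype=float)
    labels = np.asarray(labels).astype(bool)
    cases, controls = lp[labels], lp[~labels]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("design AUC needs both cases and controls")
    diff = cases[:, None] - controls[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def _event_times(p_event: np.ndarray, horizon: float, censor_rate: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exponential event times calibrated so P(T <= horizon) = p_event."""
    p = np.clip(p_event, 1e-9, 1 - 1e-9)
    lam = -np.log1p(-p) / horizon
    t_event = rng.exponential(1.0 / lam)
    if censor_rate > 0:
        lam_c = -np.log1p(-min(censor_rate, 1 - 1e-9)) / horizon
        t_cens = rng.exponential(1.0 / lam_c, size=len(p))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(p), dtype=int)
    return time, event, t_event


def generate_cohort(cspec: CohortSpec, phantom_template: PhantomSpec = DEFAULT_PHANTOM,
                    config: ExtractionConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a cohort of phantoms whose outcomes depend on image features.

    Per patient, the phantom parameters are randomized (seeded), the full
    feature vector is extracted, and the event probability by the horizon
    is ``logistic(intercept + sum coeff x standardized feature)``.  Event
    times are exponential with the matching horizon probability; censoring
    is independent.

    Returns (feature table, outcome table, ground truth); the outcome table
    has columns patient_id, efs_months, efs_event, os_months, os_event.
    """
    unknown = [f for f in cspec.outcome_feature_names if f not in FEATURE_NAMES]
    if unknown:
        raise ValueError(
            f"unknown outcome feature name(s) {unknown}; valid names follow the "
            f"schema family/..., e.g. {FEATURE_NAMES[0]!r}, {FEATURE_NAMES[18]!r}, "
            f"{FEATURE_NAMES[35]!r}, {FEATURE_NAMES[172]!r}")
    ss = np.random.SeedSequence([int(cspec.seed), 2203])
    child = ss.spawn(cspec.n_patients + 1)
    rows = {}
    for i in range(cspec.n_patients):
        rng = np.random.default_rng(child[i])
        for _attempt in range(10):
            radii = tuple(r * rng.uniform(0.8, 1.25) for r in phantom_template.tumour_radii_mm)
            spec = replace(
                phantom_template,
                seed=int(rng.integers(2**31)),
                tumour_radii_mm=radii,
                suv_tumour_mean=phantom_template.suv_tumour_mean * rng.uniform(0.8, 1.3),
                heterogeneity_amplitude=(phantom_template.heterogeneity_amplitude
                                         * rng.uniform(0.7, 1.4)),
                heterogeneity_scale_mm=(phantom_template.heterogeneity_scale_mm
                                        * rng.uniform(0.8, 1.25)),
            )
            pet, ct, mask, _ = generate_phantom(spec)
            res = extract_all(pet, ct, mask, config)
            if not res.excluded:
                rows[f"P{i:03d}"] = res.features
                break
        else:
            raise RuntimeError("could not draw an includable phantom in 10 attempts")
    features = pd.DataFrame(rows).T

    sub = features[list(cspec.outcome_feature_names)]
    sd = sub.std(ddof=0).replace(0.0, 1.0)
    z = (sub - sub.mean()) / sd
    lp = cspec.intercept + z.to_numpy() @ np.asarray(cspec.outcome_coefficients)
    p_event = special.expit(lp)

    rng_out = np.random.default_rng(child[-1])
    efs_t, efs_e, efs_latent = _event_times(p_event, cspec.horizon_months,
                                            cspec.censoring_rate, rng_out)
    p_os = special.expit(lp - 0.7)  # deaths are a subset of events
    os_t, os_e, _ = _event_times(p_os, cspec.horizon_months, cspec.censoring_rate, rng_out)
    outcomes = pd.DataFrame({
        "patient_id": features.index,
        "efs_months": efs_t, "efs_event": efs_e,
        "os_months": os_t, "os_event": os_e,
    }).reset_index(drop=True)

    latent_event = efs_latent <= cspec.horizon_months
    design_auc = (pairwise_design_auc(lp, latent_event)
                  if 0 < latent_event.sum() < len(lp) else None)
    truth = GroundTruth(linear_predictor=lp, design_auc=design_auc,
                        designed_robust=tuple(n for n in FEATURE_NAMES
                                              if n.startswith("shape/")))
    return features, outcomes, truth


def simulate_feature_table(n: int, seed: int, n_factors: int = 3,
                           copies_per_factor: tuple[int, ...] | int = (6, 5, 4),
                           n_noise: int = 10,
                           beta: float = RECOVERY_BETA, intercept: float = 0.0,
                           loading: tuple[float, ...] | float = (0.95, 0.9, 0.85)
                           ) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Fast tabular cohort with planted correlated feature blocks.

    Each latent factor is standard normal and expressed by a block of
    noisy copies (correlation ``loading**2`` between copies); the outcome
    is Bernoulli with logit ``intercept + beta x sum of factors``.  Block
    sizes and loadings differ across factors so the block eigenvalues are
    distinct and the principal components identify the blocks.  Pure-noise
    features are independent standard normals.  Used for
    parameter-recovery and selection studies where image-level simulation
    would be needlessly slow.

    Returns (features, binary outcome, info) where info holds the design
    AUC (pairwise, from the realized linear predictors), the informative
    and noise column names, and the linear predictor.
    """
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n, n_factors))
    copies = ((copies_per_factor,) * n_factors if isinstance(copies_per_factor, int)
              else tuple(copies_per_factor))
    loadings = ((loading,) * n_factors if isinstance(loading, (int, float))
                else tuple(loading))
    if len(copies) != n_factors or len(loadings) != n_factors:
        raise ValueError("need one block size and one loading per factor")
    cols, data = [], []
    info_cols = []
    for k in range(n_factors):
        noise_sd = np.sqrt(max(0.0, 1.0 - loadings[k] ** 2))
        for j in range(copies[k]):
            cols.append(f"factor{k}_copy{j}")
            info_cols.append(cols[-1])
            data.append(loadings[k] * factors[:, k]
                        + noise_sd * rng.standard_normal(n))
    noise_cols = []
    for j in range(n_noise):
        cols.append(f"noise{j}")
        noise_cols.append(cols[-1])
        data.append(rng.standard_normal(n))
    X = pd.DataFrame(np.column_stack(data), columns=cols,
                     index=[f"P{i:03d}" for i in range(n)])
    lp = intercept + beta * factors.sum(axis=1)
    y = pd.Series((rng.random(n) < special.expit(lp)).astype(int), index=X.index,
                  name="event")
    info = {
        "design_auc": pairwise_design_auc(lp, y.to_numpy().astype(bool)),
        "informative": info_cols,
        "noise": noise_cols,
        "linear_predictor": lp,
    }
    return X, y, info
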