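"""End-to-end orchestration: simulate -> extract -> robustness -> model.

A single :class:`RunConfig` (one master seed, hash-chained stage seeds)
drives the whole chain and produces a machine-readable report bundle:
per-study ICC tables with per-family stability percentages, the robust
intersection with Venn counts, per-endpoint model tables for both feature
sets (all features vs robust-only), external validation and Kaplan-Meier
risk stratification.  Every output file gets a sidecar with the config
hash and package version, and identical configs produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import ExtractionConfig, extract_all
from .modelling import (binarize, cross_validate, fit_pipeline, mann_whitney_auc,
                        prognostic_overlap, select_best, stratify_km, validate)
from .robustness import STUDY_ICC_FORM, ICCResult, intersect_stable, run_study
from .synthetic import (DEFAULT_PHANTOM, CohortSpec, PhantomSpec,
                        attenuation_variant, delineation_variants,
                        generate_cohort, generate_phantom, motion_variant)

__all__ = ["RunConfig", "StageError", "run_robustness_studies", "run_all",
           "DEFAULT_OUTCOME_FEATURES", "DEFAULT_OUTCOME_COEFFS"]

VALID_ENDPOINTS = {("efs", 12), ("efs", 18), ("efs", 24),
                   ("os", 12), ("os", 18), ("os", 24)}

# outcome driven by heterogeneity-sensitive wavelet features by default,
# mirroring the prognostic role of uptake heterogeneity
DEFAULT_OUTCOME_FEATURES = ("wavelet/LHL/intensity/coefficient_of_variation",
                            "wavelet/HLH/intensity/skewness")
DEFAULT_OUTCOME_COEFFS = (0.9, -0.6)


class StageError(RuntimeError):
    """Failure of a named pipeline stage."""


@dataclass
class RunConfig:
    """Reproducible configuration of a full pipeline run."""

    seed: int = 0
    n_robustness_patients: int = 12
    n_train: int = 40
    n_val: int = 20
    endpoints: tuple[tuple[str, int], ...] = (("efs", 12), ("efs", 24),
                                              ("os", 12), ("os", 24))
    feature_sets: tuple[str, ...] = ("all", "robust")
    lam: float = 0.5
    rho: float = 0.0
    horn_reps: int = 100
    cv_folds: int = 5
    # perturbation presets
    threshold_pct_range: tuple[float, float] = (0.27, 0.41)
    bias_strength: float = 0.06
    bias_scale_mm: float = 25.0
    bias_detail_strength: float = 0.18
    bias_detail_scale_mm: float = 6.0
    blur_fwhm_xy_mm: tuple[float, float] = (1.0, 3.0)
    blur_fwhm_z_mm: tuple[float, float] = (6.0, 16.0)
    study_icc_form: dict = field(default_factory=lambda: dict(STUDY_ICC_FORM))
    outcome_feature_names: tuple[str, ...] = DEFAULT_OUTCOME_FEATURES
    outcome_coefficients: tuple[float, ...] = DEFAULT_OUTCOME_COEFFS
    outcome_intercept: float = 0.0
    censoring_rate: float = 0.1
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self):
        self.endpoints = tuple((str(o), int(h)) for o, h in self.endpoints)
        bad = [e for e in self.endpoints if e not in VALID_ENDPOINTS]
        if bad:
            raise ValueError(f"unknown endpoint(s) {bad}; valid: sorted EFS/OS at "
                             "12, 18 or 24 months")
        if not set(self.feature_sets) <= {"all", "robust"}:
            raise ValueError("feature_sets must be drawn from {'all', 'robust'}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "endpoints" in raw:
            raw["endpoints"] = tuple(tuple(e) for e in raw["endpoints"])
        if "extraction" in raw:
            raw["extraction"] = ExtractionConfig(**raw["extraction"])
        if "phantom" in raw:
            raw["phantom"] = PhantomSpec(**raw["phantom"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extraction"] = self.extraction.to_dict()
        return json.loads(json.dumps(d, default=list))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % 2**31


def _sidecar(path: Path, config: RunConfig) -> None:
    meta = {"config_hash": config.digest(), "version": __version__,
            "config": config.to_dict()}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True))


def _randomized_phantoms(config: RunConfig, stage: str, n: int):
    """Seeded per-patient phantom specs with randomized size/uptake."""
    ss = np.random.SeedSequence([config.stage_seed(stage)])
    out = []
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        base = config.phantom
        spec = replace(
            base,
            seed=int(rng.integers(2**31)),
            tumour_radii_mm=tuple(r * rng.uniform(0.85, 1.25) for r in base.tumour_radii_mm),
            suv_tumour_mean=base.suv_tumour_mean * rng.uniform(0.7, 1.5),
            heterogeneity_amplitude=base.heterogeneity_amplitude * rng.uniform(0.5, 1.6),
            heterogeneity_scale_mm=base.heterogeneity_scale_mm * rng.uniform(0.8, 1.3),
        )
        out.append((f"R{i:03d}", spec, rng))
    return out


def run_robustness_studies(config: RunConfig) -> dict[str, ICCResult]:
    """Run the three perturbation studies on a seeded phantom set.

    Per patient the delineation study compares three ROI definitions on the
    same image; the attenuation study compares the image with and without a
    patient-specific multiplicative bias; the motion study compares the
    still image with a patient-specific respiratory-style blur (dominant
    along z).  Patients whose perturbed condition fails the size gate are
    dropped from all conditions of that study.
    """
    cfg = config.extraction
    tables: dict[str, dict[str, dict[str, pd.Series]]] = {
        "delineation": {c: {} for c in ("manual", "threshold", "gradient")},
        "attenuation": {c: {} for c in ("ct_based", "mr_based")},
        "motion": {c: {} for c in ("gated", "free_breathing")},
    }
    for pid, spec, rng in _randomized_phantoms(config, "robustness",
                                               config.n_robustness_patients):
        pet, ct, mask, _ = generate_phantom(spec)
        thr = rng.uniform(*config.threshold_pct_range)
        manual, threshold, gradient = delineation_variants(
            pet, mask, threshold_pct=thr, seed=int(rng.integers(2**31)))
        delin = {"manual": manual, "threshold": threshold, "gradient": gradient}
        res_d = {c: extract_all(pet, ct, m, cfg) for c, m in delin.items()}

        base = extract_all(pet, ct, mask, cfg)
        biased = attenuation_variant(pet, config.bias_strength,
                                     seed=int(rng.integers(2**31)), roi=mask,
                                     scale_mm=config.bias_scale_mm,
                                     detail_strength=config.bias_detail_strength,
                                     detail_scale_mm=config.bias_detail_scale_mm)
        res_a = {"ct_based": base, "mr_based": extract_all(biased, ct, mask, cfg)}

        fxy = rng.uniform(*config.blur_fwhm_xy_mm)
        fz = rng.uniform(*config.blur_fwhm_z_mm)
        blurred = motion_variant(pet, (fxy, fxy, fz))
        res_m = {"gated": base, "free_breathing": extract_all(blurred, ct, mask, cfg)}

        for study, res in (("delineation", res_d), ("attenuation", res_a),
                           ("motion", res_m)):
            if all(not r.excluded for r in res.values()):
                for cond, r in res.items():
                    tables[study][cond][pid] = r.features

    results = {}
    for study, conds in tables.items():
        dfs = {c: pd.DataFrame(d).T.sort_index() for c, d in conds.items()}
        n_pat = {c: len(df) for c, df in dfs.items()}
        if min(n_pat.values()) < 2:
            raise StageError(f"robustness ({study}): fewer than 2 usable patients")
        results[study] = run_study(dfs, study=study,
                                   form=config.study_icc_form.get(study))
    return results


def _cohort(config: RunConfig, stage: str, n: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    cspec = CohortSpec(
        n_patients=n,
        seed=config.stage_seed(stage),
        outcome_feature_names=tuple(config.outcome_feature_names),
        outcome_coefficients=tuple(config.outcome_coefficients),
        intercept=config.outcome_intercept,
        censoring_rate=config.censoring_rate,
        horizon_months=12.0,
    )
    features, outcomes, _ = generate_cohort(cspec, config.phantom, config.extraction)
    return features, outcomes


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full chain and write the report bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        studies = run_robustness_studies(config)
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"robustness: {exc}") from exc
    overlap = intersect_stable(studies)
    robust_set = set(overlap["robust_features"])

    rob_dir = out / "robustness"
    rob_dir.mkdir(exist_ok=True)
    stability_summary = {}
    for study, res in studies.items():
        path = rob_dir / f"icc_{study}.csv"
        res.table.to_csv(path, index_label="feature")
        _sidecar(path, config)
        stability_summary[study] = {
            "form": res.form,
            "percent_stable": res.percent_stable(),
            "percent_stable_by_family": res.percent_stable_by_family().to_dict(),
        }
    venn_path = rob_dir / "venn.json"
    venn_path.write_text(json.dumps(
        {k: v for k, v in overlap.items() if k != "robust_features"}, indent=2))
    _sidecar(venn_path, config)

    try:
        feat_tr, out_tr = _cohort(config, "training_cohort", config.n_train)
        feat_va, out_va = _cohort(config, "validation_cohort", config.n_val)
    except Exception as exc:
        raise StageError(f"simulate: {exc}") from exc
    data_dir = out / "cohorts"
    data_dir.mkdir(exist_ok=True)
    for name, df in (("features_training", feat_tr), ("features_validation", feat_va)):
        p = data_dir / f"{name}.csv"
        df.to_csv(p, index_label="patient_id")
        _sidecar(p, config)
    for name, df in (("outcomes_training", out_tr), ("outcomes_validation", out_va)):
        p = data_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        _sidecar(p, config)

    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    model_rows = []
    models = {}
    for outcome, horizon in config.endpoints:
        for fs in config.feature_sets:
            key = f"{outcome}{horizon}_{fs}"
            try:
                y_tr = binarize(out_tr, outcome, horizon)
                cols = ([f for f in feat_tr.columns if f in robust_set]
                        if fs == "robust" else list(feat_tr.columns))
                X = feat_tr[cols]
                seed = config.stage_seed(f"model:{key}")
                model = fit_pipeline(X, y_tr, seed=seed, horn_reps=config.horn_reps,
                                     endpoint=f"{outcome}{horizon}", feature_set=fs)
                cv = cross_validate(X, y_tr, k=config.cv_folds, seed=seed,
                                    horn_reps=config.horn_reps)
                model.cv_auc_mean = cv.mean_auc
                model.cv_auc_range = cv.auc_range
                model.fold_aucs = cv.fold_aucs
                model.risk_cutoff = float(np.median(model.predict(X).to_numpy()))
                models[key] = (model, y_tr)
            except StageError:
                raise
            except ValueError as exc:
                raise StageError(f"modelling ({key}): {exc}") from exc

    # per (outcome, feature set): best-trade-off endpoint validated externally
    validated = {}
    for outcome in sorted({o for o, _ in config.endpoints}):
        for fs in config.feature_sets:
            pool = {k: m for k, (m, _) in models.items()
                    if k.startswith(outcome) and k.endswith(fs)}
            if not pool:
                continue
            best_key = select_best(pool, lam=config.lam)
            model, _ = models[best_key]
            horizon = int("".join(ch for ch in best_key.split("_")[0]
                                  if ch.isdigit()))
            y_va = binarize(out_va, outcome, horizon)
            try:
                auc, ci = validate(model, feat_va, y_va)
                model.validation_auc, model.validation_ci = auc, ci
            except ValueError:
                model.validation_auc, model.validation_ci = None, None
            validated[best_key] = model

    for key, (model, _) in models.items():
        p = model_dir / f"model_{key}.json"
        p.write_text(json.dumps(model.to_dict(), indent=2))
        _sidecar(p, config)
        model_rows.append({
            "model": key, "endpoint": model.endpoint, "feature_set": model.feature_set,
            "n_features": len(model.features),
            "features": ";".join(model.features),
            "cv_auc_mean": model.cv_auc_mean, "cv_auc_range": model.cv_auc_range,
            "validation_auc": model.validation_auc,
        })
    metrics_path = model_dir / "metrics.csv"
    pd.DataFrame(model_rows).sort_values("model").to_csv(metrics_path, index=False)
    _sidecar(metrics_path, config)

    # KM stratification of the best all-features EFS model
    km_summary = None
    efs_keys = [k for k in validated if k.startswith("efs") and k.endswith("all")]
    if efs_keys:
        key = efs_keys[0]
        model = validated[key]
        y_tr = models[key][1]
        probs_tr = model.predict(feat_tr.loc[y_tr.index])
        strat_tr = stratify_km(probs_tr, out_tr, outcome="efs", rho=config.rho)
        probs_va = model.predict(feat_va)
        strat_va = stratify_km(probs_va, out_va, outcome="efs",
                               cutoff=strat_tr.cutoff, rho=config.rho)
        km_dir = out / "km"
        km_dir.mkdir(exist_ok=True)
        for tag, strat in (("training", strat_tr), ("validation", strat_va)):
            for g, curve in strat.km_curves.items():
                p = km_dir / f"km_{tag}_{g}.csv"
                curve.to_csv(p, index=False)
                _sidecar(p, config)
        km_summary = {
            "model": key, "cutoff": strat_tr.cutoff,
            "training": {"p_value": strat_tr.p_value,
                         "median_survival": strat_tr.median_survival},
            "validation": {"p_value": strat_va.p_value,
                           "median_survival": strat_va.median_survival},
        }

    y12_tr = binarize(out_tr, "efs", 12)
    y12_va = binarize(out_va, "efs", 12)
    try:
        overlap_report = prognostic_overlap(
            feat_tr, y12_tr, feat_va, y12_va,
            {s: r.stable_set for s, r in studies.items()})
        overlap_report = {k: v for k, v in overlap_report.items()
                          if k != "prognostic_features"}
    except ValueError:
        overlap_report = {"defined": False}

    summary = {
        "config_hash": config.digest(),
        "version": __version__,
        "stability": stability_summary,
        "fraction_robust": overlap["fraction_robust"],
        "n_robust": overlap["n_robust"],
        "models": sorted(model_rows, key=lambda r: r["model"]),
        "km": km_summary,
        "prognostic_overlap": overlap_report,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _sidecar(out / "summary.json", config)
    return summary
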