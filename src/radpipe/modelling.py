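"""Prognostic modelling of binarized survival endpoints from radiomic features.

The modelling chain follows common radiomics practice for moderate cohorts:

1. binarize event-free / overall survival at a horizon (12, 18 or 24
   months); patients censored before the horizon carry no label and are
   excluded from that endpoint (optionally treated as non-events),
2. group correlated features by principal components, the number of
   retained components chosen by Horn's parallel analysis,
3. per group keep the feature with the largest univariable
   (Mann-Whitney) AUC, retained only if its univariable logistic Wald
   p-value is < 0.05,
4. multivariable logistic regression with backward elimination on AIC,
5. stratified fivefold cross-validation that re-runs the entire selection
   inside each fold, a trade-off model choice (largest mean AUC, smallest
   fold range), frozen-model external validation with a DeLong 95 % CI,
   and Kaplan-Meier risk stratification at the training-median predicted
   probability with a Harrington-Fleming G-rho test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import special, stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "binarize",
    "mann_whitney_auc",
    "horn_components",
    "group_features",
    "univariable_screen",
    "fit_backward_aic",
    "fit_pipeline",
    "cross_validate",
    "select_best",
    "validate",
    "delong_ci",
    "stratify_km",
    "prognostic_overlap",
    "PrognosticModel",
    "CVResult",
    "StratifyResult",
]


# ------------------------------------------------------------ endpoints

def binarize(outcomes: pd.DataFrame, outcome: str = "efs", horizon: float = 12.0,
             censored_as_nonevent: bool = False) -> pd.Series:
    """Event-by-horizon labels from a survival table.

    ``outcomes`` needs columns ``patient_id``, ``<outcome>_months`` and
    ``<outcome>_event``.  Event at or before the horizon -> 1; event-free
    follow-up reaching the horizon -> 0; censored before the horizon ->
    excluded (dropped) unless ``censored_as_nonevent``.
    """
    tcol, ecol = f"{outcome}_months", f"{outcome}_event"
    t = outcomes[tcol].to_numpy(dtype=float)
    e = outcomes[ecol].to_numpy(dtype=int)
    if np.any(t < 0):
        raise ValueError("negative survival times")
    label = np.where((e == 1) & (t <= horizon), 1.0,
                     np.where(t >= horizon, 0.0, np.nan))
    if censored_as_nonevent:
        label = np.where(np.isnan(label), 0.0, label)
    out = pd.Series(label, index=pd.Index(outcomes["patient_id"], name="patient_id"),
                    name=f"{outcome}{int(horizon)}")
    return out.dropna().astype(int)


# ------------------------------------------------------------ AUC

def mann_whitney_auc(x, labels) -> float:
    """AUC as the Mann-Whitney concordance P(case > control), ties 1/2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(x)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _oriented_auc(x, labels) -> float:
    a = mann_whitney_auc(x, labels)
    return max(a, 1.0 - a)


# ------------------------------------------------------------ Horn / PCA

def _standardize(X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = X.to_numpy(dtype=float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (arr - mu) / sd_safe, mu, sd


def _corr_eigenvalues(Z: np.ndarray) -> np.ndarray:
    """Nonzero correlation-matrix eigenvalues via the smaller Gram matrix."""
    n, p = Z.shape
    r = min(n - 1, p)
    if p <= n:
        g = Z.T @ Z / (n - 1)
    else:
        g = Z @ Z.T / (n - 1)
    ev = np.linalg.eigvalsh(g)[::-1]
    return np.clip(ev[:r], 0.0, None)


def horn_components(X: pd.DataFrame | np.ndarray, n_reps: int = 1000,
                    quantile: float = 0.95, seed: int | None = None) -> int:
    """Horn's parallel analysis: retained principal components.

    Components are kept while their correlation-matrix eigenvalue exceeds
    the rank-matched ``quantile`` of eigenvalues from ``n_reps``
    standard-normal datasets of identical shape (counted consecutively
    from the top).
    """
    X = pd.DataFrame(X)
    n, p = X.shape
    if p < 2:
        raise ValueError("parallel analysis needs at least 2 features")
    if n < 3:
        raise ValueError("parallel analysis needs at least 3 subjects")
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    Z, _, _ = _standardize(X)
    obs = _corr_eigenvalues(Z)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_reps, len(obs)))
    for r in range(n_reps):
        Zr = rng.standard_normal((n, p))
        Zr = (Zr - Zr.mean(axis=0)) / Zr.std(axis=0)
        sims[r] = _corr_eigenvalues(Zr)
    thresh = np.quantile(sims, quantile, axis=0)
    keep = 0
    for o, t in zip(obs, thresh):
        if o > t:
            keep += 1
        else:
            break
    return keep


def group_features(X: pd.DataFrame, n_components: int) -> pd.Series:
    """Assign each feature to the retained component it correlates with most.

    Features are standardized; component scores come from the PCA of the
    correlation matrix.  Zero-variance features go to the sentinel group
    -1 and are excluded downstream (with a warning).
    """
    if n_components < 1:
        raise ValueError("need at least one retained component")
    Z, _, sd = _standardize(X)
    m = min(n_components, min(Z.shape[0] - 1, Z.shape[1]))
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    scores = u[:, :m] * s[:m]
    groups = np.empty(X.shape[1], dtype=int)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance feature(s) assigned "
                      "to the degenerate group", stacklevel=2)
    score_sd = scores.std(axis=0)
    score_sd[score_sd == 0] = 1.0
    zc = (scores - scores.mean(axis=0)) / score_sd
    corr = np.abs(Z.T @ zc) / Z.shape[0]
    groups = corr.argmax(axis=1)
    groups[degenerate] = -1
    return pd.Series(groups, index=X.columns, name="group")


# ------------------------------------------------------------ screening

def univariable_screen(X: pd.DataFrame, y: pd.Series, groups: pd.Series,
                       alpha: float = 0.05) -> tuple[list[str], pd.DataFrame]:
    """Per-group surrogate selection with a univariable significance filter.

    In every (non-degenerate) group the feature with the largest oriented
    AUC wins (ties broken lexicographically); it is retained as a candidate
    only if the Wald p-value of its single-feature logistic regression is
    below ``alpha``.  Returns (candidates, per-surrogate statistics).
    """
    yv = y.to_numpy()
    if len(np.unique(yv)) < 2:
        raise ValueError("labels contain a single class")
    rows = []
    candidates = []
    for g in sorted(set(groups) - {-1}):
        members = sorted(groups.index[groups == g])
        aucs = {f: _oriented_auc(X[f].to_numpy(), yv) for f in members}
        best = max(members, key=lambda f: (aucs[f], ))  # lexicographic tie-break
        best = sorted([f for f in members if aucs[f] == aucs[best]])[0]
        p = _wald_p(X[best].to_numpy(), yv)
        keep = bool(p < alpha)
        rows.append({"group": g, "feature": best, "auc": aucs[best], "p": p,
                     "selected": keep})
        if keep:
            candidates.append(best)
    stats_df = pd.DataFrame(rows)
    return candidates, stats_df


def _wald_p(x: np.ndarray, y: np.ndarray) -> float:
    sd = x.std()
    if sd == 0:
        return 1.0
    z = (x - x.mean()) / sd
    design = sm.add_constant(z)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if abs(fit.params[1]) > 10:
            # (near-)complete separation: the Wald statistic collapses
            # (Hauck-Donner); score the feature as maximally significant
            return 0.0
        return float(fit.pvalues[1])
    except Exception:
        return 0.0


# ------------------------------------------------------------ models

@dataclass
class PrognosticModel:
    """A frozen logistic model on standardized features."""

    features: list[str]
    coefficients: np.ndarray
    intercept: float
    means: np.ndarray
    sds: np.ndarray
    aic: float
    endpoint: str = ""
    feature_set: str = "all"
    penalized: bool = False
    cv_auc_mean: float | None = None
    cv_auc_range: float | None = None
    fold_aucs: list[float] | None = None
    validation_auc: float | None = None
    validation_ci: tuple[float, float] | None = None
    risk_cutoff: float | None = None

    def predict(self, X: pd.DataFrame) -> pd.Series:
        if self.features:
            z = (X[self.features].to_numpy(dtype=float) - self.means) / self.sds
            lp = self.intercept + z @ self.coefficients
        else:
            lp = np.full(len(X), self.intercept)
        return pd.Series(special.expit(lp), index=X.index, name="probability")

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "feature_set": self.feature_set,
            "features": list(self.features),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "standardization": {"means": [float(m) for m in self.means],
                                "sds": [float(s) for s in self.sds]},
            "aic": float(self.aic),
            "penalized": self.penalized,
            "cv_auc_mean": self.cv_auc_mean,
            "cv_auc_range": self.cv_auc_range,
            "fold_aucs": self.fold_aucs,
            "validation_auc": self.validation_auc,
            "validation_ci": list(self.validation_ci) if self.validation_ci else None,
            "risk_cutoff": self.risk_cutoff,
        }


def _loglik(y: np.ndarray, lp: np.ndarray) -> float:
    p = np.clip(special.expit(lp), 1e-12, 1 - 1e-12)
    return float((y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def _fit_logit(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """ML logistic fit; returns (params incl. intercept, AIC, penalized_flag)."""
    design = sm.add_constant(Z, has_constant="add")
    k = design.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params, dtype=float)
        if np.all(np.isfinite(params)) and np.abs(params).max() < 1e3:
            return params, float(2 * k - 2 * fit.llf), False
    except Exception:
        pass
    # separation fallback: small ridge penalty, AIC from the penalized params
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, design).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
    params = np.asarray(fit.params, dtype=float)
    aic = 2 * k - 2 * _loglik(y, design @ params)
    return params, float(aic), True


def fit_backward_aic(X: pd.DataFrame, y: pd.Series, candidates: list[str],
                     endpoint: str = "", feature_set: str = "all") -> PrognosticModel:
    """Backward elimination on AIC from the full candidate set.

    At each step the single variable whose removal most decreases the AIC
    is dropped; elimination stops when no removal decreases it.  An empty
    candidate set yields the intercept-only model.  Complete separation is
    handled by a documented ridge-penalized fallback (flagged on the
    model).
    """
    yv = y.to_numpy(dtype=float)
    current = sorted(candidates)
    mu_all = X.mean()
    sd_all = X.std(ddof=0).replace(0.0, 1.0)

    def zmat(feats):
        return ((X[feats] - mu_all[feats]) / sd_all[feats]).to_numpy(dtype=float)

    def fit(feats):
        Z = zmat(feats) if feats else np.empty((len(yv), 0))
        return _fit_logit(Z, yv)

    params, aic, pen = fit(current)
    improved = True
    while improved and current:
        improved = False
        trials = []
        for f in current:
            reduced = [c for c in current if c != f]
            trials.append((fit(reduced), reduced))
        (best_fit, best_feats) = min(trials, key=lambda t: t[0][1])
        if best_fit[1] < aic:
            params, aic, pen = best_fit
            current = best_feats
            improved = True
    return PrognosticModel(
        features=current,
        coefficients=params[1:] if current else np.empty(0),
        intercept=float(params[0]),
        means=mu_all[current].to_numpy(dtype=float),
        sds=sd_all[current].to_numpy(dtype=float),
        aic=aic,
        endpoint=endpoint,
        feature_set=feature_set,
        penalized=pen,
    )


def fit_pipeline(X: pd.DataFrame, y: pd.Series, seed: int = 0,
                 horn_reps: int = 200, horn_quantile: float = 0.95,
                 alpha: float = 0.05, endpoint: str = "",
                 feature_set: str = "all") -> PrognosticModel:
    """Full selection chain: Horn -> PCA grouping -> screening -> backward AIC."""
    Xs = X.loc[y.index]
    if Xs.shape[1] == 0:
        return fit_backward_aic(Xs, y, [], endpoint=endpoint, feature_set=feature_set)
    if Xs.shape[1] == 1:
        groups = pd.Series([0], index=Xs.columns, name="group")
        candidates, _ = univariable_screen(Xs, y, groups, alpha=alpha)
        return fit_backward_aic(Xs, y, candidates, endpoint=endpoint,
                                feature_set=feature_set)
    n_comp = max(1, horn_components(Xs, n_reps=horn_reps, quantile=horn_quantile,
                                    seed=seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        groups = group_features(Xs, n_comp)
    candidates, _ = univariable_screen(Xs, y, groups, alpha=alpha)
    return fit_backward_aic(Xs, y, candidates, endpoint=endpoint,
                            feature_set=feature_set)


# ------------------------------------------------------------ evaluation

@dataclass
class CVResult:
    mean_auc: float
    fold_aucs: list[float]
    auc_range: float


def cross_validate(X: pd.DataFrame, y: pd.Series, k: int = 5, seed: int = 0,
                   **pipeline_kwargs) -> CVResult:
    """Stratified k-fold CV re-running the whole selection per fold."""
    X = X.loc[y.index]
    yv = y.to_numpy()
    counts = np.bincount(yv.astype(int), minlength=2)
    if counts.min() < k:
        raise ValueError(f"a class has fewer than k={k} members; use a smaller k")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs = []
    child = np.random.SeedSequence(seed).spawn(k)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(yv)), yv)):
        Xt, yt = X.iloc[tr], y.iloc[tr]
        model = fit_pipeline(Xt, yt, seed=int(child[fold].generate_state(1)[0] % 2**31),
                             **pipeline_kwargs)
        probs = model.predict(X.iloc[te])
        fold_aucs.append(mann_whitney_auc(probs.to_numpy(), y.iloc[te].to_numpy()))
    return CVResult(mean_auc=float(np.mean(fold_aucs)), fold_aucs=fold_aucs,
                    auc_range=float(np.max(fold_aucs) - np.min(fold_aucs)))


def select_best(models: dict, lam: float = 0.5):
    """Trade-off choice: maximize cv_auc_mean - lam * cv_auc_range.

    ``models`` maps a key to an object with ``cv_auc_mean``/``cv_auc_range``
    attributes (or a (mean, range) tuple).  Ties fall back to the higher
    mean, then to lexicographic key order.
    """
    if not models:
        raise ValueError("no models to select from")

    def stats_of(v):
        if hasattr(v, "cv_auc_mean"):
            return v.cv_auc_mean, v.cv_auc_range
        return v[0], v[1]

    def score(item):
        key, v = item
        mean, rng = stats_of(v)
        return (-(mean - lam * rng), -mean, str(key))

    return min(models.items(), key=score)[0]


def delong_ci(labels: np.ndarray, probs: np.ndarray,
              level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUC and DeLong confidence interval of predicted probabilities."""
    y = np.asarray(labels).astype(bool)
    x = np.asarray(probs, dtype=float)
    cases, controls = x[y], x[~y]
    n1, n0 = len(cases), len(controls)
    if n1 == 0 or n0 == 0:
        raise ValueError("DeLong CI needs both classes present")
    psi = (cases[:, None] > controls[None, :]).astype(float)
    psi += 0.5 * (cases[:, None] == controls[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = (v10.var(ddof=1) / n1 if n1 > 1 else 0.0) + \
          (v01.var(ddof=1) / n0 if n0 > 1 else 0.0)
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def validate(model: PrognosticModel, X: pd.DataFrame, y: pd.Series
             ) -> tuple[float, tuple[float, float]]:
    """Frozen-model AUC and DeLong 95 % CI on an external cohort."""
    if len(np.unique(y.to_numpy())) < 2:
        raise ValueError("validation labels contain a single class")
    probs = model.predict(X.loc[y.index])
    return delong_ci(y.to_numpy(), probs.to_numpy())


# ------------------------------------------------------------ KM stratification

@dataclass
class StratifyResult:
    cutoff: float
    groups: pd.Series           # "high" / "low" per patient
    median_survival: dict
    p_value: float
    test_statistic: float
    km_curves: dict             # group -> DataFrame(time, survival)


def stratify_km(probs: pd.Series, outcomes: pd.DataFrame, outcome: str = "efs",
                cutoff: float | None = None, rho: float = 0.0) -> StratifyResult:
    """Median-split Kaplan-Meier risk stratification with a G-rho test.

    ``cutoff`` defaults to the median of ``probs`` (pass the training-cohort
    cutoff when stratifying a validation cohort).  ``rho=0`` is the
    log-rank test; ``rho=1`` weights early events (Peto-Prentice flavour).
    """
    tcol, ecol = f"{outcome}_months", f"{outcome}_event"
    table = outcomes.set_index("patient_id").loc[probs.index]
    if cutoff is None:
        cutoff = float(np.median(probs.to_numpy()))
    high = probs.to_numpy() > cutoff
    if high.all() or (~high).all():
        raise ValueError("all patients fall on one side of the risk cutoff")
    groups = pd.Series(np.where(high, "high", "low"), index=probs.index, name="risk")

    km_curves, medians = {}, {}
    for g in ("low", "high"):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(table.loc[sel.values, tcol], table.loc[sel.values, ecol], label=g)
        medians[g] = float(kmf.median_survival_time_)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        km_curves[g] = sf

    if rho == 0:
        res = logrank_test(table.loc[~high, tcol], table.loc[high, tcol],
                           table.loc[~high, ecol], table.loc[high, ecol])
    else:
        res = logrank_test(table.loc[~high, tcol], table.loc[high, tcol],
                           table.loc[~high, ecol], table.loc[high, ecol],
                           weightings="fleming-harrington", p=rho, q=0.0)
    return StratifyResult(cutoff=cutoff, groups=groups, median_survival=medians,
                          p_value=float(res.p_value),
                          test_statistic=float(res.test_statistic),
                          km_curves=km_curves)


# ------------------------------------------------------------ overlap report

def prognostic_overlap(X_train: pd.DataFrame, y_train: pd.Series,
                       X_val: pd.DataFrame, y_val: pd.Series,
                       stable_sets: dict[str, set[str]],
                       auc_threshold: float = 0.6) -> dict:
    """Features prognostic in both cohorts, and their per-factor stability.

    A feature is prognostic when its oriented univariable AUC exceeds
    ``auc_threshold`` in both the training and the validation cohort.  For
    each robustness factor the percentage of prognostic features in that
    factor's stable set is reported; an empty prognostic set is flagged.
    """
    yt, yv = y_train.to_numpy(), y_val.to_numpy()
    prognostic = [f for f in X_train.columns
                  if _oriented_auc(X_train[f].loc[y_train.index].to_numpy(), yt) > auc_threshold
                  and _oriented_auc(X_val[f].loc[y_val.index].to_numpy(), yv) > auc_threshold]
    out = {"prognostic_features": prognostic, "n_prognostic": len(prognostic),
           "defined": bool(prognostic), "percent_stable": {}}
    for study, stable in stable_sets.items():
        if prognostic:
            pct = 100.0 * sum(f in stable for f in prognostic) / len(prognostic)
        else:
            pct = 0.0
        out["percent_stable"][study] = pct
    return out
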