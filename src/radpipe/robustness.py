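"""Intraclass-correlation robustness screening of radiomic features.

Each robustness study compares per-patient feature values across measurement
conditions (delineation methods, attenuation corrections, motion states).
Conditions play the role of raters in a subjects x raters ANOVA; a feature
is called stable when its ICC exceeds 0.9 (strictly).

Three Shrout-Fleiss forms are supported:

* ``ICC(1,1)`` — one-way random, single measure: (BMS-WMS)/(BMS+(k-1)WMS)
* ``ICC(3,1)`` — two-way mixed consistency, single measure:
  (BMS-EMS)/(BMS+(k-1)EMS)
* ``ICC(3,k)`` — two-way mixed consistency, average of the k measures:
  (BMS-EMS)/BMS

with BMS/WMS/EMS the between-subject, within-subject and residual mean
squares.  Negative ICCs are kept as computed; they simply fail stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import family_of

__all__ = [
    "ICC_FORMS",
    "STABILITY_THRESHOLD",
    "STUDY_ICC_FORM",
    "icc",
    "ICCResult",
    "run_study",
    "intersect_stable",
]

ICC_FORMS = ("icc11", "icc31", "icc3k")
STABILITY_THRESHOLD = 0.9

#: study -> ICC form mapping (configurable; delineation treats the three
#: methods as random raters, the paired-scan studies as fixed conditions
#: with the motion pair scored as an average measure)
STUDY_ICC_FORM = {"delineation": "icc11", "attenuation": "icc31", "motion": "icc3k"}


def _mean_squares(data: np.ndarray) -> tuple[float, float, float, int]:
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_within = ((data - row_means[:, None]) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    wms = ss_within / (n * (k - 1))
    ems = ss_err / ((n - 1) * (k - 1))
    return bms, wms, ems, k


def icc(data: np.ndarray, form: str = "icc31", warn_constant: bool = True) -> float:
    """ICC of a subjects x raters matrix for the requested form.

    All-identical data is defined as perfect agreement (ICC = 1, with a
    warning); missing values are rejected.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("ICC needs at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(data)):
        raise ValueError("ICC input contains missing or non-finite cells")
    if form not in ICC_FORMS:
        raise ValueError(f"unknown ICC form {form!r}; expected one of {ICC_FORMS}")
    if np.ptp(data) == 0:
        if warn_constant:
            warnings.warn("all values identical; ICC defined as 1", stacklevel=2)
        return 1.0
    bms, wms, ems, k = _mean_squares(data)
    if form == "icc11":
        denom = bms + (k - 1) * wms
        return float((bms - wms) / denom) if denom > 0 else 1.0
    if form == "icc31":
        denom = bms + (k - 1) * ems
        return float((bms - ems) / denom) if denom > 0 else 1.0
    return float((bms - ems) / bms) if bms > 0 else 1.0


@dataclass
class ICCResult:
    """Per-feature ICCs of one robustness study."""

    study: str
    form: str
    table: pd.DataFrame  # columns: icc, stable (indexed by feature)

    @property
    def stable_set(self) -> set[str]:
        return set(self.table.index[self.table["stable"]])

    def percent_stable_by_family(self) -> pd.Series:
        fams = self.table.index.map(family_of)
        return (self.table.groupby(fams)["stable"].mean() * 100.0).rename("percent_stable")

    def percent_stable(self) -> float:
        return float(self.table["stable"].mean() * 100.0)


def run_study(tables: dict[str, pd.DataFrame] | list[pd.DataFrame],
              study: str = "delineation", form: str | None = None,
              threshold: float = STABILITY_THRESHOLD) -> ICCResult:
    """Per-feature ICC across condition feature tables (patients x features).

    ``tables`` holds one table per condition; all tables must share the
    same patients and features.  The ICC form defaults to the study's
    entry in :data:`STUDY_ICC_FORM`.
    """
    tabs = list(tables.values()) if isinstance(tables, dict) else list(tables)
    if len(tabs) < 2:
        raise ValueError("a robustness study needs at least 2 conditions")
    first = tabs[0]
    for t in tabs[1:]:
        if not t.index.equals(first.index) or not t.columns.equals(first.columns):
            raise ValueError("condition tables must share patients and features")
    form = form or STUDY_ICC_FORM.get(study, "icc31")
    cube = np.stack([t.to_numpy(dtype=float) for t in tabs], axis=2)  # n x p x k
    iccs = np.empty(cube.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features are defined as ICC 1
        for j in range(cube.shape[1]):
            iccs[j] = icc(cube[:, j, :], form)
    table = pd.DataFrame({"icc": iccs, "stable": iccs > threshold}, index=first.columns)
    return ICCResult(study=study, form=form, table=table)


def intersect_stable(results: dict[str, ICCResult] | list[ICCResult]) -> dict:
    """Features stable in all three studies, plus the 7 Venn region counts.

    Venn regions are keyed by sorted study-name combinations (e.g.
    ``"delineation&motion"`` for features stable in exactly those two).
    Returns overall counts and per-family breakdowns.
    """
    res = list(results.values()) if isinstance(results, dict) else list(results)
    if len(res) != 3:
        raise ValueError("intersection is defined over exactly 3 studies")
    names = [r.study for r in res]
    sets = {r.study: r.stable_set for r in res}
    universe = set(res[0].table.index)

    def regions(pool: set[str]) -> dict[str, int]:
        out = {}
        for code in range(1, 8):
            members = [names[i] for i in range(3) if code >> i & 1]
            region = pool.copy()
            for nm in names:
                s = sets[nm] & pool
                region &= s if nm in members else (pool - s)
            out["&".join(sorted(members))] = len(region)
        return out

    robust = sets[names[0]] & sets[names[1]] & sets[names[2]]
    by_family: dict[str, dict[str, int]] = {}
    fams = pd.Index(sorted(universe)).map(family_of)
    for fam in sorted(set(fams)):
        pool = {f for f in universe if family_of(f) == fam}
        by_family[fam] = regions(pool)
    return {
        "robust_features": sorted(robust),
        "n_robust": len(robust),
        "fraction_robust": len(robust) / len(universe) if universe else 0.0,
        "venn": regions(universe),
        "venn_by_family": by_family,
    }
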