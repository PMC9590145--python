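"""Study-level analytic surface: exposure grouping, oral-self-care splits,
group-specific fits, stratified analyses and report tables.

The exposure is the questionnaire count of remaining teeth, collapsed from
six levels into three groups (0-9, 10-19, >=20).  Oral self-care analyses
split the two low-teeth groups by whether a care measure is practiced
(brushing at least twice daily, denture use, or regular dental checkups),
giving five cells; the >=20 group is never split.  Every analysis runs
separately by sex, and each cell gets its own independently fitted
transition model — stratification replaces covariate adjustment.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .lifetable import confidence_intervals
from .model import TransitionModel
from .panel import PanelDataset, PanelRecord, round_half_up
from .states import HealthState

__all__ = [
    "ExposureGroup",
    "OralCareSplit",
    "AnalysisSettings",
    "assign_teeth_group",
    "assign_care_category",
    "run_group_analysis",
    "baseline_table",
]

TEETH_GROUPS = ("0-9", "10-19", ">=20")

_SIX_TO_THREE = {
    "none": "0-9",
    "few": "0-9",
    "about_half": "10-19",
    "moderate": ">=20",
    "most": ">=20",
    "all": ">=20",
}

CARE_MEASURES = ("brushing_ge2", "dentures", "checkups")

#: The five oral-self-care analysis cells.
CARE_CATEGORY_LABELS = {
    1: "0-9 teeth, non-practicing",
    2: "0-9 teeth, practicing",
    3: "10-19 teeth, non-practicing",
    4: "10-19 teeth, practicing",
    5: ">=20 teeth",
}

STRATA_LEVELS = {
    "smoking": ("never_former", "current"),
    "bmi_class": ("normal", "abnormal"),
    "walking": ("ge_half_hour", "lt_half_hour"),
    "education": ("high", "low"),
}


@dataclasses.dataclass(frozen=True)
class ExposureGroup:
    label: str  # "0-9" | "10-19" | ">=20"

    def __post_init__(self):
        if self.label not in TEETH_GROUPS:
            raise ValueError(f"unknown exposure group {self.label!r}")


@dataclasses.dataclass(frozen=True)
class OralCareSplit:
    care_measure: str
    category: int  # 1..5

    @property
    def label(self) -> str:
        return CARE_CATEGORY_LABELS[self.category]


def assign_teeth_group(teeth_category: str) -> str:
    """Collapse a six-level questionnaire response into the 3-group exposure."""
    try:
        return _SIX_TO_THREE[teeth_category]
    except KeyError:
        raise ValueError(
            f"teeth_category {teeth_category!r} is not one of the six levels"
        ) from None


def _practices(record: PanelRecord, care_measure: str) -> Optional[bool]:
    if care_measure == "brushing_ge2":
        if record.brushing_per_day is None:
            return None
        return record.brushing_per_day >= 2
    if care_measure == "dentures":
        return record.dentures
    if care_measure == "checkups":
        return record.checkups
    raise ValueError(f"unknown care measure {care_measure!r}")


def assign_care_category(
    record: PanelRecord, care_measure: str
) -> Optional[OralCareSplit]:
    """Five-way oral-self-care category, or None when the care value is
    missing in a splittable (0-9 / 10-19) group — such records are excluded
    with a count, never guessed."""
    group = assign_teeth_group(record.teeth_category)
    if group == ">=20":
        return OralCareSplit(care_measure, 5)
    practicing = _practices(record, care_measure)
    if practicing is None:
        return None
    base = 1 if group == "0-9" else 3
    return OralCareSplit(care_measure, base + (1 if practicing else 0))


@dataclasses.dataclass
class AnalysisSettings:
    """Reporting defaults for group analyses (start age 65, monthly chain)."""

    start_age: float = 65.0
    max_age: float = 110.0
    initial_state: HealthState = HealthState.NONDISABLED
    n_draws: int = 2000
    seed: int = 0
    min_cell_size: int = 50
    step_months: float = 1.0
    estimate_slopes: bool = True


def _cell_label(record: PanelRecord, grouping: str) -> Optional[str]:
    if grouping == "teeth3":
        return assign_teeth_group(record.teeth_category)
    if grouping.startswith("care5:"):
        split = assign_care_category(record, grouping.split(":", 1)[1])
        return None if split is None else split.label
    if grouping == "all":
        return "all"
    raise ValueError(f"unknown grouping {grouping!r}")


def run_group_analysis(
    dataset: PanelDataset,
    grouping: str = "teeth3",
    stratify: Optional[str] = None,
    settings: Optional[AnalysisSettings] = None,
) -> tuple[pd.DataFrame, dict]:
    """Fit the transition model and life table independently per cell.

    ``grouping`` is ``"teeth3"``, ``"care5:<measure>"`` or ``"all"``;
    ``stratify`` optionally adds a lifestyle stratum (records with a missing
    stratum value are excluded and counted).  Cells are always sex-specific.
    Returns a report table (one row per cell, DFLE/DLE/TLE with 95% CIs) and
    a dict of the per-cell (fit, life table) objects.  Cells below the
    minimum size or failing to fit are reported as such, never fatal.
    """
    settings = settings or AnalysisSettings()
    cells: dict[tuple, list[PanelRecord]] = {}
    n_excluded_missing = 0
    for rec in dataset:
        label = _cell_label(rec, grouping)
        if label is None:
            n_excluded_missing += 1
            continue
        key = (rec.sex, label)
        if stratify is not None:
            level = getattr(rec, stratify)
            if level is None:
                n_excluded_missing += 1
                continue
            key = key + (level,)
        cells.setdefault(key, []).append(rec)

    rows = []
    detail: dict[tuple, tuple] = {}
    for i, key in enumerate(sorted(cells)):
        recs = cells[key]
        row = {"sex": key[0], "group": key[1]}
        if stratify is not None:
            row[stratify] = key[2]
        row["n"] = len(recs)
        cell_seed = (settings.seed * 1_000_003 + i) % (2**31)
        if len(recs) < settings.min_cell_size:
            row["note"] = f"cell below minimum size ({settings.min_cell_size})"
            rows.append(row)
            continue
        try:
            fit = TransitionModel(PanelDataset(records=recs)).fit(
                estimate_slopes=settings.estimate_slopes
            )
            lt = confidence_intervals(
                fit,
                start_age=settings.start_age,
                max_age=settings.max_age,
                initial_state=settings.initial_state,
                n_draws=settings.n_draws,
                seed=cell_seed,
                step_months=settings.step_months,
            )
        except ValueError as e:
            row["note"] = f"fit failed: {e}"
            rows.append(row)
            continue
        row.update(
            DFLE=lt.dfle,
            DFLE_lo=lt.ci_95["DFLE"][0],
            DFLE_hi=lt.ci_95["DFLE"][1],
            DLE=lt.dle,
            DLE_lo=lt.ci_95["DLE"][0],
            DLE_hi=lt.ci_95["DLE"][1],
            TLE=lt.tle,
            TLE_lo=lt.ci_95["TLE"][0],
            TLE_hi=lt.ci_95["TLE"][1],
            converged=fit.convergence["converged"],
        )
        if fit.convergence["non_identifiable"]:
            row["note"] = "non-identifiable: " + ",".join(
                fit.convergence["non_identifiable"]
            )
        rows.append(row)
        detail[key] = (fit, lt)
    report = pd.DataFrame(rows)
    report.attrs["n_excluded_missing"] = n_excluded_missing
    report.attrs["grouping"] = grouping
    report.attrs["stratify"] = stratify
    return report, detail


def _pct(series: pd.Series, predicate) -> tuple[float, int]:
    """Percentage of non-missing values satisfying predicate, and n missing."""
    present = series[series.notna()]
    n_missing = int(series.isna().sum())
    if len(present) == 0:
        return float("nan"), n_missing
    return round_half_up(100.0 * predicate(present).mean()), n_missing


def baseline_table(dataset: PanelDataset) -> pd.DataFrame:
    """Descriptive baseline summary per teeth group (missing excluded per column)."""
    from .panel import to_dataframe

    df = to_dataframe(dataset)
    rows = []
    for group in TEETH_GROUPS:
        sub = df[df["teeth_group"] == group]
        if len(sub) == 0:
            rows.append({"teeth_group": group, "n": 0})
            continue
        age = sub["baseline_age"]
        row = {
            "teeth_group": group,
            "n": len(sub),
            "age_mean": round_half_up(float(age.mean())),
            "age_sd": round_half_up(float(age.std(ddof=1))) if len(sub) > 1 else float("nan"),
            "male_pct": round_half_up(100.0 * (sub["sex"] == "male").mean()),
        }
        for col, name, pred in (
            ("dentures", "dentures_pct", lambda s: s.astype(bool)),
            ("checkups", "checkups_pct", lambda s: s.astype(bool)),
            ("brushing_per_day", "brushing_ge2_pct", lambda s: s >= 2),
            ("smoking", "current_smoker_pct", lambda s: s == "current"),
            ("bmi_class", "bmi_abnormal_pct", lambda s: s == "abnormal"),
            ("walking", "walking_lt_half_pct", lambda s: s == "lt_half_hour"),
            ("education", "education_high_pct", lambda s: s == "high"),
        ):
            pct, n_missing = _pct(sub[col], pred)
            row[name] = pct
            row[f"{name}_missing"] = n_missing
        rows.append(row)
    return pd.DataFrame(rows)
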