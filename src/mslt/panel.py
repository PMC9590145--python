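"""Panel-data containers, readers/writers, exclusion cascade and accounting.

The unit of data is one participant: baseline covariates plus a dated
sequence of health-state observations (months since baseline), with death
and emigration recorded as dated terminal events.  Two CSV dialects are
supported:

``tidy_long``
    one row per (participant, observation); per-participant constants
    (covariates, death/emigration months) repeated on every row.
``wide_wave``
    one row per participant with wave columns ``state_m<month>`` whose
    names carry the wave schedule (e.g. ``state_m0, state_m12, ...``).

Death is encoded both as a ``death_month`` column and as a final state-3
observation row at that month; the two encodings are normalised on read so
that :attr:`PanelRecord.observations` holds living-state observations only.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

from .states import HealthState

__all__ = [
    "PanelRecord",
    "PanelDataset",
    "ExclusionLog",
    "PanelFormatError",
    "PanelValidationError",
    "read_panel",
    "write_panel",
    "apply_exclusions",
    "outcome_distribution",
    "follow_up_rate",
    "to_dataframe",
    "round_half_up",
]

#: Six-level questionnaire response on remaining teeth.
TEETH_LEVELS = ("none", "few", "about_half", "moderate", "most", "all")

_COVARIATE_COLUMNS = (
    "teeth_category",
    "brushing_per_day",
    "dentures",
    "checkups",
    "smoking",
    "bmi_class",
    "walking",
    "education",
)
_FLAG_COLUMNS = ("consent", "baseline_disabled", "prefollowup_loss")


class PanelFormatError(ValueError):
    """A file does not conform to the declared CSV dialect."""


class PanelValidationError(ValueError):
    """One or more records violate panel invariants."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed cohort tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class PanelRecord:
    """One participant's covariates and observation history.

    ``observations`` holds (month, state) pairs for *living* states only,
    strictly increasing in time, with month 0 present for analysis-eligible
    records.  ``death_month``/``emigration_month`` are months since baseline.
    Missing covariates are ``None``.
    """

    participant_id: str
    sex: str  # "male" | "female"
    baseline_age: float  # years
    observations: list[tuple[int, HealthState]] = dataclasses.field(default_factory=list)
    death_month: Optional[int] = None
    emigration_month: Optional[int] = None
    consent: bool = True
    baseline_disabled: bool = False
    prefollowup_loss: bool = False  # died or moved before follow-up start
    teeth_category: Optional[str] = None
    brushing_per_day: Optional[int] = None
    dentures: Optional[bool] = None
    checkups: Optional[bool] = None
    smoking: Optional[str] = None  # never_former | current
    bmi_class: Optional[str] = None  # normal | abnormal
    walking: Optional[str] = None  # ge_half_hour | lt_half_hour
    education: Optional[str] = None  # high | low

    def validate(self) -> list[str]:
        """Return invariant violations (empty list when the record is valid)."""
        errs: list[str] = []
        pid = self.participant_id
        months = [m for m, _ in self.observations]
        if any(b <= a for a, b in zip(months, months[1:])):
            errs.append(f"{pid}: observation times not strictly increasing")
        if any(s == HealthState.DEAD for _, s in self.observations):
            errs.append(f"{pid}: DEAD retained among living observations")
        if self.death_month is not None:
            if any(m >= self.death_month for m in months):
                errs.append(f"{pid}: observation at or after death_month")
            if self.emigration_month is not None:
                errs.append(f"{pid}: both death and emigration recorded")
        if self.emigration_month is not None and any(
            m > self.emigration_month for m in months
        ):
            errs.append(f"{pid}: observation after emigration_month")
        if self.teeth_category is not None and self.teeth_category not in TEETH_LEVELS:
            errs.append(f"{pid}: unknown teeth_category {self.teeth_category!r}")
        return errs

    @property
    def last_living_state(self) -> Optional[HealthState]:
        return self.observations[-1][1] if self.observations else None

    def outcome(self) -> str:
        """End-of-follow-up outcome class for accounting tables."""
        if self.death_month is not None:
            return "dead"
        if self.emigration_month is not None:
            return "emigrated"
        if not self.observations:
            raise PanelValidationError(
                [f"{self.participant_id}: no observations and no terminal event"]
            )
        return (
            "non-disabled"
            if self.last_living_state == HealthState.NONDISABLED
            else "disabled"
        )


@dataclasses.dataclass
class PanelDataset:
    records: list[PanelRecord]
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.participant_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise PanelValidationError(["duplicate participant_id values"])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self) -> None:
        errs: list[str] = []
        for r in self.records:
            errs.extend(r.validate())
        if errs:
            raise PanelValidationError(errs)


@dataclasses.dataclass
class ExclusionLog:
    """Ordered accounting of an exclusion cascade (flowchart-style)."""

    steps: list[tuple[str, int, int]]  # (criterion_label, n_removed, n_remaining)

    @property
    def final_n(self) -> int:
        return self.steps[-1][2] if self.steps else 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["criterion", "n_removed", "n_remaining"]
        )


# ---------------------------------------------------------------------------
# readers / writers


def _parse_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    if isinstance(v, str):
        return {"yes": True, "no": False, "1": True, "0": False,
                "true": True, "false": False}[v.strip().lower()]
    return bool(v)


def _fmt_bool(v: Optional[bool]) -> str:
    return "" if v is None else ("yes" if v else "no")


def _opt(v):
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return v


def _record_constants(rec: PanelRecord) -> dict:
    return {
        "participant_id": rec.participant_id,
        "sex": rec.sex,
        "baseline_age": rec.baseline_age,
        "death_month": "" if rec.death_month is None else rec.death_month,
        "emigration_month": ""
        if rec.emigration_month is None
        else rec.emigration_month,
        "consent": _fmt_bool(rec.consent),
        "baseline_disabled": _fmt_bool(rec.baseline_disabled),
        "prefollowup_loss": _fmt_bool(rec.prefollowup_loss),
        "teeth_category": rec.teeth_category or "",
        "brushing_per_day": ""
        if rec.brushing_per_day is None
        else rec.brushing_per_day,
        "dentures": _fmt_bool(rec.dentures),
        "checkups": _fmt_bool(rec.checkups),
        "smoking": rec.smoking or "",
        "bmi_class": rec.bmi_class or "",
        "walking": rec.walking or "",
        "education": rec.education or "",
    }


def _constants_from_row(row: pd.Series) -> dict:
    brushing = _opt(row.get("brushing_per_day"))
    return dict(
        participant_id=str(row["participant_id"]),
        sex=str(row["sex"]),
        baseline_age=float(row["baseline_age"]),
        death_month=None
        if _opt(row.get("death_month")) is None
        else int(row["death_month"]),
        emigration_month=None
        if _opt(row.get("emigration_month")) is None
        else int(row["emigration_month"]),
        consent=_parse_bool(row.get("consent")) is not False,
        baseline_disabled=_parse_bool(row.get("baseline_disabled")) is True,
        prefollowup_loss=_parse_bool(row.get("prefollowup_loss")) is True,
        teeth_category=_opt(row.get("teeth_category")),
        brushing_per_day=None if brushing is None else int(brushing),
        dentures=_parse_bool(row.get("dentures")),
        checkups=_parse_bool(row.get("checkups")),
        smoking=_opt(row.get("smoking")),
        bmi_class=_opt(row.get("bmi_class")),
        walking=_opt(row.get("walking")),
        education=_opt(row.get("education")),
    )


def read_panel(path, dialect: str = "tidy_long") -> PanelDataset:
    """Read a panel CSV file, enforcing all record invariants.

    Malformed rows raise :class:`PanelValidationError` naming the offending
    participants; a missing required column raises :class:`PanelFormatError`
    naming the column.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    if dialect == "tidy_long":
        required = ["participant_id", "sex", "baseline_age", "month", "state"]
    elif dialect == "wide_wave":
        required = ["participant_id", "sex", "baseline_age"]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in required:
        if col not in df.columns:
            raise PanelFormatError(f"missing required column: {col}")

    records: list[PanelRecord] = []
    errs: list[str] = []
    if dialect == "tidy_long":
        for pid, grp in df.groupby("participant_id", sort=False):
            grp = grp.sort_values("month")
            consts = _constants_from_row(grp.iloc[0])
            obs: list[tuple[int, HealthState]] = []
            for _, row in grp.iterrows():
                month, state = int(row["month"]), HealthState(int(row["state"]))
                if state == HealthState.DEAD:
                    # dead row encodes the dated death event
                    if consts["death_month"] is None:
                        consts["death_month"] = month
                    elif consts["death_month"] != month:
                        errs.append(f"{pid}: DEAD row at {month} contradicts "
                                    f"death_month {consts['death_month']}")
                else:
                    if consts["death_month"] is not None and month > consts["death_month"]:
                        errs.append(f"{pid}: living state observed after death")
                    obs.append((month, state))
            rec = PanelRecord(observations=obs, **consts)
            rec_errs = rec.validate()
            if rec_errs:
                errs.extend(rec_errs)
            else:
                records.append(rec)
    else:  # wide_wave
        wave_cols = [c for c in df.columns if c.startswith("state_m")]
        if not wave_cols:
            raise PanelFormatError("missing required column: state_m<month>")
        try:
            schedule = sorted((int(c[len("state_m"):]), c) for c in wave_cols)
        except ValueError as e:
            raise PanelFormatError(f"malformed wave column name: {e}") from e
        for _, row in df.iterrows():
            consts = _constants_from_row(row)
            pid = consts["participant_id"]
            obs = []
            for month, col in schedule:
                v = _opt(row[col])
                if v is None:
                    continue
                state = HealthState(int(v))
                if state == HealthState.DEAD:
                    if consts["death_month"] is None:
                        consts["death_month"] = month
                else:
                    obs.append((month, state))
            rec = PanelRecord(observations=obs, **consts)
            rec_errs = rec.validate()
            if rec_errs:
                errs.extend(rec_errs)
            else:
                records.append(rec)
    if errs:
        raise PanelValidationError(errs)
    return PanelDataset(records=records)


def write_panel(dataset: PanelDataset, path, dialect: str = "tidy_long") -> None:
    """Write a panel CSV (UTF-8, comma-separated, header row)."""
    rows: list[dict] = []
    if dialect == "tidy_long":
        for rec in dataset:
            consts = _record_constants(rec)
            emitted = False
            for month, state in rec.observations:
                rows.append({**consts, "month": month, "state": int(state)})
                emitted = True
            if rec.death_month is not None:
                rows.append(
                    {**consts, "month": rec.death_month, "state": int(HealthState.DEAD)}
                )
                emitted = True
            if not emitted:
                raise PanelValidationError(
                    [f"{rec.participant_id}: nothing to write (no observations)"]
                )
        cols = ["participant_id", "sex", "baseline_age", "month", "state"] + [
            c
            for c in _record_constants(dataset.records[0])
            if c not in ("participant_id", "sex", "baseline_age")
        ] if dataset.records else []
        df = pd.DataFrame(rows)
        if dataset.records:
            df = df[cols]
    elif dialect == "wide_wave":
        months = sorted(
            {m for rec in dataset for m, _ in rec.observations}
            | {rec.death_month for rec in dataset if rec.death_month is not None}
        )
        for rec in dataset:
            row = _record_constants(rec)
            for m in months:
                row[f"state_m{m}"] = ""
            for m, s in rec.observations:
                row[f"state_m{m}"] = int(s)
            if rec.death_month is not None:
                row[f"state_m{rec.death_month}"] = int(HealthState.DEAD)
            rows.append(row)
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# exclusion cascade and accounting

#: Fixed cascade order; a doubly-excludable record counts at its first match.
EXCLUSION_CRITERIA = (
    ("no consent for LTCI review", lambda r: not r.consent),
    ("disability certified before follow-up", lambda r: r.baseline_disabled),
    ("died or moved before follow-up", lambda r: r.prefollowup_loss),
    ("missing number of remaining teeth", lambda r: r.teeth_category is None),
)


def apply_exclusions(dataset: PanelDataset) -> tuple[PanelDataset, ExclusionLog]:
    """Apply the study's exclusion cascade, logging counts at each step."""
    remaining = list(dataset.records)
    steps: list[tuple[str, int, int]] = []
    for label, predicate in EXCLUSION_CRITERIA:
        kept = [r for r in remaining if not predicate(r)]
        steps.append((label, len(remaining) - len(kept), len(kept)))
        remaining = kept
    return (
        PanelDataset(records=remaining, metadata=dict(dataset.metadata)),
        ExclusionLog(steps=steps),
    )


def to_dataframe(dataset: PanelDataset) -> pd.DataFrame:
    """One row per participant: covariates plus the end-of-follow-up outcome."""
    from .study import assign_teeth_group  # derived grouping column

    rows = []
    for rec in dataset:
        row = {
            "participant_id": rec.participant_id,
            "sex": rec.sex,
            "baseline_age": rec.baseline_age,
            "teeth_category": rec.teeth_category,
            "teeth_group": (
                assign_teeth_group(rec.teeth_category)
                if rec.teeth_category is not None
                else None
            ),
            "brushing_per_day": rec.brushing_per_day,
            "dentures": rec.dentures,
            "checkups": rec.checkups,
            "smoking": rec.smoking,
            "bmi_class": rec.bmi_class,
            "walking": rec.walking,
            "education": rec.education,
            "outcome": rec.outcome(),
        }
        rows.append(row)
    return pd.DataFrame(rows)


OUTCOME_ORDER = ("non-disabled", "disabled", "dead", "emigrated")


def outcome_distribution(
    dataset: PanelDataset, by: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """End-of-follow-up outcome counts and within-group percentages.

    ``by`` names grouping columns of :func:`to_dataframe` (e.g. ``["sex",
    "teeth_group"]``).  Percentages are rounded half-up to one decimal.
    """
    df = to_dataframe(dataset)
    keys = list(by) if by else []
    out_rows = []
    groups = df.groupby(keys, sort=True) if keys else [((), df)]
    for key, grp in groups:
        if keys and not isinstance(key, tuple):
            key = (key,)
        n = len(grp)
        counts = grp["outcome"].value_counts()
        for outcome in OUTCOME_ORDER:
            c = int(counts.get(outcome, 0))
            out_rows.append(
                dict(zip(keys, key))
                | {
                    "outcome": outcome,
                    "n": c,
                    "pct": round_half_up(100.0 * c / n) if n else float("nan"),
                }
            )
        out_rows.append(dict(zip(keys, key)) | {"outcome": "total", "n": n, "pct": 100.0})
    return pd.DataFrame(out_rows)


def follow_up_rate(dataset: PanelDataset) -> float:
    """Percentage of participants not lost to emigration, one decimal."""
    n = len(dataset)
    if n == 0:
        raise PanelValidationError(["follow-up rate undefined for empty dataset"])
    n_emig = sum(
        1
        for r in dataset
        if r.emigration_month is not None and r.death_month is None
    )
    return round_half_up(100.0 * (n - n_emig) / n)
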