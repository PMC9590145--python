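"""Synthetic reconstructions of the study's published accounting tables.

The original cohort's individual-level records are not public.  These
builders construct *synthetic* stand-in datasets that encode only the
published marginal counts — the participant-flow (exclusion cascade) totals
and the end-of-follow-up outcome distribution by sex and teeth group — so
the package's accounting operations can recompute the printed figures.
No record here corresponds to a real person; timing details (e.g. the month
a death is dated) are arbitrary placeholders that do not enter the counts.
"""

from __future__ import annotations

from .panel import PanelDataset, PanelRecord
from .states import HealthState

__all__ = [
    "EXCLUSION_FLOW",
    "OUTCOME_COUNTS",
    "published_outcome_dataset",
    "published_flowchart_dataset",
]

#: Participant flow: initial n and counts removed at each cascade step.
EXCLUSION_FLOW = {
    "initial": 23091,
    "no consent for LTCI review": 6333,
    "disability certified before follow-up": 1979,
    "died or moved before follow-up": 5,
    "missing number of remaining teeth": 568,
}

#: End-of-follow-up outcome counts by (sex, teeth group).
OUTCOME_COUNTS = {
    ("male", "0-9"): {"non-disabled": 802, "disabled": 156, "dead": 1586, "emigrated": 105},
    ("male", "10-19"): {"non-disabled": 699, "disabled": 121, "dead": 715, "emigrated": 47},
    ("male", ">=20"): {"non-disabled": 1217, "disabled": 147, "dead": 746, "emigrated": 65},
    ("female", "0-9"): {"non-disabled": 1547, "disabled": 520, "dead": 1439, "emigrated": 194},
    ("female", "10-19"): {"non-disabled": 1051, "disabled": 229, "dead": 496, "emigrated": 94},
    ("female", ">=20"): {"non-disabled": 1460, "disabled": 233, "dead": 430, "emigrated": 107},
}

_GROUP_CATEGORY = {"0-9": "few", "10-19": "about_half", ">=20": "all"}

_FOLLOWUP_END = 156  # months


def _outcome_record(pid: str, sex: str, group: str, outcome: str) -> PanelRecord:
    obs = [(0, HealthState.NONDISABLED)]
    death = emig = None
    if outcome == "non-disabled":
        obs.append((_FOLLOWUP_END, HealthState.NONDISABLED))
    elif outcome == "disabled":
        obs.append((_FOLLOWUP_END, HealthState.DISABLED))
    elif outcome == "dead":
        death = 60  # placeholder timing; only the outcome class is published
    elif outcome == "emigrated":
        emig = 60
    else:
        raise ValueError(outcome)
    return PanelRecord(
        participant_id=pid,
        sex=sex,
        baseline_age=74.0,
        observations=obs,
        death_month=death,
        emigration_month=emig,
        teeth_category=_GROUP_CATEGORY[group],
    )


def published_outcome_dataset() -> PanelDataset:
    """Synthetic analysis cohort reproducing the published outcome counts."""
    records = []
    i = 0
    for (sex, group), counts in OUTCOME_COUNTS.items():
        for outcome, n in counts.items():
            for _ in range(n):
                i += 1
                records.append(_outcome_record(f"s{i:05d}", sex, group, outcome))
    return PanelDataset(records=records, metadata={"source": "published counts"})


def published_flowchart_dataset() -> PanelDataset:
    """Synthetic source cohort whose exclusion cascade reproduces the
    published participant flow, terminating in the outcome dataset."""
    analysis = published_outcome_dataset()
    records: list[PanelRecord] = []
    i = 0

    def excluded(**kwargs) -> PanelRecord:
        nonlocal i
        i += 1
        return PanelRecord(
            participant_id=f"x{i:05d}",
            sex="female",
            baseline_age=74.0,
            observations=[(0, HealthState.NONDISABLED)],
            teeth_category="few",
            **kwargs,
        )

    for _ in range(EXCLUSION_FLOW["no consent for LTCI review"]):
        records.append(excluded(consent=False))
    for _ in range(EXCLUSION_FLOW["disability certified before follow-up"]):
        records.append(excluded(baseline_disabled=True))
    for _ in range(EXCLUSION_FLOW["died or moved before follow-up"]):
        records.append(excluded(prefollowup_loss=True))
    for _ in range(EXCLUSION_FLOW["missing number of remaining teeth"]):
        rec = excluded()
        rec.teeth_category = None
        records.append(rec)
    records.extend(analysis.records)
    ds = PanelDataset(records=records, metadata={"source": "published counts"})
    assert len(ds) == EXCLUSION_FLOW["initial"]
    return ds
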