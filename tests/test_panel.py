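"""Panel containers, CSV dialects, exclusion cascade and accounting."""

import pandas as pd
import pytest

from mslt.panel import (
    PanelDataset,
    PanelFormatError,
    PanelRecord,
    PanelValidationError,
    apply_exclusions,
    follow_up_rate,
    outcome_distribution,
    read_panel,
    round_half_up,
    write_panel,
)
from mslt.states import HealthState


def test_tidy_long_reads_single_participant(tmp_path):
    path = tmp_path / "p.csv"
    path.write_text(
        "participant_id,sex,baseline_age,month,state\n"
        "a,male,70,0,1\na,male,70,12,1\na,male,70,24,2\n"
    )
    ds = read_panel(path)
    assert len(ds) == 1
    assert ds.records[0].observations == [
        (0, HealthState.NONDISABLED),
        (12, HealthState.NONDISABLED),
        (24, HealthState.DISABLED),
    ]


def test_living_state_after_death_is_rejected(tmp_path):
    path = tmp_path / "p.csv"
    path.write_text(
        "participant_id,sex,baseline_age,month,state\n"
        "a,male,70,0,1\na,male,70,12,3\na,male,70,24,1\n"
    )
    with pytest.raises(PanelValidationError, match="a"):
        read_panel(path)


def test_missing_column_named_in_error(tmp_path):
    path = tmp_path / "p.csv"
    path.write_text("participant_id,sex,month,state\na,male,0,1\n")
    with pytest.raises(PanelFormatError, match="baseline_age"):
        read_panel(path)


def test_non_monotone_observation_times_rejected():
    rec = PanelRecord(
        participant_id="z",
        sex="male",
        baseline_age=70,
        observations=[(0, HealthState.NONDISABLED), (0, HealthState.NONDISABLED)],
    )
    assert any("increasing" in e for e in rec.validate())


def test_emigration_after_death_is_a_validation_error():
    rec = PanelRecord(
        participant_id="z",
        sex="male",
        baseline_age=70,
        observations=[(0, HealthState.NONDISABLED)],
        death_month=12,
        emigration_month=24,
    )
    assert any("death and emigration" in e for e in rec.validate())


@pytest.mark.parametrize("dialect", ["tidy_long", "wide_wave"])
def test_round_trip_is_lossless(tmp_path, tiny_dataset, dialect):
    path = tmp_path / f"rt_{dialect}.csv"
    write_panel(tiny_dataset, path, dialect=dialect)
    back = read_panel(path, dialect=dialect)
    assert len(back) == len(tiny_dataset)
    for orig, rec in zip(tiny_dataset, back):
        assert rec == orig


# ---------------------------------------------------------------------------
# exclusion cascade


def _flagged(pid, **kwargs):
    return PanelRecord(
        participant_id=pid,
        sex="female",
        baseline_age=70,
        observations=[(0, HealthState.NONDISABLED)],
        teeth_category=kwargs.pop("teeth_category", "few"),
        **kwargs,
    )


def test_cascade_counts_doubly_flagged_record_once():
    # 10 records: 3 without consent, one of which also has missing teeth
    records = [
        _flagged("c1", consent=False),
        _flagged("c2", consent=False),
        _flagged("c3", consent=False, teeth_category=None),
    ] + [_flagged(f"k{i}") for i in range(7)]
    kept, log = apply_exclusions(PanelDataset(records=records))
    assert len(kept) == 7
    steps = dict((label, n) for label, n, _ in log.steps)
    assert steps["no consent for LTCI review"] == 3
    assert steps["missing number of remaining teeth"] == 0


def test_cascade_identity_when_nothing_flagged():
    records = [_flagged(f"k{i}") for i in range(5)]
    ds = PanelDataset(records=records)
    kept, log = apply_exclusions(ds)
    assert len(kept) == 5
    assert all(n == 0 for _, n, _ in log.steps)
    assert [r.participant_id for r in kept] == [r.participant_id for r in ds]


def test_cascade_partition_invariant():
    records = (
        [_flagged(f"a{i}", consent=False) for i in range(4)]
        + [_flagged(f"b{i}", baseline_disabled=True) for i in range(3)]
        + [_flagged(f"c{i}", prefollowup_loss=True) for i in range(2)]
        + [_flagged(f"d{i}", teeth_category=None) for i in range(5)]
        + [_flagged(f"e{i}") for i in range(6)]
    )
    kept, log = apply_exclusions(PanelDataset(records=records))
    assert sum(n for _, n, _ in log.steps) + len(kept) == len(records)
    remaining = [n for _, _, n in log.steps]
    assert remaining == sorted(remaining, reverse=True)
    assert log.final_n == len(kept)


# ---------------------------------------------------------------------------
# outcome accounting


def test_single_death_is_all_dead():
    rec = PanelRecord(
        participant_id="d",
        sex="male",
        baseline_age=70,
        observations=[(0, HealthState.NONDISABLED)],
        death_month=60,
    )
    table = outcome_distribution(PanelDataset(records=[rec]))
    dead = table[table.outcome == "dead"].iloc[0]
    assert dead.n == 1 and dead.pct == 100.0


def test_outcome_counts_partition_each_group(tiny_dataset):
    table = outcome_distribution(tiny_dataset, by=["sex"])
    for _, grp in table.groupby("sex"):
        total = int(grp[grp.outcome == "total"].n.iloc[0])
        assert grp[grp.outcome != "total"].n.sum() == total


def test_record_without_outcome_is_an_error():
    rec = PanelRecord(participant_id="n", sex="male", baseline_age=70)
    with pytest.raises(PanelValidationError):
        outcome_distribution(PanelDataset(records=[rec]))


def test_follow_up_rate_arithmetic():
    records = [_flagged(f"k{i}") for i in range(9)]
    records.append(
        PanelRecord(
            participant_id="e",
            sex="male",
            baseline_age=70,
            observations=[(0, HealthState.NONDISABLED)],
            emigration_month=30,
            teeth_category="few",
        )
    )
    assert follow_up_rate(PanelDataset(records=records)) == 90.0
    assert follow_up_rate(PanelDataset(records=records[:9])) == 100.0
    with pytest.raises(PanelValidationError):
        follow_up_rate(PanelDataset(records=[]))


def test_half_up_rounding_convention():
    assert round_half_up(30.25) == 30.3
    assert round_half_up(95.6924) == 95.7
    assert round_half_up(2.349) == 2.3
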