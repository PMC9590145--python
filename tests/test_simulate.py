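"""Synthetic-cohort generator: determinism, absorbing-state behaviour,
agreement of empirical occupancy with closed-form expectations, and the
default scenario's structure."""

import numpy as np
import pytest

from mslt.lifetable import expectancies
from mslt.panel import outcome_distribution
from mslt.params import TransitionParameters
from mslt.simulate import (
    GroupScenario,
    ScenarioConfig,
    default_ohsaki_like_scenario,
    simulate_cohort,
)
from mslt.states import HealthState

from conftest import logits_from_monthly_probs


def _one_group(truth, n, **kwargs):
    return ScenarioConfig(
        n_participants=n,
        groups={"g": GroupScenario(proportion=1.0,
                                   params={"male": truth, "female": truth})},
        **kwargs,
    )


def test_identical_seed_gives_identical_dataset():
    cfg = _one_group(logits_from_monthly_probs(0.004, 0.004, 0.01, 0.02), 300)
    a = simulate_cohort(cfg, seed=11)
    b = simulate_cohort(cfg, seed=11)
    assert a.records == b.records
    c = simulate_cohort(cfg, seed=12)
    deaths = lambda ds: sum(r.death_month is not None for r in ds)
    assert a.records != c.records
    assert deaths(a) != deaths(c) or a.records[0] != c.records[0]


def test_numerically_impossible_events_never_occur():
    truth = TransitionParameters(
        intercepts=np.full(4, -50.0), slopes=np.zeros(4)
    )
    ds = simulate_cohort(_one_group(truth, 400, emigration_hazard=0.0), seed=2)
    for rec in ds:
        assert rec.death_month is None
        assert all(s == HealthState.NONDISABLED for _, s in rec.observations)
        assert len(rec.observations) == 14  # all annual waves over 13 years


def test_geometric_mean_survival():
    """Monthly death probability 1/120 from the non-disabled state: mean
    lifetime near 120 months (within 3 standard errors at n=5000)."""
    truth = logits_from_monthly_probs(1e-9, 1.0 / 120.0, 0.01, 0.01)
    cfg = _one_group(truth, 5000, emigration_hazard=0.0,
                     wave_schedule=tuple(range(0, 1212, 12)))
    ds = simulate_cohort(cfg, seed=7)
    deaths = np.array([r.death_month for r in ds if r.death_month is not None])
    assert len(deaths) > 4900  # horizon long enough that nearly all die
    se = np.sqrt(119.0 * 120.0**2 / 120.0) / np.sqrt(len(deaths))
    assert abs(deaths.mean() - 120.0) < 3 * se


def test_empirical_occupancy_matches_fundamental_matrix():
    """Latent-path months in each living state converge to (I - Q)^-1."""
    truth = logits_from_monthly_probs(0.02, 0.01, 0.01, 0.04)
    N = np.linalg.inv(np.eye(2) - np.array([[0.97, 0.02], [0.01, 0.95]]))
    cfg = _one_group(truth, 5000, emigration_hazard=0.0,
                     wave_schedule=tuple(range(0, 1212, 12)))
    ds = simulate_cohort(cfg, seed=9, emit_latent=True)
    paths = np.stack(list(ds.metadata["latent_paths"].values()))
    months_nd = (paths == 1).sum(axis=1)
    months_d = (paths == 2).sum(axis=1)
    for emp, exact in ((months_nd, N[0, 0]), (months_d, N[0, 1])):
        se = emp.std(ddof=1) / np.sqrt(len(emp))
        assert abs(emp.mean() - exact) < 3 * se


def test_latent_paths_never_leave_death():
    truth = logits_from_monthly_probs(0.02, 0.02, 0.02, 0.05)
    ds = simulate_cohort(_one_group(truth, 200), seed=5, emit_latent=True)
    for path in ds.metadata["latent_paths"].values():
        dead = np.nonzero(path == 3)[0]
        if len(dead):
            assert (path[dead[0]:] == 3).all()


def test_emigration_truncates_and_rate_is_plausible():
    truth = logits_from_monthly_probs(0.004, 0.004, 0.01, 0.02)
    ds = simulate_cohort(_one_group(truth, 4000, emigration_hazard=0.0004), seed=21)
    n_emig = sum(r.emigration_month is not None for r in ds)
    assert 0.02 < n_emig / len(ds) < 0.08  # ~4-5% lost over 13 years
    for r in ds:
        if r.emigration_month is not None:
            assert r.death_month is None
            assert all(m < r.emigration_month for m, _ in r.observations)


def test_invalid_configs_rejected():
    truth = logits_from_monthly_probs(0.004, 0.004, 0.01, 0.02)
    grp = GroupScenario(proportion=0.5, params={"male": truth, "female": truth})
    with pytest.raises(ValueError, match="proportions"):
        ScenarioConfig(n_participants=10, groups={"g": grp}).validate()
    cfg = _one_group(truth, 10, wave_schedule=(12, 0))
    with pytest.raises(ValueError, match="wave_schedule"):
        cfg.validate()


def test_yaml_round_trip(tmp_path):
    sc = default_ohsaki_like_scenario(n_participants=500)
    path = tmp_path / "scenario.yaml"
    sc.to_yaml(path)
    back = ScenarioConfig.from_yaml(path)
    assert back.n_participants == sc.n_participants
    assert set(back.groups) == set(sc.groups)
    for label in sc.groups:
        for sex in ("male", "female"):
            assert np.array_equal(
                back.groups[label].params[sex].to_vector(),
                sc.groups[label].params[sex].to_vector(),
            )
    assert simulate_cohort(back, seed=3).records == simulate_cohort(sc, seed=3).records


def test_default_scenario_structure():
    sc = default_ohsaki_like_scenario(n_participants=6000)
    sc.validate()
    # analytic ground-truth DFLE ordering within each sex
    for sex in ("male", "female"):
        dfle = {
            g: expectancies(sc.groups[g].params[sex], 65, 110).dfle
            for g in sc.groups
        }
        assert dfle[">=20"] > dfle["10-19"] > dfle["0-9"]
    # crude death percentage decreases with more teeth (direction only)
    ds = simulate_cohort(sc, seed=13)
    table = outcome_distribution(ds, by=["teeth_group"])
    dead = table[table.outcome == "dead"].set_index("teeth_group")["pct"]
    assert dead["0-9"] > dead["10-19"] > dead[">=20"]
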