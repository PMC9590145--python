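"""Step matrices, interval products and the interval-censored likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mslt.likelihood import PairData, dataset_log_likelihood, record_log_likelihood
from mslt.panel import PanelDataset, PanelRecord
from mslt.params import (
    TransitionParameters,
    interval_matrix,
    read_parameters,
    step_matrix,
    write_parameters,
)
from mslt.simulate import GroupScenario, ScenarioConfig, simulate_cohort
from mslt.states import HealthState


def tp(intercepts, slopes=(0, 0, 0, 0)):
    return TransitionParameters(np.array(intercepts, float), np.array(slopes, float))


def test_softmax_row_matches_direct_formula():
    params = tp([-2.0, -3.0, -50.0, -50.0])
    M = step_matrix(params, age=80.0)
    denom = 1 + math.exp(-2) + math.exp(-3)
    assert M[0, 1] == pytest.approx(math.exp(-2) / denom, rel=1e-12)
    assert M[0, 2] == pytest.approx(math.exp(-3) / denom, rel=1e-12)
    assert M[0, 0] == pytest.approx(1 / denom, rel=1e-12)


def test_extreme_negative_logits_give_identity_on_transient_rows():
    M = step_matrix(tp([-50, -50, -50, -50]), age=80.0)
    assert np.allclose(M[:2, :2], np.eye(2), atol=1e-20)


def test_dead_row_is_absorbing_for_any_age():
    params = tp([1.5, -0.5, 0.3, 2.0], [0.1, -0.2, 0.05, 0.3])
    for age in (65, 80, 110):
        assert np.array_equal(step_matrix(params, age)[2], [0.0, 0.0, 1.0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-30, 8), min_size=4, max_size=4),
    st.lists(st.floats(-0.5, 0.5), min_size=4, max_size=4),
    st.floats(65, 110),
)
def test_step_matrix_is_row_stochastic(intercepts, slopes, age):
    M = step_matrix(tp(intercepts, slopes), age)
    assert np.all(M >= 0) and np.all(M <= 1)
    assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)


def test_nan_parameters_rejected():
    with pytest.raises(ValueError):
        tp([np.nan, -3, -3, -3])


def test_interval_matrix_zero_steps_is_identity():
    assert np.array_equal(interval_matrix(tp([-2, -3, -4, -2]), 70.0, 0), np.eye(3))


def test_interval_matrix_homogeneous_two_steps_is_square():
    params = tp([-2.5, -3.0, -3.5, -2.0])
    M = step_matrix(params, 70.0)
    assert np.allclose(interval_matrix(params, 70.0, 2), M @ M, atol=1e-15)


def test_interval_matrix_matches_brute_force_product():
    params = tp([-4, -5, -3.5, -3], [0.1, 0.09, -0.02, 0.06])
    expected = np.eye(3)
    for k in range(24):
        expected = expected @ step_matrix(params, 72.0 + k / 12.0)
    assert np.allclose(interval_matrix(params, 72.0, 24), expected, atol=1e-14)


def test_chapman_kolmogorov_identity():
    params = tp([-4, -5, -3.5, -3], [0.1, 0.09, -0.02, 0.06])
    full = interval_matrix(params, 70.0, 30)
    split = interval_matrix(params, 70.0, 12) @ interval_matrix(
        params, 70.0 + 12 / 12.0, 18
    )
    assert np.allclose(full, split, atol=1e-14)


def test_raising_death_logit_never_raises_retention():
    base = tp([-3, -4, -3, -3])
    for delta in (0.5, 1.0, 3.0):
        bumped = base.shifted({"intercept_1->3": delta})
        assert step_matrix(bumped, 80)[0, 0] <= step_matrix(base, 80)[0, 0]


def test_negative_steps_rejected():
    with pytest.raises(ValueError):
        interval_matrix(tp([-2, -2, -2, -2]), 70.0, -1)


def test_parameter_file_round_trip(tmp_path):
    params = TransitionParameters(
        intercepts=np.array([-5.123456789012345, -4.2, -3.3, -2.4]),
        slopes=np.array([0.123456789012345, -0.01, 0.0, 0.3]),
        age_center=78.5,
        covariate_slopes={"smoking": np.array([0.1, 0.2, -0.1, 0.05])},
    )
    path = tmp_path / "params.txt"
    write_parameters(params, path)
    back = read_parameters(path)
    assert np.array_equal(back.to_vector(), params.to_vector())
    assert back.age_center == params.age_center
    assert np.array_equal(back.covariate_slopes["smoking"],
                          params.covariate_slopes["smoking"])


# ---------------------------------------------------------------------------
# record and dataset likelihood


def _record(obs, death=None, age=70.0, pid="r"):
    return PanelRecord(
        participant_id=pid, sex="male", baseline_age=age,
        observations=[(m, HealthState(s)) for m, s in obs], death_month=death,
    )


def test_single_retention_pair_is_log_p11():
    params = tp([-2.5, -3.0, -3.0, -3.0])
    p11 = step_matrix(params, 70.0)[0, 0]
    rec = _record([(0, 1), (1, 1)])
    assert record_log_likelihood(params, rec) == pytest.approx(math.log(p11), abs=1e-12)


def test_baseline_only_record_contributes_zero():
    assert record_log_likelihood(tp([-2, -2, -2, -2]), _record([(0, 1)])) == 0.0


def test_three_wave_record_matches_hand_computed_sum():
    params = tp([-4, -5, -3.5, -3], [0.1, 0.09, -0.02, 0.06])
    rec = _record([(0, 1), (12, 1), (24, 2)], age=70.0)
    P1 = interval_matrix(params, 70.0, 12)
    P2 = interval_matrix(params, 71.0, 12)
    expected = math.log(P1[0, 0]) + math.log(P2[0, 1])
    assert record_log_likelihood(params, rec) == pytest.approx(expected, abs=1e-12)


def test_death_factor_is_exact_month_probability():
    # survive 4 months from the last wave in a living state, die in month 5
    params = tp([-4, -5, -3.5, -3], [0.1, 0.09, -0.02, 0.06])
    rec = _record([(0, 1), (12, 1)], death=17, age=70.0)
    A = interval_matrix(params, 71.0, 4)
    M = step_matrix(params, 71.0 + 4 / 12.0)
    expected_death = A[0, 0] * M[0, 2] + A[0, 1] * M[1, 2]
    expected = math.log(interval_matrix(params, 70.0, 12)[0, 0]) + math.log(
        expected_death
    )
    assert record_log_likelihood(params, rec) == pytest.approx(expected, abs=1e-12)


def test_zero_probability_transition_gives_minus_inf_with_diagnostic():
    # recovery logit at -inf in practice: observed 2 -> 1 is impossible
    params = tp([-2, -2, -800, -2])
    rec = _record([(0, 2), (1, 1)], pid="zp")
    diags = []
    ll = record_log_likelihood(params, rec, diagnostics=diags)
    assert ll == -math.inf
    assert any("zp" in d for d in diags)


def test_dataset_likelihood_additive_and_empty():
    params = tp([-3, -3, -3, -3])
    rec = _record([(0, 1), (12, 2)])
    rec2 = _record([(0, 1), (12, 2)], pid="r2")
    two = dataset_log_likelihood(params, PanelDataset(records=[rec, rec2]))
    one = record_log_likelihood(params, rec)
    assert two == pytest.approx(2 * one, rel=1e-14)
    assert dataset_log_likelihood(params, PanelDataset(records=[])) == 0.0


def test_fast_pair_evaluation_matches_naive_sum():
    truth = TransitionParameters(
        intercepts=np.array([-5.0, -5.3, -3.6, -3.4]),
        slopes=np.array([0.1, 0.09, -0.02, 0.05]),
    )
    cfg = ScenarioConfig(
        n_participants=50,
        groups={"g": GroupScenario(proportion=1.0,
                                   params={"male": truth, "female": truth})},
        emigration_hazard=0.001,
    )
    ds = simulate_cohort(cfg, seed=3)
    eval_params = truth.shifted({"intercept_1->3": 0.2, "slope_2->3": -0.01})
    pairs = PairData.from_dataset(ds)
    fast = pairs.log_likelihood(eval_params)
    naive = dataset_log_likelihood(eval_params, ds)
    assert fast == pytest.approx(naive, abs=1e-10)
    # invariant to record order
    shuffled = PanelDataset(records=list(reversed(ds.records)))
    assert PairData.from_dataset(shuffled).log_likelihood(eval_params) == (
        pytest.approx(fast, abs=1e-10)
    )
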