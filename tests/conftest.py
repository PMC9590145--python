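"""Shared fixtures: tiny hand-built panels, analytic oracle parameters, and
a session-scoped bank of replicate synthetic-cohort fits used by the
estimation and coverage checks."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mslt.model import TransitionModel
from mslt.panel import PanelDataset, PanelRecord
from mslt.params import TransitionParameters
from mslt.simulate import GroupScenario, ScenarioConfig, simulate_cohort
from mslt.states import HealthState


def logits_from_monthly_probs(p12, p13, p21, p23) -> TransitionParameters:
    """Age-homogeneous parameters with exact monthly transition probabilities.

    Inverts the multinomial logit: a_ij = ln(p_ij / p_ii) with the retention
    probability as reference.
    """
    p11 = 1.0 - p12 - p13
    p22 = 1.0 - p21 - p23
    return TransitionParameters(
        intercepts=np.array(
            [math.log(p12 / p11), math.log(p13 / p11),
             math.log(p21 / p22), math.log(p23 / p22)]
        ),
        slopes=np.zeros(4),
    )


@pytest.fixture(scope="session")
def oracle_q_params():
    """Monthly retention matrix Q = [[0.97, 0.02], [0.01, 0.95]] as logits."""
    return logits_from_monthly_probs(p12=0.02, p13=0.01, p21=0.01, p23=0.04)


@pytest.fixture
def tiny_record():
    return PanelRecord(
        participant_id="a1",
        sex="male",
        baseline_age=70.0,
        observations=[
            (0, HealthState.NONDISABLED),
            (12, HealthState.NONDISABLED),
            (24, HealthState.DISABLED),
        ],
        teeth_category="few",
        brushing_per_day=2,
        dentures=True,
        checkups=False,
        smoking="never_former",
        bmi_class="normal",
        walking="ge_half_hour",
        education="high",
    )


@pytest.fixture
def tiny_dataset(tiny_record):
    dead = PanelRecord(
        participant_id="a2",
        sex="female",
        baseline_age=80.5,
        observations=[(0, HealthState.NONDISABLED), (12, HealthState.NONDISABLED)],
        death_month=20,
        teeth_category="about_half",
    )
    emigrant = PanelRecord(
        participant_id="a3",
        sex="female",
        baseline_age=68.0,
        observations=[(0, HealthState.NONDISABLED)],
        emigration_month=7,
        teeth_category="all",
        brushing_per_day=1,
    )
    return PanelDataset(records=[tiny_record, dead, emigrant])


# ---------------------------------------------------------------------------
# replicate synthetic cohorts with known ground truth

#: ground truth for the replicate bank: realistic age-dependent parameters
REPLICATE_TRUTH = TransitionParameters(
    intercepts=np.array([-5.50, -5.82, -3.70, -3.55]),
    slopes=np.array([0.105, 0.088, -0.03, 0.055]),
)

N_REPLICATES = 50
REPLICATE_N = 2000


def _single_group_config(truth: TransitionParameters, n: int) -> ScenarioConfig:
    return ScenarioConfig(
        n_participants=n,
        groups={"g": GroupScenario(proportion=1.0,
                                   params={"male": truth, "female": truth})},
        sex_ratio_male=1.0,
        emigration_hazard=0.0004,
    )


@pytest.fixture(scope="session")
def replicate_fits():
    """Fits of 50 replicate cohorts (n=2000, annual waves, 13-year follow-up)
    simulated from known ground truth, each with a seeded 95% CI life table."""
    out = []
    for rep in range(N_REPLICATES):
        cfg = _single_group_config(REPLICATE_TRUTH, REPLICATE_N)
        ds = simulate_cohort(cfg, seed=10_000 + rep)
        fit = TransitionModel(ds).fit()
        lt = fit.life_table(start_age=65, max_age=110, n_draws=2000,
                            seed=20_000 + rep)
        out.append((fit, lt))
    return out
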