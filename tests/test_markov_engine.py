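"""Markov engine: rate conversion, matrix composition, cohort propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mscea.config import (
    build_arm,
    build_settings,
    build_transition_table,
)
from mscea.markov_engine import (
    ArmParameters,
    ModelError,
    ModelSettings,
    TransitionTable,
    build_transition_matrix,
    discount,
    rate_to_prob,
    run_cohort,
    simulate_individuals,
)
from mscea.states import LIVING_STATES, RRMS_STATES


def uniform_arm(utility=1.0, drug=0.0, other=0.0, relapse=0.0, name="test"):
    return ArmParameters(
        name=name,
        annual_relapse_prob=relapse,
        state_utilities={s: utility for s in LIVING_STATES},
        drug_cost=drug,
        other_costs={s: other for s in LIVING_STATES},
    )


def identity_table(death_pct=0.0):
    return TransitionTable(
        living_rows=np.eye(4) * 100.0,
        death_probs=np.full(4, death_pct),
    )


# -------------------------------------------------------------- rate_to_prob


@pytest.mark.parametrize(
    "rate,t,expected",
    [(0.0, 1.0, 0.0), (0.5, 1.0, 0.393469), (1e9, 1.0, 1.0)],
)
def test_rate_to_prob_closed_form(rate, t, expected):
    assert rate_to_prob(rate, t) == pytest.approx(expected, abs=1e-6)


def test_rate_to_prob_rejects_negative_rate():
    with pytest.raises(ModelError):
        rate_to_prob(-0.1)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(rate=st.floats(0, 100), t=st.floats(0.01, 10))
def test_rate_to_prob_is_a_probability(rate, t):
    p = rate_to_prob(rate, t)
    assert 0.0 <= p < 1.0 or p == pytest.approx(1.0, abs=1e-12)


# ------------------------------------------------------------------ discount


@pytest.mark.parametrize(
    "value,rate,k,expected",
    [(7.0, 0.03, 0, 7.0), (7.0, 0.0, 13, 7.0), (100.0, 0.03, 2, 94.259591)],
)
def test_discount_examples(value, rate, k, expected):
    assert discount(value, rate, k) == pytest.approx(expected, abs=1e-4)


def test_discount_passes_negative_values_through():
    assert discount(-100.0, 0.03, 1) == pytest.approx(-100.0 / 1.03)


# ------------------------------------------------------- matrix composition


def test_death_first_composition_worst_state(base_cfg):
    # From the most disabled band: stay prob 0.9575 among survivors times
    # survival 0.9455 = 0.905317.
    tt = build_transition_table(base_cfg)
    m = build_transition_matrix(tt)
    assert m[3, 3] == pytest.approx(0.9575 * 0.9455, abs=1e-9)
    assert m[3, 4] == pytest.approx(0.0545)


def test_rows_sum_to_one(base_cfg):
    m = build_transition_matrix(build_transition_table(base_cfg))
    assert np.abs(m.sum(axis=1) - 1.0).max() < 1e-12
    assert (m >= 0).all()


def test_zero_death_recovers_normalized_rows(base_cfg):
    tt = build_transition_table(base_cfg)
    tt0 = TransitionTable(living_rows=tt.living_rows, death_probs=np.zeros(4))
    m = build_transition_matrix(tt0)
    expected = tt.living_rows / tt.living_rows.sum(axis=1, keepdims=True)
    assert np.allclose(m[:4, :4], expected, atol=1e-12)
    assert np.allclose(m[:4, 4], 0.0)


def test_identity_rows_zero_death_is_identity():
    m = build_transition_matrix(identity_table())
    assert np.allclose(m, np.eye(5))


def test_row_sum_outside_slack_rejected():
    rows = np.eye(4) * 100.0
    rows[0, 0] = 99.0  # a full percentage point off
    with pytest.raises(ModelError, match="edss_0_2_5"):
        TransitionTable(living_rows=rows, death_probs=np.zeros(4))


def test_rounding_slack_renormalized(base_cfg):
    # One published row sums to 100.005%; it is accepted and renormalized.
    tt = build_transition_table(base_cfg)
    assert tt.living_rows[1].sum() == pytest.approx(100.005)
    m = build_transition_matrix(tt)
    assert m[1].sum() == pytest.approx(1.0, abs=1e-12)


# ------------------------------------------------------------------ run_cohort


def test_static_cohort_accrues_one_qaly_per_cycle():
    settings_ = ModelSettings(
        start_age=34.0, max_age=44.0, discount_rate_costs=0.0,
        discount_rate_outcomes=0.0,
    )
    _, res = run_cohort(identity_table(), uniform_arm(), settings_)
    assert res.total_qalys == pytest.approx(10.0)
    assert res.life_years == pytest.approx(10.0)


def test_immediate_death_accrues_first_cycle_only():
    settings_ = ModelSettings(discount_rate_outcomes=0.0, discount_rate_costs=0.0)
    _, res = run_cohort(identity_table(death_pct=100.0), uniform_arm(), settings_)
    assert res.total_qalys == pytest.approx(1.0)


def test_occupancy_equals_matrix_power(base_cfg):
    tt = build_transition_table(base_cfg)
    settings_ = build_settings(base_cfg)
    trace, _ = run_cohort(tt, build_arm(base_cfg, "rituximab"), settings_)
    m = build_transition_matrix(tt)
    start = np.append(np.asarray(settings_.start_distribution), 0.0)
    for n in range(21):
        expected = start @ np.linalg.matrix_power(m, n)
        assert np.abs(trace.occupancy[n] - expected[:4]).max() < 1e-10


def test_conservation_of_mass(base_cfg):
    tt = build_transition_table(base_cfg)
    trace, _ = run_cohort(
        tt, build_arm(base_cfg, "natalizumab"), build_settings(base_cfg)
    )
    total = trace.occupancy.sum(axis=1) + trace.cum_death
    assert np.abs(total - 1.0).max() < 1e-9


def test_discounted_accruals_never_exceed_undiscounted(base_cfg):
    trace, _ = run_cohort(
        build_transition_table(base_cfg),
        build_arm(base_cfg, "rituximab"),
        build_settings(base_cfg),
    )
    assert (trace.disc_cost <= trace.cost + 1e-12).all()
    assert (trace.disc_qaly <= trace.qaly + 1e-12).all()


def test_raising_a_utility_weakly_increases_qalys(base_cfg):
    tt = build_transition_table(base_cfg)
    settings_ = build_settings(base_cfg)
    arm = build_arm(base_cfg, "rituximab")
    _, base = run_cohort(tt, arm, settings_)
    for s in LIVING_STATES:
        utils = dict(arm.state_utilities)
        utils[s] = min(1.0, utils[s] + 0.05)
        bumped = ArmParameters(
            name=arm.name,
            annual_relapse_prob=arm.annual_relapse_prob,
            state_utilities=utils,
            drug_cost=arm.drug_cost,
            other_costs=arm.other_costs,
        )
        _, res = run_cohort(tt, bumped, settings_)
        assert res.total_qalys >= base.total_qalys


def test_raising_discount_rate_weakly_decreases_totals(base_cfg):
    tt = build_transition_table(base_cfg)
    arm = build_arm(base_cfg, "natalizumab")
    s0 = build_settings(base_cfg)
    _, base = run_cohort(tt, arm, s0)
    import dataclasses

    s1 = dataclasses.replace(s0, discount_rate_costs=s0.discount_rate_costs + 0.02)
    _, r1 = run_cohort(tt, arm, s1)
    assert r1.total_cost <= base.total_cost
    s2 = dataclasses.replace(
        s0, discount_rate_outcomes=s0.discount_rate_outcomes + 0.02
    )
    _, r2 = run_cohort(tt, arm, s2)
    assert r2.total_qalys <= base.total_qalys


def test_incremental_relapses_closed_form(base_cfg):
    """With a shared transition table, the relapse gap between arms is
    (difference in relapse probability) x discounted RRMS occupancy mass."""
    tt = build_transition_table(base_cfg)
    settings_ = build_settings(base_cfg)
    arm_r = build_arm(base_cfg, "rituximab")
    arm_n = build_arm(base_cfg, "natalizumab")
    trace, res_r = run_cohort(tt, arm_r, settings_)
    _, res_n = run_cohort(tt, arm_n, settings_)
    rrms_idx = [LIVING_STATES.index(s) for s in RRMS_STATES]
    v = 1.0 + settings_.discount_rate_outcomes
    mass = sum(
        trace.occupancy[k, rrms_idx].sum() * v**-k
        for k in range(len(trace.cycles))
    )
    dp = arm_n.annual_relapse_prob - arm_r.annual_relapse_prob
    assert res_n.total_relapses - res_r.total_relapses == pytest.approx(
        dp * mass, rel=1e-10
    )


def test_microsimulation_matches_cohort_expectation(base_cfg):
    tt = build_transition_table(base_cfg)
    settings_ = build_settings(base_cfg)
    arm = build_arm(base_cfg, "natalizumab")
    _, res = run_cohort(tt, arm, settings_)
    ms = simulate_individuals(tt, arm, settings_, n_patients=50_000, seed=11)
    assert abs(ms["mean_qaly"] - res.total_qalys) < 3 * ms["se_qaly"]
    assert abs(ms["mean_cost"] - res.total_cost) < 3 * ms["se_cost"]


def test_discount_first_cycle_scales_static_run():
    import dataclasses

    s0 = ModelSettings(
        start_age=34.0, max_age=44.0, discount_rate_costs=0.0,
        discount_rate_outcomes=0.05,
    )
    _, r0 = run_cohort(identity_table(), uniform_arm(), s0)
    s1 = dataclasses.replace(s0, discount_first_cycle=True)
    _, r1 = run_cohort(identity_table(), uniform_arm(), s1)
    assert r1.total_qalys == pytest.approx(r0.total_qalys / 1.05)
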