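"""Distribution fitting, PSA machinery, CEAC/CE-plane and tornado analysis."""

import numpy as np
import pandas as pd
import pytest

from mscea.config import copy_config, get_path, set_path
from mscea.sensitivity import (
    DistributionSpec,
    InfeasibleDistributionError,
    PSAConfig,
    SensitivityError,
    beta_from_moments,
    ce_plane,
    ceac,
    default_psa_specs,
    evaluate_config,
    gamma_from_moments,
    run_psa,
    tornado,
)


# ----------------------------------------------------------- moment matching


def test_beta_moments_recovered_in_closed_form():
    a, b = beta_from_moments(0.833, 0.125)
    assert a == pytest.approx(6.583, abs=0.01)
    assert b == pytest.approx(1.320, abs=0.01)
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    assert mean == pytest.approx(0.833, rel=1e-12)
    assert np.sqrt(var) == pytest.approx(0.125, rel=1e-12)


def test_beta_uniform_corner():
    a, b = beta_from_moments(0.5, np.sqrt(1 / 12))
    assert a == pytest.approx(1.0, rel=1e-9)
    assert b == pytest.approx(1.0, rel=1e-9)


def test_beta_infeasible_sd_rejected():
    with pytest.raises(InfeasibleDistributionError):
        beta_from_moments(0.5, 0.5)
    with pytest.raises(InfeasibleDistributionError):
        beta_from_moments(1.2, 0.1)


def test_gamma_moments_recovered():
    shape, scale = gamma_from_moments(36_058.08, 7_211.616)  # CV 0.2
    assert shape == pytest.approx(25.0, rel=1e-9)
    assert scale == pytest.approx(1_442.3232, rel=1e-9)
    assert shape * scale == pytest.approx(36_058.08)
    assert np.sqrt(shape) * scale == pytest.approx(7_211.616)


def test_gamma_exponential_corner():
    shape, _ = gamma_from_moments(5.0, 5.0)
    assert shape == pytest.approx(1.0)


def test_gamma_rejects_nonpositive():
    with pytest.raises(InfeasibleDistributionError):
        gamma_from_moments(-1.0, 1.0)


def test_gamma_small_sd_concentrates_at_mean():
    spec = DistributionSpec("arms.rituximab.drug_cost", "gamma", 100.0, 0.1)
    rng = np.random.default_rng(0)
    draws = np.array([spec.draw(rng) for _ in range(200)])
    assert np.abs(draws - 100.0).max() < 1.0


def test_moment_recovery_from_large_sample():
    rng = np.random.default_rng(42)
    n = 100_000
    a, b = beta_from_moments(0.754, 0.186)
    beta_draws = rng.beta(a, b, n)
    assert beta_draws.mean() == pytest.approx(0.754, rel=0.01)
    assert beta_draws.std(ddof=1) == pytest.approx(0.186, rel=0.01)
    shape, scale = gamma_from_moments(32_942.24, 0.2 * 32_942.24)
    gamma_draws = rng.gamma(shape, scale, n)
    assert gamma_draws.mean() == pytest.approx(32_942.24, rel=0.01)
    assert gamma_draws.std(ddof=1) == pytest.approx(0.2 * 32_942.24, rel=0.01)


# -------------------------------------------------------------------- PSA


def test_same_seed_reproduces_samples(base_cfg):
    cfg = PSAConfig(specs=tuple(default_psa_specs(base_cfg)), n_iterations=20, seed=5)
    s1 = run_psa(base_cfg, cfg)
    s2 = run_psa(base_cfg, cfg)
    pd.testing.assert_frame_equal(s1, s2)
    s3 = run_psa(
        base_cfg,
        PSAConfig(specs=cfg.specs, n_iterations=20, seed=6),
    )
    assert not s3["delta_cost"].equals(s1["delta_cost"])


def test_vanishing_uncertainty_recovers_base_case(base_cfg):
    """With SDs shrunk toward zero, a single draw sits on the deterministic
    base case."""
    results, _ = evaluate_config(base_cfg)
    specs = [
        DistributionSpec(s.path, s.family, s.mean, s.mean * 1e-5)
        for s in default_psa_specs(base_cfg)
    ]
    samples = run_psa(
        base_cfg, PSAConfig(specs=tuple(specs), n_iterations=1, seed=0)
    )
    a = samples.attrs["intervention"]
    b = samples.attrs["comparator"]
    assert samples[f"cost_{a}"].iloc[0] == pytest.approx(
        results[a].total_cost, rel=1e-3
    )
    assert samples[f"qaly_{b}"].iloc[0] == pytest.approx(
        results[b].total_qalys, rel=1e-3
    )


def test_drawn_parameters_respect_domains(base_cfg):
    cfg = PSAConfig(specs=tuple(default_psa_specs(base_cfg)), n_iterations=50, seed=3)
    samples = run_psa(base_cfg, cfg)
    for spec in cfg.specs:
        col = samples[f"param:{spec.path}"]
        if spec.family == "beta":
            assert ((col > 0) & (col < 1)).all()
        else:
            assert (col > 0).all()


# ------------------------------------------------------------- CEAC / plane


def hand_samples(rows):
    df = pd.DataFrame(rows, columns=["delta_qaly", "delta_cost"])
    df.attrs["intervention"] = "a"
    df.attrs["comparator"] = "b"
    return df


def test_ceac_counts_positive_nmb_fraction():
    # Signs of the NMB difference at lambda=10: +, +, -, +  ->  0.75.
    df = hand_samples([(1.0, 5.0), (1.0, -5.0), (-1.0, 5.0), (0.5, 1.0)])
    curve = ceac(df, [10.0])
    assert curve["p_a"].iloc[0] == pytest.approx(0.75)
    assert curve["p_b"].iloc[0] == pytest.approx(0.25)


def test_ceac_at_zero_threshold_is_cheaper_fraction():
    df = hand_samples([(1.0, 5.0), (1.0, -5.0), (-1.0, -5.0), (0.5, 1.0)])
    curve = ceac(df, [0.0])
    assert curve["p_a"].iloc[0] == pytest.approx(0.5)


def test_ceac_ties_split_equally():
    df = hand_samples([(1.0, 10.0), (1.0, -10.0)])
    curve = ceac(df, [10.0])  # first sample ties exactly
    assert curve["p_a"].iloc[0] == pytest.approx(0.75)


def test_dominant_in_every_draw_gives_unit_ceac():
    df = hand_samples([(0.5, -100.0), (1.0, -50.0), (0.1, -200.0)])
    curve = ceac(df, np.linspace(0, 100_000, 11))
    assert (curve["p_a"] == 1.0).all()


def test_ceac_requires_thresholds_and_samples():
    df = hand_samples([(1.0, -1.0)])
    with pytest.raises(SensitivityError):
        ceac(df, [])
    with pytest.raises(SensitivityError):
        ceac(df.iloc[0:0], [1.0])


def test_ce_plane_one_point_per_quadrant():
    df = hand_samples([(1.0, 1.0), (1.0, -1.0), (-1.0, 1.0), (-1.0, -1.0)])
    plane = ce_plane(df, threshold=1.0)
    for key in (
        "more_effective_cheaper",
        "more_effective_costlier",
        "less_effective_cheaper",
        "less_effective_costlier",
    ):
        assert plane[key] == pytest.approx(0.25)


def test_ce_plane_symmetric_cloud(base_cfg):
    rng = np.random.default_rng(1)
    df = hand_samples(list(zip(rng.normal(size=4000), rng.normal(size=4000))))
    plane = ce_plane(df, threshold=1.0)
    for key in (
        "more_effective_cheaper",
        "more_effective_costlier",
        "less_effective_cheaper",
        "less_effective_costlier",
    ):
        assert plane[key] == pytest.approx(0.25, abs=0.03)
    assert sum(v for k, v in plane.items() if k != "accept") == pytest.approx(1.0)


def test_ce_plane_all_dominant():
    df = hand_samples([(1.0, -1.0)] * 10)
    plane = ce_plane(df, threshold=37_641.0)
    assert plane["more_effective_cheaper"] == 1.0
    assert plane["accept"] == 1.0


# ----------------------------------------------------------------- tornado


def test_zero_influence_parameter_has_zero_width(base_cfg):
    # A cost attached to a state shared identically by both arms still moves
    # each arm, but a parameter of an unreachable kind: use a utility of the
    # intervention set equal across low/high by clamping at 1.0 twice.
    cfg = copy_config(base_cfg)
    # Make the worst-band other-cost zero in both arms: perturbing zero is
    # still zero, so the bar collapses.
    set_path(cfg, "arms.rituximab.other_costs.edss_8_9_5", 0.0)
    entries = tornado(cfg, paths=["arms.rituximab.other_costs.edss_8_9_5"])
    assert entries[0].width == pytest.approx(0.0, abs=1e-9)
    assert entries[0].cost_width == pytest.approx(0.0, abs=1e-9)


def test_utility_perturbation_clamped_at_one(base_cfg):
    cfg = copy_config(base_cfg)
    set_path(cfg, "arms.rituximab.utilities.edss_0_2_5", 0.95)
    with pytest.warns(UserWarning, match="clamped"):
        entries = tornado(cfg, paths=["arms.rituximab.utilities.edss_0_2_5"])
    assert entries[0].high_input == 1.0


def test_cost_perturbation_is_linear_in_discounted_stream(base_cfg):
    """+/-20% on the intervention's drug cost moves the incremental cost by
    exactly -/+20% of that arm's discounted drug-cost stream."""
    from mscea.config import build_settings, build_transition_table, build_arm
    from mscea.markov_engine import run_cohort
    from mscea.states import LIVING_STATES

    tt = build_transition_table(base_cfg)
    settings_ = build_settings(base_cfg)
    arm = build_arm(base_cfg, "rituximab")
    trace, _ = run_cohort(tt, arm, settings_)
    active_idx = [LIVING_STATES.index(s) for s in arm.dmt_active_states]
    v = 1.0 + settings_.discount_rate_costs
    stream = sum(
        trace.occupancy[k, active_idx].sum() * v**-k
        for k in range(len(trace.cycles))
    ) * arm.drug_cost

    entries = tornado(base_cfg, paths=["arms.rituximab.drug_cost"])
    e = entries[0]
    assert e.inc_cost_high - e.inc_cost_low == pytest.approx(0.4 * stream, rel=1e-9)
    assert e.inc_cost_low == pytest.approx(
        e.inc_cost_high - 0.4 * stream, rel=1e-9
    )


def test_tornado_sorted_by_bar_width(base_cfg):
    entries = tornado(base_cfg)
    widths = [e.width for e in entries]
    assert widths == sorted(widths, reverse=True)


def test_widest_bar_is_comparator_drug_price(base_cfg):
    entries = tornado(base_cfg)
    assert entries[0].path == "arms.natalizumab.drug_cost"
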