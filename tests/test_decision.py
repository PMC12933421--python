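import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evactwin.decision import (
    AppraisalBranch,
    BeliefInitConfig,
    BeliefState,
    CalibrationConfig,
    ConstraintScore,
    DecisionWeights,
    aggregate_constructs,
    apply_message,
    apply_message_frame,
    appraise,
    calibrate_weights,
    decide,
    decide_frame,
    evacuation_propensity,
    initialize_beliefs,
    initialize_beliefs_frame,
)
from evactwin.maf import ConstructProfile, MessageCategory, profile_for
from evactwin.population import AgentProfile, generate_population_frame

from .conftest import make_single_zone_config


def make_agent(in_flood_zone=False, prior=False, distance=10.0, constraints=()):
    return AgentProfile(
        agent_id="a0",
        zone_id="Z1",
        age_band="35_64",
        income_band="middle",
        education_level="hs",
        ethnicity="a",
        in_flood_zone=in_flood_zone,
        prior_hurricane_experience=prior,
        shelter_distance_km=distance,
        constraints=frozenset(constraints),
    )


NOISELESS = BeliefInitConfig(
    noise_spread={c: 0.0 for c in BeliefInitConfig().noise_spread}
)


def test_belief_state_validates_range():
    with pytest.raises(ValueError):
        BeliefState(1.2, 0.5, 0.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        BeliefState(0.5, -0.1, 0.5, 0.5, 0.5)


def test_flood_zone_raises_susceptibility_noise_disabled():
    flooded = initialize_beliefs(make_agent(in_flood_zone=True), NOISELESS)
    dry = initialize_beliefs(make_agent(in_flood_zone=False), NOISELESS)
    assert flooded.susceptibility > dry.susceptibility
    assert flooded.severity == dry.severity


def test_identity_configuration_returns_baselines():
    cfg = replace(
        NOISELESS,
        flood_zone_susceptibility_shift=0.0,
        prior_hurricane_severity_shift=0.0,
        income_self_efficacy_shift=0.0,
        education_self_efficacy_shift=0.0,
        shelter_proximity_shift=0.0,
    )
    b = initialize_beliefs(make_agent(in_flood_zone=True, prior=True), cfg)
    for name, expected in cfg.baselines.items():
        assert getattr(b, name) == pytest.approx(expected)


def test_belief_means_match_configured_expectation_monte_carlo():
    pop_cfg = make_single_zone_config(
        5_000, seed=13, p_flood_zone=0.4, p_prior_hurricane=0.5, shelter_distance_km=10.0
    )
    frame = generate_population_frame(pop_cfg)
    init = BeliefInitConfig()
    beliefs = initialize_beliefs_frame(frame, init, np.random.default_rng(99))

    zone = pop_cfg.zones[0]
    inc_rank = sum(
        p * i / 2 for i, p in enumerate(zone.income_marginal.probs)
    )
    edu_rank = sum(
        p * i / 3 for i, p in enumerate(zone.education_marginal.probs)
    )
    expected = {
        "severity": init.baselines["severity"]
        + init.prior_hurricane_severity_shift * 0.5,
        "susceptibility": init.baselines["susceptibility"]
        + init.flood_zone_susceptibility_shift * 0.4,
        "self_efficacy": init.baselines["self_efficacy"]
        + init.income_self_efficacy_shift * inc_rank
        + init.education_self_efficacy_shift * edu_rank,
        "response_efficacy": init.baselines["response_efficacy"]
        + init.shelter_proximity_shift * (1 - 10.0 / init.distance_ref_km),
        "subjective_norm": init.baselines["subjective_norm"],
    }
    for name, mu in expected.items():
        assert abs(beliefs[name].mean() - mu) < 0.02, name


def test_apply_control_message_is_identity():
    b = BeliefState(0.3, 0.4, 0.5, 0.6, 0.7)
    assert apply_message(b, profile_for(MessageCategory.CONTROL)) == b


def test_apply_message_clips_at_one():
    b = BeliefState(0.9, 0.9, 0.2, 0.2, 0.2)
    out = apply_message(b, ConstructProfile(0.35, 0.0, 0.0))
    assert out.severity == 1.0 and out.susceptibility == 1.0


def test_fear_only_message_leaves_other_components_untouched():
    b = BeliefState(0.3, 0.4, 0.5, 0.6, 0.7)
    out = apply_message(b, profile_for(MessageCategory.FEAR))
    assert out.self_efficacy == b.self_efficacy
    assert out.response_efficacy == b.response_efficacy
    assert out.subjective_norm == b.subjective_norm
    assert out.severity > b.severity


def test_aggregate_constructs_zero_and_arithmetic():
    assert aggregate_constructs(BeliefState(0, 0, 0, 0, 0)) == (0.0, 0.0, 0.0)
    T, E, N = aggregate_constructs(BeliefState(1.0, 0.0, 0.5, 0.5, 0.3))
    assert (T, E, N) == (0.5, 0.5, 0.3)


@given(
    st.tuples(*[st.floats(0, 1) for _ in range(5)]),
    st.sampled_from(["mean", "min"]),
)
@settings(max_examples=1000, deadline=None)
def test_aggregate_constructs_bounded_by_parents(state, composition):
    b = BeliefState(*state)
    T, E, N = aggregate_constructs(b, composition)
    assert min(b.severity, b.susceptibility) - 1e-12 <= T
    assert T <= max(b.severity, b.susceptibility) + 1e-12
    assert min(b.self_efficacy, b.response_efficacy) - 1e-12 <= E
    assert E <= max(b.self_efficacy, b.response_efficacy) + 1e-12
    assert N == b.subjective_norm


def test_aggregate_constructs_product_below_min():
    b = BeliefState(0.5, 0.4, 0.9, 0.6, 0.3)
    T, E, N = aggregate_constructs(b, "product")
    assert T == pytest.approx(0.2) and T <= min(b.severity, b.susceptibility)
    assert E == pytest.approx(0.54) and E <= min(b.self_efficacy, b.response_efficacy)


def test_appraise_branches():
    w = DecisionWeights(alpha=1, beta=1, gamma=1, delta=1)
    assert appraise(0.9, 0.1, w).branch is AppraisalBranch.FEAR_CONTROL
    assert appraise(0.9, 0.9, w).branch is AppraisalBranch.DANGER_CONTROL
    out = appraise(0.0, 0.0, w)
    assert out.branch is AppraisalBranch.DANGER_CONTROL
    p = evacuation_propensity(0.0, 0.0, 0.0, 1.0, replace(w, intercept=0.5))
    assert p < 0.01


def test_appraise_rejects_out_of_range():
    w = DecisionWeights(alpha=1, beta=1, gamma=1, delta=1)
    with pytest.raises(ValueError):
        appraise(1.5, 0.5, w)


def test_propensity_zero_sum_is_half():
    w = DecisionWeights(alpha=1, beta=1, gamma=1, delta=1, logistic_scale=1.0)
    assert evacuation_propensity(0.0, 0.0, 0.0, 0.0, w) == pytest.approx(0.5)


def test_propensity_closed_form():
    w = DecisionWeights(alpha=2, beta=2, gamma=2, delta=1, logistic_scale=1.0)
    p = evacuation_propensity(1.0, 1.0, 1.0, 0.0, w)
    assert p == pytest.approx(1 / (1 + math.exp(-6.0)), abs=1e-12)
    assert p == pytest.approx(0.9975, abs=5e-4)


def test_propensity_strictly_decreasing_in_constraints():
    w = DecisionWeights(alpha=1, beta=1, gamma=1, delta=1)
    last = 1.1
    for c in np.linspace(0, 1, 11):
        p = evacuation_propensity(0.5, 0.5, 0.5, float(c), w)
        assert p < last
        last = p


def test_decide_tie_resolves_to_evacuate():
    w = DecisionWeights(alpha=1, beta=0, gamma=0, delta=0, tau=0.5, intercept=0.5)
    b = BeliefState(0.5, 0.5, 1.0, 1.0, 0.0)  # alpha*T - intercept = 0 -> p = 0.5
    assert decide(b, 0.0, w) == "evacuate"


def test_decide_fear_control_overrides_high_propensity():
    w = DecisionWeights(alpha=5, beta=0, gamma=0, delta=0, theta_threat=0.6, theta_efficacy=0.4)
    b = BeliefState(0.9, 0.9, 0.1, 0.1, 0.9)
    assert evacuation_propensity(0.9, 0.1, 0.9, 0.0, w) > 0.99
    assert decide(b, 0.0, w) == "stay"


def test_decision_boundary_matches_grid_oracle(shipped_weights):
    """Exhaustive 21^4 oracle: decide_frame vs an independent re-statement of
    the rule (appraisal gate + logistic threshold) evaluated pointwise."""
    grid = np.linspace(0.0, 1.0, 21)
    T, E, N, C = (x.ravel() for x in np.meshgrid(grid, grid, grid, grid))
    frame = pd.DataFrame(
        {
            "severity": T,
            "susceptibility": T,
            "self_efficacy": E,
            "response_efficacy": E,
            "subjective_norm": N,
            "constraint_score": C,
        }
    )
    w = shipped_weights
    got = decide_frame(frame, w)

    s = w.alpha * T + w.beta * E + w.gamma * N - w.delta * C - w.intercept
    sigma = 1.0 / (1.0 + np.exp(-w.logistic_scale * s))
    fear_control = (T >= w.theta_threat) & (E < w.theta_efficacy)
    expected = ~fear_control & (T >= w.theta_threat_low) & (sigma >= w.tau)
    assert np.array_equal(got, expected)


def test_scalar_decide_agrees_with_frame_on_sample(shipped_weights):
    rng = np.random.default_rng(4)
    vals = rng.uniform(0, 1, size=(200, 6))
    frame = pd.DataFrame(
        vals,
        columns=[
            "severity",
            "susceptibility",
            "self_efficacy",
            "response_efficacy",
            "subjective_norm",
            "constraint_score",
        ],
    )
    vector = decide_frame(frame, shipped_weights)
    for i, row in frame.iterrows():
        b = BeliefState(*row[:5])
        scalar = decide(b, float(row["constraint_score"]), shipped_weights)
        assert (scalar == "evacuate") == bool(vector[i])


@given(
    st.tuples(*[st.floats(0, 1) for _ in range(5)]),
    st.lists(
        st.sampled_from(list(MessageCategory)), min_size=0, max_size=12
    ),
)
@settings(max_examples=200, deadline=None)
def test_clipping_under_arbitrary_message_sequences(start, sequence):
    b = BeliefState(*start)
    for cat in sequence:
        b = apply_message(b, profile_for(cat))
        for name in ("severity", "susceptibility", "self_efficacy",
                     "response_efficacy", "subjective_norm"):
            assert 0.0 <= getattr(b, name) <= 1.0


def test_apply_message_frame_matches_scalar():
    rng = np.random.default_rng(8)
    frame = pd.DataFrame(
        rng.uniform(0, 1, size=(50, 5)),
        columns=["severity", "susceptibility", "self_efficacy",
                 "response_efficacy", "subjective_norm"],
    )
    prof = profile_for(MessageCategory.FEAR_EFFICACY_NORM)
    out = apply_message_frame(frame, prof)
    for i in range(len(frame)):
        expected = apply_message(BeliefState(*frame.iloc[i]), prof)
        assert out.iloc[i]["severity"] == pytest.approx(expected.severity)
        assert out.iloc[i]["subjective_norm"] == pytest.approx(expected.subjective_norm)


def test_constraint_score_from_agent():
    agent = make_agent(constraints=("mobility_limited", "pets"))
    score = ConstraintScore.from_agent(agent)
    assert score.value == pytest.approx(0.45)
    heavy = make_agent(
        constraints=("mobility_limited", "no_vehicle", "financial_barrier",
                     "pets", "caregiving")
    )
    assert ConstraintScore.from_agent(heavy).value == 1.0  # capped


SMALL_SEARCH = CalibrationConfig(
    alpha_grid=(0.12, 0.2),
    beta_grid=(0.005, 0.02),
    gamma_grid=(0.005,),
    delta_grid=(0.4,),
    theta_threat_grid=(0.58,),
    theta_efficacy_grid=(0.52, 0.6),
    n_agents=600,
    n_replications=2,
    seed=2024,
)

TABLE5_TARGETS = {
    "control": 0.009,
    "fear": 0.009,
    "efficacy": 0.012,
    "norm": 0.009,
    "fear_efficacy": 0.123,
    "fear_efficacy_norm": 0.154,
}


def test_calibrate_is_seed_deterministic():
    a = calibrate_weights(TABLE5_TARGETS, SMALL_SEARCH)
    b = calibrate_weights(TABLE5_TARGETS, SMALL_SEARCH)
    assert a == b


def test_calibrate_reproduces_qualitative_ordering():
    import evactwin as et

    w = calibrate_weights(TABLE5_TARGETS, SMALL_SEARCH)
    design = et.default_design(master_seed=1, n_replications=3)
    result = et.run_experiment(design, et.load_population_config(), w)
    rates = et.framing_rates(et.build_table(result), et.default_grouping())
    singles = [rates["fear"], rates["efficacy"], rates["norm"]]
    assert max(rates["fear_efficacy"], rates["fear_efficacy_norm"]) > 3 * max(
        rates["control"], *singles
    )


def test_calibrate_handles_degenerate_equal_targets():
    targets = {k: 0.01 for k in TABLE5_TARGETS}
    a = calibrate_weights(targets, SMALL_SEARCH)
    b = calibrate_weights(targets, SMALL_SEARCH)
    assert a == b


def test_calibrate_rejects_bad_targets():
    with pytest.raises(ValueError):
        calibrate_weights({}, SMALL_SEARCH)
    with pytest.raises(ValueError):
        calibrate_weights({"control": 1.5}, SMALL_SEARCH)


def test_decision_weights_validation():
    with pytest.raises(ValueError):
        DecisionWeights(alpha=-0.1, beta=0, gamma=0, delta=0)
    with pytest.raises(ValueError):
        DecisionWeights(alpha=1, beta=1, gamma=1, delta=1, tau=0.0)
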