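"""Platform-trial simulation: single replicates and operating characteristics."""

import numpy as np
import pytest
from scipy.stats import binom

from platoc import (
    AccrualModel,
    ArmSpec,
    BetaPrior,
    DecisionRule,
    TrialScenario,
    mpr_scenario,
    operating_characteristics,
    prob_exceeds_margin,
    simulate_trial,
)
from platoc.simulator import replicate_posteriors


def two_arm_scenario(rate_e, rate_c, **kwargs):
    return TrialScenario(
        arms=(
            ArmSpec("control", "control", rate_c, planned_n=30, open_time=0.0),
            ArmSpec("e1", "experimental", rate_e, planned_n=30, open_time=0.0),
        ),
        rule=DecisionRule(theta_t=0.67, delta=0.05),
        **kwargs,
    )


def test_scenario_requires_exactly_one_control():
    with pytest.raises(ValueError, match="control"):
        TrialScenario(
            arms=(ArmSpec("e1", "experimental", 0.2),),
            rule=DecisionRule(theta_t=0.67),
        )


def test_scenario_requires_experimental_arm():
    with pytest.raises(ValueError):
        TrialScenario(
            arms=(ArmSpec("control", "control", 0.13),),
            rule=DecisionRule(theta_t=0.67),
        )


def test_scenario_requires_increasing_entry_times():
    with pytest.raises(ValueError, match="increasing"):
        TrialScenario(
            arms=(
                ArmSpec("control", "control", 0.13),
                ArmSpec("e1", "experimental", 0.2, open_time=6.0),
                ArmSpec("e2", "experimental", 0.2, open_time=6.0),
            ),
            rule=DecisionRule(theta_t=0.67),
        )


def test_fixed_seed_reproduces_identical_result():
    scenario = mpr_scenario()
    assert simulate_trial(scenario, 123) == simulate_trial(scenario, 123)


def test_certain_effect_always_succeeds():
    scenario = two_arm_scenario(1.0, 0.0)
    for seed in range(5):
        res = simulate_trial(scenario, seed)
        (arm,) = res.arms
        assert arm.success
        assert arm.n_success == 30
        assert arm.posterior_prob > 0.99


def test_no_responses_anywhere_never_succeeds():
    scenario = two_arm_scenario(0.0, 0.0)
    for seed in range(5):
        res = simulate_trial(scenario, seed)
        (arm,) = res.arms
        assert not arm.success
        nc = arm.control_n_at_analysis
        expected_pp = prob_exceeds_margin(BetaPrior(1, 31), BetaPrior(1, 1 + nc), 0.05)
        assert arm.posterior_prob == pytest.approx(expected_pp, abs=1e-10)


def test_experimental_arms_treat_exactly_planned_n():
    res = simulate_trial(mpr_scenario(), 5)
    assert all(a.n_treated == 30 for a in res.arms)


def test_control_exceeds_cap_with_staggered_arms():
    """The control keeps accruing at the rescaled rate after its cap."""
    _, control_n = replicate_posteriors(mpr_scenario(), reps=40, seed=3)
    assert control_n.mean() > 30


def test_accrued_option_uses_controls_available_at_analysis_time():
    res = simulate_trial(mpr_scenario(control_comparison="all_accrued"), 9)
    times = [a.analysis_time for a in res.arms]
    ncs = [a.control_n_at_analysis for a in res.arms]
    # later analyses can only see more control patients
    order = np.argsort(times)
    assert all(ncs[order[i]] <= ncs[order[i + 1]] for i in range(len(order) - 1))
    assert ncs[order[-1]] <= res.control_n_treated


def test_concurrent_control_option_restricts_comparison_set():
    scenario = mpr_scenario(control_comparison="concurrent")
    res = simulate_trial(scenario, 21)
    res_all = simulate_trial(mpr_scenario(), 21)
    for conc, full in zip(res.arms, res_all.arms):
        assert conc.control_n_at_analysis <= full.control_n_at_analysis


def test_fixed_rate_accrual_is_deterministic_in_time():
    scenario = two_arm_scenario(0.3, 0.1, accrual=AccrualModel(kind="fixed_rate", rate=5.0))
    res = simulate_trial(scenario, 0)
    (arm,) = res.arms
    n_total = arm.n_treated + res.control_n_treated
    assert arm.analysis_time == pytest.approx(n_total / 5.0)


def test_single_replicate_oc_is_zero_or_one():
    oc = operating_characteristics(two_arm_scenario(0.3, 0.1), reps=1, seed=4)
    probs = oc.table.query("role == 'experimental'")["prob_claim_success"]
    assert set(probs).issubset({0.0, 1.0})


def test_oc_table_structure():
    oc = operating_characteristics(mpr_scenario(), reps=5, seed=0)
    assert list(oc.table["role"]) == ["control"] + ["experimental"] * 4
    assert oc.reps == 5
    assert oc.table["prob_claim_success"].iloc[1:].between(0, 1).all()
    assert (oc.table["mean_n"].iloc[1:] == 30.0).all()


def _exact_claim_probability(rate_e, rate_c, nc, theta, delta=0.05):
    """Enumeration oracle: Pr(claim) for a fixed 30-vs-nc comparison."""
    total = 0.0
    for se in range(31):
        w_e = binom.pmf(se, 30, rate_e)
        if w_e < 1e-10:
            continue
        for sc in range(nc + 1):
            w_c = binom.pmf(sc, nc, rate_c)
            if w_c < 1e-10:
                continue
            pp = prob_exceeds_margin(BetaPrior(1 + se, 31 - se), BetaPrior(1 + sc, 1 + nc - sc), delta)
            if pp > theta:
                total += w_e * w_c
    return total


def test_simulator_matches_enumeration_conditional_on_control_size():
    """Conditioned on the realized control size, the simulated claim rate
    matches a direct binomial-by-binomial enumeration within 3 SEs."""
    scenario = two_arm_scenario(0.26, 0.13)
    reps = 500
    streams = np.random.SeedSequence(77).spawn(reps)
    by_nc = {}
    for ss in streams:
        res = simulate_trial(scenario, np.random.default_rng(ss))
        (arm,) = res.arms
        by_nc.setdefault(arm.control_n_at_analysis, []).append(arm.success)
    nc, successes = max(by_nc.items(), key=lambda kv: len(kv[1]))
    k = len(successes)
    assert k >= 30  # modal control size has enough replicates to compare
    p_exact = _exact_claim_probability(0.26, 0.13, nc, 0.67)
    se = np.sqrt(p_exact * (1 - p_exact) / k)
    assert abs(np.mean(successes) - p_exact) < 3 * se + 1e-6


def test_success_probability_monotone_in_true_rate():
    """More effective arms are claimed successful more often."""
    oc = operating_characteristics(mpr_scenario(), reps=300, seed=8)
    probs = dict(zip(oc.table["true_rate"].iloc[1:], oc.table["prob_claim_success"].iloc[1:]))
    assert probs[0.13] < probs[0.26]
    assert probs[0.13] < probs[0.30]
    assert probs[0.195] < probs[0.30]
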