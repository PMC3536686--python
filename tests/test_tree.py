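"""Decision-tree structure and the two independent evaluation routes."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trackcea import tree
from trackcea.tree import StrategyParams, enumerate_paths, expected_outcomes

prob = st.floats(0.0, 1.0, allow_nan=False)
cost = st.floats(0.0, 200.0, allow_nan=False)


@st.composite
def strategy_params(draw, arm=None):
    return StrategyParams(
        arm=arm or draw(st.sampled_from(["tracking", "no_tracking"])),
        p_ltfu=tuple(draw(prob) for _ in range(4)),
        p_fail=tuple(draw(prob) for _ in range(4)),
        p_diag2=draw(prob),
        p_diag3=draw(prob),
        stage_costs=tuple(draw(cost) for _ in range(4)),
        c_track=draw(st.floats(0.0, 20.0)),
        attachment=draw(st.sampled_from(["fail1", "per_screened",
                                         "each_followup"])),
    )


@settings(max_examples=200, derandomize=True, deadline=None)
@given(strategy_params())
def test_terminal_probabilities_sum_to_one(params):
    total = math.fsum(p.probability for p in enumerate_paths(params))
    assert total == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(strategy_params())
def test_rollback_equals_path_enumeration(params):
    """Closed-form expectations agree with the path sum to 1e-12."""
    exp = expected_outcomes(params)
    paths = enumerate_paths(params)
    cost_sum = math.fsum(p.probability * p.accrued_cost for p in paths)
    eff_sum = math.fsum(p.probability for p in paths if p.detected)
    assert exp.expected_cost == pytest.approx(cost_sum, abs=1e-12 * (1 + cost_sum))
    assert exp.expected_effect == pytest.approx(eff_sum, abs=1e-12)


def test_eleven_terminals_with_expected_labels(tracking_params):
    paths = enumerate_paths(tracking_params)
    assert len(paths) == 11
    labels = [p.label for p in paths]
    assert labels[0] == "not_screened"
    assert sum(p.detected for p in paths) == 3
    assert {"diagnosed_after_test_2", "diagnosed_after_test_3",
            "detected_at_test_4"} == {p.label for p in paths if p.detected}


def test_no_failures_collapses_to_two_live_branches(tracking_params):
    from dataclasses import replace

    params = replace(tracking_params, p_fail=(0.0, 0.0, 0.0, 0.0))
    live = [p for p in enumerate_paths(params) if p.probability > 0]
    assert {p.label for p in live} == {"not_screened", "exit_after_test_1"}
    assert expected_outcomes(params).expected_effect == 0.0


def test_unscreened_children_cost_nothing(no_tracking_params):
    not_screened = enumerate_paths(no_tracking_params)[0]
    assert not_screened.accrued_cost == 0.0 and not not_screened.detected


def test_tracking_fee_charged_only_on_first_test_failure(tracking_params):
    """Default attachment: c_track appears in exactly the post-fail1 paths."""
    with_fee = {p.label for p in enumerate_paths(tracking_params)
                if p.probability > 0 and p.label not in
                ("not_screened", "exit_after_test_1")}
    c1 = tracking_params.stage_costs[0]
    for p in enumerate_paths(tracking_params):
        share = p.accrued_cost - (0.0 if p.label == "not_screened" else c1)
        if p.label in with_fee:
            assert share >= tracking_params.c_track - 1e-12
        elif p.label == "exit_after_test_1":
            assert share == 0.0


@pytest.mark.parametrize("k", [1, 2, 3])
def test_more_followup_loss_detects_fewer_cases(tracking_params, k):
    from dataclasses import replace

    ltfu = list(tracking_params.p_ltfu)
    ltfu[k] = min(1.0, ltfu[k] + 0.2)
    worse = replace(tracking_params, p_ltfu=tuple(ltfu))
    assert expected_outcomes(worse).expected_effect \
        <= expected_outcomes(tracking_params).expected_effect


@pytest.mark.parametrize("k", [0, 1, 2, 3])
def test_higher_failure_probability_detects_more_cases(no_tracking_params, k):
    from dataclasses import replace

    fail = list(no_tracking_params.p_fail)
    fail[k] = min(1.0, fail[k] + 0.2)
    more = replace(no_tracking_params, p_fail=tuple(fail))
    assert expected_outcomes(more).expected_effect \
        >= expected_outcomes(no_tracking_params).expected_effect


def test_arms_coincide_when_tracking_changes_nothing(inputs):
    """Equal LTFU and a zero fee make the strategies indistinguishable."""
    nt = StrategyParams.from_inputs(inputs, "no_tracking")
    from dataclasses import replace

    t = replace(StrategyParams.from_inputs(inputs, "tracking"),
                p_ltfu=nt.p_ltfu, c_track=0.0)
    et, ent = expected_outcomes(t), expected_outcomes(nt)
    assert et.expected_cost == pytest.approx(ent.expected_cost, abs=1e-12)
    assert et.expected_effect == pytest.approx(ent.expected_effect, abs=1e-15)


def test_scale_to_cohort(base_arms):
    t, nt = base_arms
    cases_nt, rounded_nt = tree.scale_to_cohort(nt, 100_000)
    cases_t, rounded_t = tree.scale_to_cohort(t, 100_000)
    assert rounded_nt == 21
    assert cases_t == pytest.approx(51.7, abs=0.5)
    assert tree.scale_to_cohort(
        tree.ArmExpectation("x", 0.0, 0.0), 1000) == (0.0, 0)
    with pytest.raises(ValueError):
        tree.scale_to_cohort(t, 0)


def test_attachment_modes_order_total_cost(inputs):
    """Per-screened charging is far more expensive than charging failures."""
    costs = {}
    for mode in ("fail1", "per_screened", "each_followup"):
        p = StrategyParams.from_inputs(inputs, "tracking", mode)
        costs[mode] = expected_outcomes(p).expected_cost
    assert costs["per_screened"] > costs["fail1"]
    assert costs["per_screened"] - costs["fail1"] > 4.0  # ~0.955 x 4.55
    assert costs["each_followup"] > costs["fail1"] - 4.55


def test_invalid_parameters_rejected(inputs):
    with pytest.raises(ValueError):
        StrategyParams("tracking", (0.1, 0.2, 0.3, 1.4), (0.1,) * 4,
                       0.1, 0.1, (1.0,) * 4)
    with pytest.raises(ValueError):
        StrategyParams("tracking", (0.1,) * 4, (0.1,) * 4,
                       0.1, 0.1, (1.0, 1.0, -1.0, 1.0))


def test_paths_table_and_tree_rendering(tracking_params):
    df = tree.paths_table(enumerate_paths(tracking_params))
    assert list(df.columns) == ["label", "probability", "accrued_cost",
                                "detected"]
    assert len(df) == 11
    assert "bilateral fail" in tree.format_tree(tracking_params)
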