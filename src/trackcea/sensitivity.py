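"""Deterministic, structural and probabilistic sensitivity analyses.

One-way analysis varies each parameter to 50% and 150% of its base value
(rounded to two decimals before evaluation, the precision at which the
varied values are tabulated); the structural analysis forces every failed
second (or third) test straight to the diagnostic visit; the probabilistic
analysis is a second-order Monte Carlo over beta-distributed probabilities
and gamma-distributed costs, re-evaluating both arms per draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from . import tree
from .cea import CEComparison, icer
from .parameters import STAGE_COST_NAMES, ModelInputs, default_inputs

__all__ = ["ScenarioSpec", "univariate_sa", "table6", "structural_sa",
           "run_psa", "UNIVARIATE_PARAMS", "STRUCTURAL_SCENARIOS"]

#: Parameters varied in the published one-way analysis: follow-up losses
#: before tests 2-4 in both arms, and the tracking fee.
UNIVARIATE_PARAMS = ("p_Ltfu2_t", "p_Ltfu2_nt", "p_Ltfu3_t", "p_Ltfu3_nt",
                     "p_Ltfu4_t", "p_Ltfu4_nt", "c_tracking")


@dataclass(frozen=True)
class ScenarioSpec:
    """A structural scenario: named parameter overrides."""

    name: str
    overrides: dict[str, float] = field(default_factory=dict)


#: Everybody who bilaterally fails test 2 (scenario A) or test 3 after a
#: continued test-2 failure (scenario B) is referred straight to the
#: pediatric audiologist and receives a final diagnosis there.
STRUCTURAL_SCENARIOS = (
    ScenarioSpec("diagnosis_after_2nd_test", {"p_diagnosis_after_2nd_test": 1.0}),
    ScenarioSpec("diagnosis_after_3rd_test", {"p_diagnosis_after_2nd_test": 0.0,
                                              "p_diagnosis_after_3rd_test": 1.0}),
)


def _round2(x: float) -> float:
    """Two-decimal half-up rounding, matching the tabulated varied values.

    A ±50% perturbation of a two-decimal base lands exactly on a half cent
    (e.g. 1.5 x 0.29 = 0.435); pre-rounding to nine decimals removes the
    binary representation error so the half rounds up, not to even.
    """
    return float(Decimal(repr(round(x, 9))).quantize(Decimal("0.01"),
                                                     ROUND_HALF_UP))


def _evaluate(inputs: ModelInputs, attachment: tree.Attachment):
    t = tree.expected_outcomes(
        tree.StrategyParams.from_inputs(inputs, "tracking", attachment),
        include_paths=False)
    nt = tree.expected_outcomes(
        tree.StrategyParams.from_inputs(inputs, "no_tracking", attachment),
        include_paths=False)
    return t, nt


def univariate_sa(param: str, low: float | None = None,
                  high: float | None = None,
                  inputs: ModelInputs | None = None,
                  attachment: tree.Attachment = "fail1") -> pd.DataFrame:
    """One-way sensitivity analysis of a single parameter.

    Evaluates both arms at the low, base and high value (defaults: base
    ±50%, rounded to two decimals; probabilities clamped to [0, 1]) and
    recomputes the ICER.  Arm-specific parameters move only within their
    own arm; shared parameters move in both.
    """
    if inputs is None:
        inputs = default_inputs()
    if param not in inputs.parameter_names():
        raise KeyError(f"unknown model parameter {param!r}")
    base = inputs.value(param)
    is_prob = param in inputs.probabilities
    if low is None:
        low = _round2(0.5 * base)
    if high is None:
        high = _round2(1.5 * base)
    if is_prob:
        low, high = max(low, 0.0), min(high, 1.0)
    if not low <= base <= high:
        raise ValueError(f"{param}: require low <= base <= high, "
                         f"got ({low}, {base}, {high})")
    rows = []
    for value in (low, base, high):
        t, nt = _evaluate(inputs.with_overrides({param: value}), attachment)
        comp = icer(t.expected_cost, t.expected_effect,
                    nt.expected_cost, nt.expected_effect)
        rows.append({
            "parameter": param, "value": value,
            "cost_no_tracking": nt.expected_cost,
            "cost_tracking": t.expected_cost,
            "incremental_cost": comp.delta_cost,
            "effect_no_tracking": nt.expected_effect,
            "effect_tracking": t.expected_effect,
            "incremental_effect": comp.delta_effect,
            "icer": comp.icer,
        })
    return pd.DataFrame(rows)


def table6(inputs: ModelInputs | None = None,
           attachment: tree.Attachment = "fail1") -> pd.DataFrame:
    """The full one-way analysis: 7 parameters x {low, base, high}."""
    frames = [univariate_sa(p, inputs=inputs, attachment=attachment)
              for p in UNIVARIATE_PARAMS]
    return pd.concat(frames, ignore_index=True)


def structural_sa(scenario: ScenarioSpec,
                  inputs: ModelInputs | None = None,
                  attachment: tree.Attachment = "fail1") -> CEComparison:
    """Evaluate both arms under a structural scenario's overrides."""
    if inputs is None:
        inputs = default_inputs()
    t, nt = _evaluate(inputs.with_overrides(scenario.overrides), attachment)
    return icer(t.expected_cost, t.expected_effect,
                nt.expected_cost, nt.expected_effect)


def run_psa(n_iter: int = 10_000, seed: int | np.random.Generator = 0,
            inputs: ModelInputs | None = None,
            attachment: tree.Attachment = "fail1",
            point_mass: bool = False) -> pd.DataFrame:
    """Second-order Monte Carlo over all uncertain parameters.

    Each iteration draws every probability from its beta distribution and
    every cost from its gamma distribution, then evaluates both arms on the
    same draw.  Shared parameters (failure and referral probabilities,
    costs) use one draw per iteration across arms; the arm-specific
    loss-to-follow-up parameters are distinct named parameters and are
    drawn independently.  Returns one row per draw with the full sampled
    vector, per-arm outcomes and the incremental pair (delta_cost,
    delta_effect); fully reproducible from ``seed``.

    ``point_mass=True`` freezes every distribution at its base value
    (a degenerate PSA; every row then equals the base case).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if inputs is None:
        inputs = default_inputs()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    dists = inputs.uncertainty()  # raises before sampling if infeasible
    draws: dict[str, np.ndarray] = {}
    for name in (*inputs.probabilities, *STAGE_COST_NAMES, "c_tracking"):
        if point_mass:
            draws[name] = np.full(n_iter, inputs.value(name))
        else:
            draws[name] = dists[name].sample(rng, n_iter)

    def arm_outcomes(suffix: str, tracked: bool):
        c1, c2, c3, cpa = (draws[n] for n in STAGE_COST_NAMES)
        ct = draws["c_tracking"] if tracked else np.zeros(n_iter)
        if attachment == "fail1":
            node = (c1, c2, c3, cpa, cpa, ct)
        elif attachment == "per_screened":
            node = (c1 + ct, c2, c3, cpa, cpa, np.zeros(n_iter))
        elif attachment == "each_followup":
            node = (c1, c2 + ct, c3 + ct, cpa, cpa + ct, np.zeros(n_iter))
        else:
            raise ValueError(f"unknown attachment {attachment!r}")
        return tree._rollback(
            *(draws[f"p_Ltfu{k}{suffix}"] for k in range(1, 5)),
            draws["p_fail_1st_test"], draws["p_fail_2nd_test"],
            draws["p_fail_3rd_test"], draws["p_fail_4th_test"],
            draws["p_diagnosis_after_2nd_test"],
            draws["p_diagnosis_after_3rd_test"], *node)

    cost_t, eff_t = arm_outcomes("_t", True)
    cost_nt, eff_nt = arm_outcomes("_nt", False)
    out = pd.DataFrame(draws)
    out.insert(0, "draw", np.arange(n_iter))
    out["cost_tracking"] = cost_t
    out["effect_tracking"] = eff_t
    out["cost_no_tracking"] = cost_nt
    out["effect_no_tracking"] = eff_nt
    out["delta_cost"] = cost_t - cost_nt
    out["delta_effect"] = eff_t - eff_nt
    return out
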