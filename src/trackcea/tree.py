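"""Four-stage test-procedure decision tree, evaluated analytically.

A cohort newborn either is not screened, or enters the in-hospital two-stage
screen (test 1).  Newborns bilaterally failing a test are scheduled for the
next one; before each follow-up test they may be lost to follow-up, and
after bilaterally failing test 2 or test 3 they may instead be referred
directly to the pediatric audiologist for an early diagnosis.  Test 4 *is*
the diagnostic visit; bilateral failure there confirms the case.  Passing,
unilateral failure and loss to follow-up all leave the procedure undetected
(such children may be found later, outside the programme, and do not count
towards its yield).

The two strategy arms differ only in the loss-to-follow-up probabilities
(tracking recalls families by letter and telephone) and in the per-newborn
tracking surcharge.  Expected cost and expected detected cases per cohort
newborn are computed two independent ways — a closed-form rollback and an
explicit terminal-path enumeration — which must agree to 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .parameters import ModelInputs, STAGE_COST_NAMES

__all__ = [
    "Attachment",
    "StrategyParams",
    "TerminalPath",
    "ArmExpectation",
    "enumerate_paths",
    "expected_outcomes",
    "scale_to_cohort",
]

#: Where the tracking surcharge is charged in the tracking arm.  The node
#: used by the original TreeAge model is not recoverable; charging it once
#: per newborn bilaterally failing the first test is the only attachment
#: consistent with the published one-way sensitivity of total cost to the
#: tracking fee (a weight of about P(screened) x P(fail test 1) ~ 0.006).
Attachment = Literal["fail1", "per_screened", "each_followup"]


@dataclass(frozen=True)
class StrategyParams:
    """Complete parameter set for one strategy arm."""

    arm: Literal["tracking", "no_tracking"]
    p_ltfu: tuple[float, float, float, float]  # before tests 1..4
    p_fail: tuple[float, float, float, float]  # bilateral failure at tests 1..4
    p_diag2: float  # referred for early diagnosis after failing test 2
    p_diag3: float  # ... after failing test 3
    stage_costs: tuple[float, float, float, float]  # c1, c2, c3, c_PA
    c_track: float = 0.0
    attachment: Attachment = "fail1"

    def __post_init__(self) -> None:
        for p in (*self.p_ltfu, *self.p_fail, self.p_diag2, self.p_diag3):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for c in (*self.stage_costs, self.c_track):
            if c < 0:
                raise ValueError("costs must be >= 0")

    @classmethod
    def from_inputs(cls, inputs: ModelInputs,
                    arm: Literal["tracking", "no_tracking"],
                    attachment: Attachment = "fail1") -> "StrategyParams":
        suffix = "_t" if arm == "tracking" else "_nt"
        v = inputs.value
        return cls(
            arm=arm,
            p_ltfu=tuple(v(f"p_Ltfu{k}{suffix}") for k in range(1, 5)),
            p_fail=(v("p_fail_1st_test"), v("p_fail_2nd_test"),
                    v("p_fail_3rd_test"), v("p_fail_4th_test")),
            p_diag2=v("p_diagnosis_after_2nd_test"),
            p_diag3=v("p_diagnosis_after_3rd_test"),
            stage_costs=tuple(v(n) for n in STAGE_COST_NAMES),
            c_track=v("c_tracking") if arm == "tracking" else 0.0,
            attachment=attachment,
        )


@dataclass(frozen=True)
class TerminalPath:
    label: str
    probability: float
    accrued_cost: float
    detected: bool


@dataclass(frozen=True)
class ArmExpectation:
    """Per-cohort-newborn expected cost (EUR) and detected cases for one arm."""

    arm: str
    expected_cost: float
    expected_effect: float
    terminal_paths: tuple[TerminalPath, ...] = field(default=(), repr=False)


def _node_costs(params: StrategyParams):
    """Stage costs with the tracking surcharge folded into its charge node.

    Returns (c1, c2, c3, c_pa_diag, c_pa_test4, c_fail1_extra): the cost of
    tests 1-3, of the early-diagnosis visit, of the attended fourth test,
    and the lump charged once at bilateral first-test failure.
    """
    c1, c2, c3, cpa = params.stage_costs
    ct = params.c_track if params.arm == "tracking" else 0.0
    if params.attachment == "fail1":
        return c1, c2, c3, cpa, cpa, ct
    if params.attachment == "per_screened":
        return c1 + ct, c2, c3, cpa, cpa, 0.0
    if params.attachment == "each_followup":
        return c1, c2 + ct, c3 + ct, cpa, cpa + ct, 0.0
    raise ValueError(f"unknown attachment {params.attachment!r}")


def enumerate_paths(params: StrategyParams) -> list[TerminalPath]:
    """All terminal paths of the tree, as branch-probability products.

    Eleven terminals: not screened; pass/unilateral exit after each of
    tests 1-4; loss to follow-up before tests 2-4; early diagnosis after
    tests 2 and 3; bilateral failure at test 4 (the confirmed case).
    """
    l1, l2, l3, l4 = params.p_ltfu
    f1, f2, f3, f4 = params.p_fail
    d2, d3 = params.p_diag2, params.p_diag3
    c1, c2, c3, cpa_d, cpa4, c_f1 = _node_costs(params)

    s = 1.0 - l1                     # screened
    pf1 = s * f1                     # bilaterally failed test 1
    at2 = pf1 * (1.0 - l2)           # attended test 2
    pf2 = at2 * f2
    cont3 = pf2 * (1.0 - d2)         # failed test 2, not referred early
    at3 = cont3 * (1.0 - l3)
    pf3 = at3 * f3
    cont4 = pf3 * (1.0 - d3)
    at4 = cont4 * (1.0 - l4)

    k1 = c1 + c_f1                   # accrued by every first-test failure
    paths = [
        TerminalPath("not_screened", l1, 0.0, False),
        TerminalPath("exit_after_test_1", s * (1.0 - f1), c1, False),
        TerminalPath("ltfu_before_test_2", pf1 * l2, k1, False),
        TerminalPath("exit_after_test_2", at2 * (1.0 - f2), k1 + c2, False),
        TerminalPath("diagnosed_after_test_2", pf2 * d2, k1 + c2 + cpa_d, True),
        TerminalPath("ltfu_before_test_3", cont3 * l3, k1 + c2, False),
        TerminalPath("exit_after_test_3", at3 * (1.0 - f3), k1 + c2 + c3, False),
        TerminalPath("diagnosed_after_test_3", pf3 * d3,
                     k1 + c2 + c3 + cpa_d, True),
        TerminalPath("ltfu_before_test_4", cont4 * l4, k1 + c2 + c3, False),
        TerminalPath("exit_after_test_4", at4 * (1.0 - f4),
                     k1 + c2 + c3 + cpa4, False),
        TerminalPath("detected_at_test_4", at4 * f4,
                     k1 + c2 + c3 + cpa4, True),
    ]
    return paths


def _rollback(l1, l2, l3, l4, f1, f2, f3, f4, d2, d3,
              c1, c2, c3, cpa_d, cpa4, c_f1):
    """Closed-form expected (cost, effect); numpy-broadcastable.

    Rolled back from the deepest stage: every attended fourth test costs
    ``cpa4`` and detects with probability f4; a failed third (second) test
    is referred for diagnosis with probability d3 (d2) at cost ``cpa_d``.
    """
    a2, a3, a4 = 1.0 - l2, 1.0 - l3, 1.0 - l4
    s = 1.0 - l1
    effect = s * f1 * a2 * f2 * (d2 + (1.0 - d2) * a3 * f3
                                 * (d3 + (1.0 - d3) * a4 * f4))
    cost = s * c1 + s * f1 * (
        c_f1 + a2 * (c2 + f2 * (d2 * cpa_d + (1.0 - d2) * a3
                                * (c3 + f3 * (d3 * cpa_d
                                              + (1.0 - d3) * a4 * cpa4))))
    )
    return cost, effect


def expected_outcomes(params: StrategyParams,
                      include_paths: bool = True) -> ArmExpectation:
    """Expected cost and detected cases per cohort newborn for one arm."""
    cost, effect = _rollback(*params.p_ltfu, *params.p_fail,
                             params.p_diag2, params.p_diag3,
                             *_node_costs(params))
    paths = tuple(enumerate_paths(params)) if include_paths else ()
    return ArmExpectation(params.arm, float(cost), float(effect), paths)


def scale_to_cohort(expectation: ArmExpectation, n: int) -> tuple[float, int]:
    """Detected cases in a cohort of ``n`` newborns (exact, and rounded)."""
    if n <= 0:
        raise ValueError("cohort size must be > 0")
    cases = n * expectation.expected_effect
    return cases, int(round(cases))


def paths_table(paths: Sequence[TerminalPath]):
    """Terminal paths as a DataFrame (label, probability, cost, detected)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "label": [p.label for p in paths],
            "probability": [p.probability for p in paths],
            "accrued_cost": [p.accrued_cost for p in paths],
            "detected": [p.detected for p in paths],
        }
    )


def format_tree(params: StrategyParams) -> str:
    """Indented text rendering of the tree for documentation."""
    l1, l2, l3, l4 = params.p_ltfu
    f1, f2, f3, f4 = params.p_fail
    lines = [
        f"{params.arm}",
        f"├─ not screened (p={l1:g})",
        f"└─ screened: test 1 (p={1 - l1:g})",
        f"   ├─ pass / unilateral fail (p={1 - f1:g})",
        f"   └─ bilateral fail (p={f1:g})",
        f"      ├─ lost before test 2 (p={l2:g})",
        f"      └─ test 2 (p={1 - l2:g})",
        f"         ├─ pass / unilateral fail (p={1 - f2:g})",
        f"         └─ bilateral fail (p={f2:g})",
        f"            ├─ early diagnosis (p={params.p_diag2:g}) [detected]",
        f"            ├─ lost before test 3",
        f"            └─ test 3 ... analogous; test 4 is the diagnostic visit",
    ]
    return "\n".join(lines)
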