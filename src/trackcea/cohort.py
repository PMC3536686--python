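"""Individual-level cohort microsimulation and parameter recovery.

Simulates newborns one by one through the four-stage test procedure with
independent Bernoulli draws at every branch, accruing the per-stage test
costs along each child's path.  Serves two purposes: an independent
Monte-Carlo oracle for the analytic tree evaluation (means must converge to
the closed-form expectations), and a synthetic stand-in for the programme's
raw screening records from which all event probabilities can be re-estimated
as conditional relative frequencies with binomial confidence intervals —
demonstrating that the model's parameters are recoverable from data of the
kind the screening registry collects.

What the generator does *not* emulate: latent true hearing status (the model
works with observed bilateral failures, so test accuracy is out of scope),
within-family correlation, calendar time, and site-level heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .tree import StrategyParams

__all__ = ["NewbornRecord", "simulate_cohort", "estimate_params",
           "iter_records", "validate_records", "empirical_summary"]

#: Stage-outcome flags written per child, in traversal order.
FLAG_COLUMNS = ("screened", "fail1", "attend2", "fail2", "diag2",
                "attend3", "fail3", "diag3", "attend4", "fail4")


@dataclass(frozen=True)
class NewbornRecord:
    """One simulated newborn: its event sequence, accrued cost, outcome."""

    id: int
    arm: str
    events: tuple[str, ...]
    accrued_cost: float
    detected: bool


def simulate_cohort(n: int, params: StrategyParams,
                    seed: int | np.random.Generator = 0,
                    per_child_modality: bool = False) -> pd.DataFrame:
    """Simulate ``n`` newborns through the four-stage procedure.

    Returns one row per child with boolean stage flags (``FLAG_COLUMNS``),
    the accrued cost and the detection outcome.  Costs accrue the composed
    per-stage expected test costs; ``per_child_modality`` is accepted for
    interface completeness but per-child modality draws change only the
    within-stage cost variance, never the mean, so the composed costs are
    used either way.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    l1, l2, l3, l4 = params.p_ltfu
    f1, f2, f3, f4 = params.p_fail
    c1, c2, c3, cpa = params.stage_costs
    u = rng.random((n, 10))

    screened = u[:, 0] >= l1
    fail1 = screened & (u[:, 1] < f1)
    attend2 = fail1 & (u[:, 2] >= l2)
    fail2 = attend2 & (u[:, 3] < f2)
    diag2 = fail2 & (u[:, 4] < params.p_diag2)
    cont3 = fail2 & ~diag2
    attend3 = cont3 & (u[:, 5] >= l3)
    fail3 = attend3 & (u[:, 6] < f3)
    diag3 = fail3 & (u[:, 7] < params.p_diag3)
    cont4 = fail3 & ~diag3
    attend4 = cont4 & (u[:, 8] >= l4)
    fail4 = attend4 & (u[:, 9] < f4)
    detected = diag2 | diag3 | fail4

    cost = np.zeros(n)
    cost[screened] += c1
    if params.arm == "tracking" and params.c_track:
        if params.attachment == "fail1":
            cost[fail1] += params.c_track
        elif params.attachment == "per_screened":
            cost[screened] += params.c_track
        elif params.attachment == "each_followup":
            for m in (attend2, attend3, attend4):
                cost[m] += params.c_track
    cost[attend2] += c2
    cost[attend3] += c3
    cost[diag2 | diag3 | attend4] += cpa  # the diagnostic visit

    frame = {"id": np.arange(n), "arm": params.arm}
    for name, mask in zip(FLAG_COLUMNS,
                          (screened, fail1, attend2, fail2, diag2,
                           attend3, fail3, diag3, attend4, fail4)):
        frame[name] = mask
    frame["accrued_cost"] = cost
    frame["detected"] = detected
    return pd.DataFrame(frame)


_ESTIMANDS = (
    # name suffixed by arm?, numerator, denominator, complement?
    ("p_Ltfu1", True, "screened", None, True),
    ("p_Ltfu2", True, "attend2", "fail1", True),
    ("p_Ltfu3", True, "attend3", "cont3", True),
    ("p_Ltfu4", True, "attend4", "cont4", True),
    ("p_fail_1st_test", False, "fail1", "screened", False),
    ("p_fail_2nd_test", False, "fail2", "attend2", False),
    ("p_fail_3rd_test", False, "fail3", "attend3", False),
    ("p_fail_4th_test", False, "fail4", "attend4", False),
    ("p_diagnosis_after_2nd_test", False, "diag2", "fail2", False),
    ("p_diagnosis_after_3rd_test", False, "diag3", "fail3", False),
)


def estimate_params(records: pd.DataFrame,
                    ci_method: str = "wilson") -> pd.DataFrame:
    """Re-estimate every event probability from simulated records.

    Each probability is the conditional relative frequency appropriate to
    its position in the cascade (e.g. failing the second test is estimated
    among attenders of the second test), with a 95% binomial CI (Wilson by
    default, ``ci_method="normal"`` for Wald).  Loss-to-follow-up
    probabilities are arm-specific and estimated per arm present in the
    records; stages never reached yield NaN estimates, not zeros.
    """
    if records.empty:
        raise ValueError("no records to estimate from")
    df = records.copy()
    df["everyone"] = True
    df["cont3"] = df["fail2"] & ~df["diag2"]
    df["cont4"] = df["fail3"] & ~df["diag3"]
    arms = sorted(df["arm"].unique())
    rows = []

    def add(name, sub, num, den, complement):
        denom = sub["everyone"] if den is None else sub[den]
        n_den = int(denom.sum())
        if n_den == 0:
            rows.append({"name": name, "estimate": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "numerator": 0, "denominator": 0})
            return
        k = int((sub[num] & denom).sum())
        if complement:
            k = n_den - k
        lo, hi = proportion_confint(k, n_den, alpha=0.05, method=ci_method)
        rows.append({"name": name, "estimate": k / n_den,
                     "ci_low": float(np.clip(lo, 0, 1)),
                     "ci_high": float(np.clip(hi, 0, 1)),
                     "numerator": k, "denominator": n_den})

    for name, arm_specific, num, den, complement in _ESTIMANDS:
        if arm_specific:
            for arm in arms:
                suffix = "_t" if arm == "tracking" else "_nt"
                add(name + suffix, df[df["arm"] == arm], num, den, complement)
        else:
            add(name, df, num, den, complement)
    return pd.DataFrame(rows)


_EVENT_LABELS = (
    ("screened", "screened"), ("fail1", "bilateral_fail_test_1"),
    ("attend2", "attended_test_2"), ("fail2", "bilateral_fail_test_2"),
    ("diag2", "early_diagnosis_after_test_2"),
    ("attend3", "attended_test_3"), ("fail3", "bilateral_fail_test_3"),
    ("diag3", "early_diagnosis_after_test_3"),
    ("attend4", "attended_test_4"), ("fail4", "detected_at_test_4"),
)


def iter_records(records: pd.DataFrame) -> Iterator[NewbornRecord]:
    """Yield per-child records with readable event sequences."""
    for row in records.itertuples(index=False):
        events = tuple(label for col, label in _EVENT_LABELS
                       if getattr(row, col))
        if not row.screened:
            events = ("not_screened",)
        yield NewbornRecord(int(row.id), row.arm, events,
                            float(row.accrued_cost), bool(row.detected))


def validate_records(records: pd.DataFrame) -> bool:
    """Check structural consistency of every record with the tree topology.

    No stage outcome may occur without its parent event, early diagnosis
    terminates the cascade, and detection is exactly diag2|diag3|fail4.
    Raises AssertionError on the first violation.
    """
    df = records
    implications = [
        ("fail1", "screened"), ("attend2", "fail1"), ("fail2", "attend2"),
        ("diag2", "fail2"), ("attend3", "fail2"), ("fail3", "attend3"),
        ("diag3", "fail3"), ("attend4", "fail3"), ("fail4", "attend4"),
    ]
    for a, b in implications:
        assert (~df[a] | df[b]).all(), f"{a} without {b}"
    assert not (df["diag2"] & df["attend3"]).any(), "test 3 after early diagnosis"
    assert not (df["diag3"] & df["attend4"]).any(), "test 4 after early diagnosis"
    expected = df["diag2"] | df["diag3"] | df["fail4"]
    assert (df["detected"] == expected).all(), "detected flag inconsistent"
    return True


def empirical_summary(records: pd.DataFrame) -> dict[str, float]:
    """Mean accrued cost and detected fraction, with Monte-Carlo SEs."""
    n = len(records)
    cost = records["accrued_cost"].to_numpy()
    det = records["detected"].to_numpy().astype(float)
    return {
        "n": n,
        "mean_cost": float(cost.mean()),
        "se_cost": float(cost.std(ddof=1) / np.sqrt(n)),
        "detected_fraction": float(det.mean()),
        "se_detected": float(det.std(ddof=1) / np.sqrt(n)),
    }
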