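"""Cost-effectiveness comparison of the two arms.

Incremental and average cost-effectiveness ratios, dominance classification,
net monetary benefit, and the cost-effectiveness acceptability curve (CEAC)
over a willingness-to-pay grid.  The effect unit throughout is one detected
case of bilateral hearing impairment; costs are EUR per cohort newborn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import round_cents

__all__ = ["CEComparison", "WtpGrid", "icer", "acer", "acer_reported",
           "nmb", "ceac"]


@dataclass(frozen=True)
class CEComparison:
    """Incremental comparison of intervention vs comparator."""

    delta_cost: float
    delta_effect: float
    icer: float | None  # EUR per additional detected case; None if undefined
    dominance: str  # none | intervention_dominant | intervention_dominated
    acer_intervention: float | None = None
    acer_comparator: float | None = None


@dataclass(frozen=True)
class WtpGrid:
    """Willingness-to-pay thresholds, EUR per additional detected case."""

    thresholds: tuple[float, ...] = tuple(float(x) for x in range(0, 5001, 100))

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) == 0 or any(x < 0 for x in t):
            raise ValueError("thresholds must be nonnegative and nonempty")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")


def acer(cost: float, effect: float) -> float | None:
    """Average cost-effectiveness ratio, EUR per detected case.

    Undefined (None) for nonpositive effects.
    """
    if effect <= 0:
        return None
    return cost / effect


def acer_reported(cost: float, effect: float) -> float | None:
    """ACER at the published display precision.

    Costs enter rounded to cents and effects to five decimals — the
    precision at which the source tabulates them — and the ratio is rounded
    to whole euros, so published per-case costs reproduce exactly.
    """
    effect_r = round(effect, 5)
    if effect_r <= 0:
        return None
    return float(round(round_cents(cost) / effect_r))


def icer(cost_int: float, effect_int: float,
         cost_comp: float, effect_comp: float) -> CEComparison:
    """Incremental cost-effectiveness ratio of intervention vs comparator.

    Returns a dominance flag instead of a ratio when one strategy is both
    cheaper and more effective, and an undefined marker when the effect
    difference is exactly zero.
    """
    for x in (cost_int, effect_int, cost_comp, effect_comp):
        if not math.isfinite(x):
            raise ValueError("ICER inputs must be finite")
    dc = cost_int - cost_comp
    de = effect_int - effect_comp
    dominance = "none"
    ratio: float | None
    if dc < 0 and de > 0:
        dominance = "intervention_dominant"
        ratio = dc / de
    elif dc > 0 and de < 0:
        dominance = "intervention_dominated"
        ratio = dc / de
    elif de == 0:
        ratio = None
    else:
        ratio = dc / de
    return CEComparison(dc, de, ratio, dominance,
                        acer(cost_int, effect_int), acer(cost_comp, effect_comp))


def nmb(wtp: float, cost: float, effect: float) -> float:
    """Net monetary benefit at willingness to pay ``wtp``: wtp*E - C."""
    if wtp < 0:
        raise ValueError("willingness to pay must be >= 0")
    return wtp * effect - cost


def ceac(samples: Sequence[tuple[float, float]] | np.ndarray | pd.DataFrame,
         grid: WtpGrid | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from PSA draws.

    ``samples`` holds one (delta_cost, delta_effect) pair per draw (or a
    DataFrame with ``delta_cost``/``delta_effect`` columns).  For each
    threshold the curve gives the fraction of draws with strictly positive
    incremental net monetary benefit; exact ties count as not cost-effective.
    """
    if grid is None:
        grid = WtpGrid()
    if isinstance(samples, pd.DataFrame):
        dc = samples["delta_cost"].to_numpy()
        de = samples["delta_effect"].to_numpy()
    else:
        arr = np.asarray(samples, dtype=float)
        if arr.size == 0:
            raise ValueError("CEAC requires at least one PSA sample")
        dc, de = arr[:, 0], arr[:, 1]
    if dc.size == 0:
        raise ValueError("CEAC requires at least one PSA sample")
    lam = np.asarray(grid.thresholds)
    prob = (lam[:, None] * de[None, :] - dc[None, :] > 0).mean(axis=1)
    return pd.DataFrame({"wtp": lam, "probability_cost_effective": prob})
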