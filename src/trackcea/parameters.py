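"""Model inputs: event probabilities, tariff-based test costs, tracking ledger.

Every input of the model is a published point value: fourteen event
probabilities with 95% confidence intervals (loss to follow-up before each
of the four hearing tests, arm-specific; bilateral failure at each test;
early referral to diagnosis after the second and third tests), eight tariff
fee items priced as points x point value (German DKG-NT hospital tariff and
EBM doctor's fee scale), modality-mix weights that combine fee items into a
per-stage test cost, and the itemised annual budget of the tracking centre.

This module loads those tables from the packaged CSVs, composes the four
per-stage test costs, derives the per-newborn tracking cost, and fits the
uncertainty distributions used by the probabilistic sensitivity analysis
(beta for probabilities via moment matching on the CI width, gamma for
costs via a coefficient of variation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "ProbabilityParam",
    "FeeItem",
    "ModalityMix",
    "TrackingLedger",
    "UncertainParam",
    "ModelInputs",
    "fee_item_cost",
    "compose_test_cost",
    "tracking_cost_per_newborn",
    "beta_from_mean_ci",
    "gamma_from_mean_cv",
    "load_probability_table",
    "load_fee_items",
    "load_modality_mixes",
    "load_tracking_ledger",
    "default_inputs",
    "round_cents",
]

#: Half-width of a symmetric 95% normal interval, in standard errors.
_Z95_WIDTH = 3.92

#: Cohort denominator that reproduces the published EUR 4.55 per-newborn
#: tracking cost from the EUR 78,025 ledger total; the source never prints it.
DEFAULT_N_SCREENED = 17_148

STAGE_COST_NAMES = ("c_1st_test_2stages", "c_2nd_test_1stage_ENT",
                    "c_3rd_test_1stage_ENT", "c_test_PA")

PROBABILITY_NAMES = (
    "p_Ltfu1_t", "p_Ltfu1_nt", "p_Ltfu2_t", "p_Ltfu2_nt",
    "p_Ltfu3_t", "p_Ltfu3_nt", "p_Ltfu4_t", "p_Ltfu4_nt",
    "p_fail_1st_test", "p_fail_2nd_test", "p_fail_3rd_test",
    "p_fail_4th_test", "p_diagnosis_after_2nd_test",
    "p_diagnosis_after_3rd_test",
)


def round_cents(x: float) -> float:
    """Round a EUR amount to cents, half away from zero (tariff practice)."""
    return math.floor(x * 100 + 0.5) / 100 if x >= 0 else -round_cents(-x)


@dataclass(frozen=True)
class ProbabilityParam:
    """A model event probability with its 95% confidence interval."""

    name: str
    mean: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.mean <= self.ci_high <= 1.0:
            raise ValueError(
                f"{self.name}: require 0 <= ci_low <= mean <= ci_high <= 1, "
                f"got ({self.ci_low}, {self.mean}, {self.ci_high})"
            )


@dataclass(frozen=True)
class FeeItem:
    """A tariff cost item priced as points x point value.

    ``point_value`` is in EUR per point (the catalogues print cents).
    """

    name: str
    tariff_code: str
    points: int
    point_value: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.points < 0:
            raise ValueError(f"{self.name}: points must be >= 0")
        if self.point_value <= 0:
            raise ValueError(f"{self.name}: point value must be > 0")


def fee_item_cost(item: FeeItem) -> float:
    """Unrounded cost of a fee item, points x point value, in EUR.

    Display rounding to cents is a separate step (:func:`round_cents`);
    composed stage costs use the cent-rounded value because that is the
    amount the tariff actually reimburses.
    """
    return item.points * item.point_value


@dataclass(frozen=True)
class ModalityMix:
    """Shares of newborns receiving OAE, AABR or both at one test stage.

    ``p_stage2_aabr`` is nonzero only for the first test, which is a
    two-stage screen: every newborn bilaterally failing the first-stage
    OAE/AABR screen (7.66%) receives a confirmatory AABR in hospital.
    """

    w_oae: float
    w_aabr: float
    w_both: float
    p_stage2_aabr: float = 0.0

    def __post_init__(self) -> None:
        total = self.w_oae + self.w_aabr + self.w_both
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"modality weights must sum to 1, got {total}")
        if not 0.0 <= self.p_stage2_aabr <= 1.0:
            raise ValueError("p_stage2_aabr must be a probability")


def compose_test_cost(stage: int, mix: ModalityMix,
                      items: Mapping[str, float]) -> float:
    """Modality-weighted cost of one test stage, in EUR (unrounded).

    ``items`` maps fee-item names to their EUR costs (cent-rounded, as
    reimbursed).  Stage 1 is the in-hospital two-stage screen; stages 2-3
    are office-based ENT tests with a lump sum, where newborns tested with
    both modalities are billed the AABR item; stage 4 is the pediatric
    audiologist's diagnostic visit (lump sum + middle-ear impedance + AABR).
    """
    if stage == 1:
        first = mix.w_oae * items["c_OAE_inpatient"] \
            + (mix.w_aabr + mix.w_both) * items["c_AABR_inpatient"]
        return first + mix.p_stage2_aabr * items["c_AABR_inpatient"]
    if stage in (2, 3):
        return ((mix.w_both + mix.w_aabr) * items["c_AABR_outpatient_ENT"]
                + mix.w_oae * items["c_OAE_outpatient_ENT"]
                + items["c_lumpsum_ENT"])
    if stage == 4:
        return (items["c_lumpsum_PA"] + items["c_MEM_reflex_outpatient_PA"]
                + items["c_AABR_outpatient_PA"])
    raise ValueError(f"stage must be 1..4, got {stage}")


@dataclass(frozen=True)
class TrackingLedger:
    """Line items of the tracking centre's budget for one screening period."""

    items: tuple[tuple[str, str, float], ...]  # (section, label, amount EUR)
    n_screened_per_period: int = DEFAULT_N_SCREENED

    def __post_init__(self) -> None:
        for _, label, amount in self.items:
            if amount < 0:
                raise ValueError(f"negative ledger amount for {label!r}")

    def section_total(self, section: str) -> float:
        return sum(a for s, _, a in self.items if s == section)

    @property
    def total(self) -> float:
        return sum(a for _, _, a in self.items)


def tracking_cost_per_newborn(ledger: TrackingLedger) -> float:
    """Total tracking budget divided by the number of newborns screened."""
    if not ledger.items:
        return 0.0
    if ledger.n_screened_per_period <= 0:
        raise ValueError("n_screened_per_period must be > 0")
    return ledger.total / ledger.n_screened_per_period


@dataclass(frozen=True)
class UncertainParam:
    """A parameter with its second-order uncertainty distribution.

    ``family`` is ``beta`` for probabilities, ``gamma`` for costs, or
    ``fixed`` for a point mass; ``a``/``b`` are (alpha, beta) for the beta
    family and (shape, scale) for the gamma family.
    """

    base: float
    family: Literal["beta", "gamma", "fixed"]
    a: float = 0.0
    b: float = 0.0

    def distribution(self):
        """Frozen scipy distribution (point masses are not supported)."""
        if self.family == "beta":
            return stats.beta(self.a, self.b)
        if self.family == "gamma":
            return stats.gamma(self.a, scale=self.b)
        raise ValueError("a fixed parameter has no sampling distribution")

    def sample(self, rng, size=None):
        if self.family == "beta":
            return rng.beta(self.a, self.b, size)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size)
        import numpy as np

        return np.broadcast_to(self.base, () if size is None else (size,)).copy()


def beta_from_mean_ci(p: ProbabilityParam) -> UncertainParam:
    """Beta distribution matching a probability's mean and 95% CI width.

    The CI is treated as symmetric: SE = (ci_high - ci_low)/3.92.  Method of
    moments then gives nu = mean(1-mean)/SE^2 - 1 and shapes
    (mean*nu, (1-mean)*nu).  Infeasible variances (SE^2 >= mean(1-mean),
    i.e. nu <= 0) are rejected.
    """
    if not 0.0 < p.mean < 1.0:
        raise ValueError(f"{p.name}: mean must be strictly inside (0, 1)")
    if p.ci_high <= p.ci_low:
        raise ValueError(f"{p.name}: ci_high must exceed ci_low")
    se = (p.ci_high - p.ci_low) / _Z95_WIDTH
    var = se * se
    if var >= p.mean * (1.0 - p.mean):
        raise ValueError(
            f"{p.name}: CI width implies variance {var:.4g} >= "
            f"mean(1-mean) = {p.mean * (1 - p.mean):.4g}; beta moments infeasible"
        )
    nu = p.mean * (1.0 - p.mean) / var - 1.0
    return UncertainParam(p.mean, "beta", p.mean * nu, (1.0 - p.mean) * nu)


def gamma_from_mean_cv(base: float, cv: float) -> UncertainParam:
    """Gamma distribution with mean ``base`` and coefficient of variation ``cv``.

    shape = 1/cv^2, scale = base*cv^2.  ``cv = 0`` degenerates to a point
    mass (family ``fixed``).
    """
    if base <= 0:
        raise ValueError("base cost must be > 0")
    if cv < 0:
        raise ValueError("coefficient of variation must be >= 0")
    if cv == 0:
        return UncertainParam(base, "fixed")
    return UncertainParam(base, "gamma", 1.0 / cv**2, base * cv**2)


# ---------------------------------------------------------------------------
# packaged input tables


def _data(name: str):
    return resources.files("trackcea.data").joinpath(name)


def load_probability_table(path=None) -> dict[str, ProbabilityParam]:
    """Event probabilities (mean, 95% CI) keyed by parameter name."""
    df = pd.read_csv(path if path is not None else _data("table1_probabilities.csv"))
    return {
        r.name: ProbabilityParam(r.name, r.mean, r.ci_low, r.ci_high)
        for r in df.itertuples(index=False)
    }


def load_fee_items(path=None) -> dict[str, FeeItem]:
    """Tariff fee items; point values are converted from cents to EUR."""
    df = pd.read_csv(
        path if path is not None else _data("table2_fee_items.csv"),
        dtype={"tariff_code": str},
    )
    return {
        r.name: FeeItem(r.name, r.tariff_code, int(r.points),
                        r.point_value_cents / 100.0, r.source)
        for r in df.itertuples(index=False)
    }


def load_modality_mixes(path=None) -> dict[str, tuple[int, ModalityMix]]:
    """Per-stage modality mixes keyed by composite-cost name."""
    df = pd.read_csv(path if path is not None else _data("table3_modality_mix.csv"))
    return {
        r.name: (int(r.stage),
                 ModalityMix(r.w_oae, r.w_aabr, r.w_both, r.p_stage2_aabr))
        for r in df.itertuples(index=False)
    }


def load_tracking_ledger(path=None,
                         n_screened: int = DEFAULT_N_SCREENED) -> TrackingLedger:
    df = pd.read_csv(path if path is not None else _data("table4_tracking_ledger.csv"))
    items = tuple(
        (r.section, r.label, float(r.amount_eur)) for r in df.itertuples(index=False)
    )
    return TrackingLedger(items, n_screened)


@dataclass(frozen=True)
class ModelInputs:
    """The complete parameter set of the model (both arms).

    ``stage_costs`` are the composed per-stage test costs in tree order
    (test 1, test 2, test 3, diagnostic visit); ``c_tracking`` is the
    per-newborn tracking surcharge.
    """

    probabilities: dict[str, ProbabilityParam]
    stage_costs: dict[str, float]
    c_tracking: float
    cost_cv: float = 0.2
    overrides: dict[str, float] = field(default_factory=dict)

    def value(self, name: str) -> float:
        """Point value of any named parameter, override-aware."""
        if name in self.overrides:
            return self.overrides[name]
        if name in self.probabilities:
            return self.probabilities[name].mean
        if name in self.stage_costs:
            return self.stage_costs[name]
        if name == "c_tracking":
            return self.c_tracking
        raise KeyError(f"unknown model parameter {name!r}")

    def with_overrides(self, overrides: Mapping[str, float]) -> "ModelInputs":
        unknown = [k for k in overrides if k not in self.parameter_names()]
        if unknown:
            raise KeyError(f"unknown model parameter(s) {unknown}")
        for k, v in overrides.items():
            if k in self.probabilities and not 0.0 <= v <= 1.0:
                raise ValueError(f"{k}: probability override {v} outside [0, 1]")
            if k not in self.probabilities and v < 0:
                raise ValueError(f"{k}: cost override must be >= 0")
        return replace(self, overrides={**self.overrides, **overrides})

    def parameter_names(self) -> tuple[str, ...]:
        return tuple(self.probabilities) + tuple(self.stage_costs) + ("c_tracking",)

    def uncertainty(self) -> dict[str, UncertainParam]:
        """PSA distributions: beta for probabilities, gamma for costs.

        Overridden parameters keep their distribution family but are
        re-centred on the override (probabilities reuse the CI width).
        """
        dists: dict[str, UncertainParam] = {}
        for name, p in self.probabilities.items():
            if name in self.overrides:
                half = (p.ci_high - p.ci_low) / 2.0
                v = self.overrides[name]
                p = ProbabilityParam(name, v, max(v - half, 0.0), min(v + half, 1.0))
            dists[name] = beta_from_mean_ci(p)
        for name in (*self.stage_costs, "c_tracking"):
            dists[name] = gamma_from_mean_cv(self.value(name), self.cost_cv)
        return dists


def default_inputs(cost_cv: float = 0.2,
                   probability_table=None, fee_table=None,
                   mix_table=None, ledger_table=None,
                   n_screened: int | None = None,
                   c_tracking: float | None = None) -> ModelInputs:
    """Assemble the published base-case inputs.

    Stage costs are composed from cent-rounded fee items; ``c_tracking``
    defaults to the published EUR 4.55 (the ledger total over the default
    screening denominator, at cent precision).
    """
    probs = load_probability_table(probability_table)
    fees = load_fee_items(fee_table)
    item_costs = {k: round_cents(fee_item_cost(v)) for k, v in fees.items()}
    mixes = load_modality_mixes(mix_table)
    stage_costs = {
        name: compose_test_cost(stage, mix, item_costs)
        for name, (stage, mix) in mixes.items()
    }
    if c_tracking is None:
        ledger = load_tracking_ledger(
            ledger_table, n_screened if n_screened else DEFAULT_N_SCREENED
        )
        c_tracking = round_cents(tracking_cost_per_newborn(ledger))
    return ModelInputs(probs, stage_costs, c_tracking, cost_cv)
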