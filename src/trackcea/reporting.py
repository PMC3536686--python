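"""Result tables at both full and display precision, plus the run log.

Display precision follows the source tables: costs to cents, effects
(detected cases per newborn) to five decimals, cost-effectiveness ratios to
whole euros.  Every emitted table carries the unrounded value next to its
display rounding so results remain traceable.
"""

from __future__ import annotations

import sys
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cea import CEComparison, acer_reported
from .parameters import round_cents
from .tree import ArmExpectation, scale_to_cohort

__all__ = ["basecase_table", "write_table", "write_run_log",
           "round_effect", "round_euro"]


def round_effect(x: float) -> float:
    return round(x, 5)


def round_euro(x: float | None) -> float | None:
    return None if x is None else float(round(x))


def basecase_table(tracking: ArmExpectation, no_tracking: ArmExpectation,
                   comparison: CEComparison,
                   cohort_size: int = 100_000) -> pd.DataFrame:
    """Per-arm base-case report: costs, effects, ACER, ICER, cohort yield.

    Each quantity appears unrounded and at display precision; the displayed
    ACER is recomputed from the displayed cost and effect, mirroring how
    the published per-case costs were derived.
    """
    rows = []
    for exp, acer_raw in ((tracking, comparison.acer_intervention),
                          (no_tracking, comparison.acer_comparator)):
        cases, cases_int = scale_to_cohort(exp, cohort_size)
        rows.append({
            "strategy": exp.arm,
            "cost": exp.expected_cost,
            "cost_display": round_cents(exp.expected_cost),
            "effect": exp.expected_effect,
            "effect_display": round_effect(exp.expected_effect),
            "acer": acer_raw,
            "acer_display": acer_reported(exp.expected_cost,
                                          exp.expected_effect),
            f"cases_per_{cohort_size}": cases,
            f"cases_per_{cohort_size}_display": cases_int,
            "icer": None,
            "icer_display": None,
        })
    rows[0]["icer"] = comparison.icer
    rows[0]["icer_display"] = round_euro(comparison.icer)
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, out_dir: str | Path, name: str,
                float_format: str = "%.10g") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / name
    df.to_csv(path, index=False, float_format=float_format)
    return path


def write_run_log(out_dir: str | Path, config_echo: dict,
                  notes: dict | None = None, log_stream=None) -> Path:
    """Echo the configuration, seed and package version next to the outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "trackcea_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "config": config_echo,
    }
    if notes:
        payload["notes"] = notes
    text = yaml.safe_dump(payload, sort_keys=False)
    path = out / "run_log.yaml"
    path.write_text(text)
    print(text, file=log_stream if log_stream is not None else sys.stderr)
    return path
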