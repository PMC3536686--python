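"""Run configuration: parameter-file paths, overrides and analysis settings.

A run is fully described by a small YAML file; every setting has a default
reproducing the published base case, so an empty config is valid.  Example::

    parameter_files:
      probabilities: my_table1.csv      # optional; packaged tables otherwise
    overrides:
      p_Ltfu2_nt: 0.40
      c_tracking: 5.00
    attachment: fail1                   # fail1 | per_screened | each_followup
    psa: {n_iter: 10000, seed: 42, cost_cv: 0.2}
    wtp: {min: 0, max: 5000, step: 100}
    cohort_size: 100000
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cea import WtpGrid
from .parameters import ModelInputs, default_inputs

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    probabilities_file: str | None = None
    fee_items_file: str | None = None
    modality_mix_file: str | None = None
    tracking_ledger_file: str | None = None
    n_screened: int | None = None
    overrides: dict[str, float] = field(default_factory=dict)
    attachment: str = "fail1"
    n_iter: int = 10_000
    seed: int = 0
    cost_cv: float = 0.2
    wtp_min: float = 0.0
    wtp_max: float = 5000.0
    wtp_step: float = 100.0
    cohort_size: int = 100_000
    out_dir: str = "results"

    def model_inputs(self) -> ModelInputs:
        for f in (self.probabilities_file, self.fee_items_file,
                  self.modality_mix_file, self.tracking_ledger_file):
            if f is not None and not Path(f).exists():
                raise FileNotFoundError(f"parameter file not found: {f}")
        inputs = default_inputs(
            cost_cv=self.cost_cv,
            probability_table=self.probabilities_file,
            fee_table=self.fee_items_file,
            mix_table=self.modality_mix_file,
            ledger_table=self.tracking_ledger_file,
            n_screened=self.n_screened,
        )
        return inputs.with_overrides(self.overrides) if self.overrides else inputs

    def wtp_grid(self) -> WtpGrid:
        n = int(round((self.wtp_max - self.wtp_min) / self.wtp_step))
        return WtpGrid(tuple(self.wtp_min + i * self.wtp_step
                             for i in range(n + 1)))

    def echo(self) -> dict:
        """Everything needed to reproduce the run, for the run log."""
        return {k: v for k, v in self.__dict__.items()}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` yields the defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    files = raw.get("parameter_files", {})
    cfg.probabilities_file = files.get("probabilities")
    cfg.fee_items_file = files.get("fee_items")
    cfg.modality_mix_file = files.get("modality_mix")
    cfg.tracking_ledger_file = files.get("tracking_ledger")
    cfg.n_screened = raw.get("n_screened")
    cfg.overrides = {k: float(v) for k, v in (raw.get("overrides") or {}).items()}
    cfg.attachment = raw.get("attachment", cfg.attachment)
    psa = raw.get("psa", {})
    cfg.n_iter = int(psa.get("n_iter", cfg.n_iter))
    cfg.seed = int(psa.get("seed", cfg.seed))
    cfg.cost_cv = float(psa.get("cost_cv", cfg.cost_cv))
    wtp = raw.get("wtp", {})
    cfg.wtp_min = float(wtp.get("min", cfg.wtp_min))
    cfg.wtp_max = float(wtp.get("max", cfg.wtp_max))
    cfg.wtp_step = float(wtp.get("step", cfg.wtp_step))
    cfg.cohort_size = int(raw.get("cohort_size", cfg.cohort_size))
    cfg.out_dir = raw.get("out_dir", cfg.out_dir)
    return cfg
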