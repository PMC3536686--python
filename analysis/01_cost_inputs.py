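#!/usr/bin/env python
"""Assemble the model's cost inputs from the tariff tables.

Prices each fee item (points x point value), composes the four per-stage
test costs from the modality mixes, and totals the tracking-centre ledger
into the per-newborn tracking fee.  Writes the assembled inputs under
results/ and prints the headline values: stage costs EUR 42.22 / 38.99 /
43.39 / 91.83 and a tracking fee of EUR 4.55 per newborn screened.
"""

import pandas as pd

from trackcea.parameters import (fee_item_cost, load_fee_items,
                                 load_tracking_ledger, round_cents,
                                 tracking_cost_per_newborn, default_inputs)
from trackcea.reporting import write_table

OUT = "results"


def main() -> None:
    items = load_fee_items()
    fee_table = pd.DataFrame(
        [{"name": k, "tariff_code": v.tariff_code, "points": v.points,
          "point_value_eur": v.point_value,
          "cost_unrounded": fee_item_cost(v),
          "cost_eur": round_cents(fee_item_cost(v))} for k, v in items.items()]
    )
    write_table(fee_table, OUT, "fee_items.csv")

    inputs = default_inputs()
    stage_table = pd.DataFrame(
        [{"name": k, "cost_unrounded": v, "cost_eur": round_cents(v)}
         for k, v in inputs.stage_costs.items()]
    )
    write_table(stage_table, OUT, "stage_costs.csv")

    ledger = load_tracking_ledger()
    per_newborn = tracking_cost_per_newborn(ledger)
    print("Per-stage test costs (EUR):")
    print(stage_table.to_string(index=False))
    print(f"\nTracking ledger: personnel {ledger.section_total('personnel'):,.0f}"
          f" + non-personnel {ledger.section_total('non_personnel'):,.0f}"
          f" = {ledger.total:,.0f} EUR per period")
    print(f"Tracking cost per newborn screened "
          f"({ledger.n_screened_per_period:,} newborns): "
          f"EUR {round_cents(per_newborn):.2f}")


if __name__ == "__main__":
    main()
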