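#!/usr/bin/env python
"""Reconstruct the analysis dataset: basket inputs plus back-derived users.

The published basket prints every welfare input except the number of users
per drug (confidential). The welfare formula is linear in that count, so the
printed per-drug welfare at the 100,000/QALY base-case threshold pins it
exactly. This script inverts all 31 counts, writes the populated basket, and
reports the per-drug welfare reproduced with those counts.

Outputs: results/basket_populated.csv, results/welfare_base_case.csv
"""

from pathlib import Path

import drugwelfare as dw

THRESHOLD = 100_000.0
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    basket, welfare_column = dw.table2_fixture()
    print(f"loaded bundled basket: {len(basket)} drugs, "
          f"{sum(r.ratio_target.amount < 0 for r in basket)} dominant (negative ICER)")

    populated = dw.populate_users(basket, welfare_column, THRESHOLD)
    dw.write_basket(populated, OUT / "basket_populated.csv")

    agg = dw.total_welfare(THRESHOLD, populated)
    dw.write_results(agg.per_drug, OUT / "welfare_base_case.csv", agg)

    worst = min(agg.per_drug, key=lambda r: r.welfare)
    print(f"all user counts inverted from the printed welfare column at "
          f"threshold {THRESHOLD:,.0f}")
    print(f"re-evaluated total: CHF {agg.total:,.2f} "
          f"(printed column sums to {sum(welfare_column.values()):,.0f})")
    print(f"only drug with negative welfare: {worst.name} "
          f"(CHF {worst.welfare:,.0f}; its ICER exceeds the threshold)")
    print(f"wrote {OUT/'basket_populated.csv'} and {OUT/'welfare_base_case.csv'}")


if __name__ == "__main__":
    main()
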