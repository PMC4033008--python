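#!/usr/bin/env python
"""Aggregate welfare at the base-case and alternative QALY thresholds.

The basket total is affine in the threshold λ: W(λ) = λ·Σ(Δe/T·n) − Σ(c·Δe/T·n),
so totals at 50,000 and 150,000 follow in closed form from one basket pass.
Also expresses the base-case total as a share of national drug expenditure.

Output: results/welfare_totals.csv
"""

from pathlib import Path

import pandas as pd

import drugwelfare as dw

THRESHOLD = 100_000.0
DRUG_EXPENDITURE_CHF = 6.05e9   # national pharmaceutical spending, 2010
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    basket, welfare_column = dw.table2_fixture()
    populated = dw.populate_users(basket, welfare_column, THRESHOLD)

    totals = dw.welfare_at_thresholds(populated, [50_000.0, THRESHOLD, 150_000.0])
    agg = dw.total_welfare(THRESHOLD, populated)

    rows = [{"threshold": lam, "total_welfare": f"{w:.2f}",
             "total_welfare_millions": f"{w / 1e6:.2f}"}
            for lam, w in sorted(totals.items())]
    pd.DataFrame(rows).to_csv(OUT / "welfare_totals.csv", index=False)

    share = 100.0 * totals[THRESHOLD] / DRUG_EXPENDITURE_CHF
    print(f"annual QALY throughput of the basket (slope): {agg.slope:,.1f} QALY/yr")
    for lam, w in sorted(totals.items()):
        print(f"  W({lam:>9,.0f}) = CHF {w / 1e6:,.2f} M")
    print(f"base-case total is {share:.1f}% (~{round(share)}%) of the "
          f"CHF {DRUG_EXPENDITURE_CHF / 1e9:.2f} B national drug expenditure")
    caveats = sum(r.outcome_unit_caveat for r in agg.per_drug)
    print(f"{caveats} drugs valued via LY/MLY effects carry the outcome-unit "
          f"caveat (their QALY-based welfare could be lower)")
    print(f"wrote {OUT/'welfare_totals.csv'}")


if __name__ == "__main__":
    main()
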