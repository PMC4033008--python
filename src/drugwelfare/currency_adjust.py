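"""Harmonizing cost-effectiveness ratios across countries and price years.

A ratio published for country c in price year y is carried to the target
country-year in two fixed steps:

1. **deflate** — within the source currency, rescale to target-year price
   levels using the ratio of GDP-deflator indices,
   ``amount × D(c, Y_target) / D(c, y)``;
2. **ppp_convert** — cross the currency border at purchasing-power parity,
   ``amount × PPP(c → target, Y_target)``.

The order matters whenever deflator ratios differ between the two currency
areas; this module is pinned to deflate-then-convert, i.e. the cross-border
step happens at target-year price levels. Both steps are linear and
sign-preserving, so dominant (negative) ratios stay negative.
"""

from __future__ import annotations

from dataclasses import replace

from .errors import WelfareError
from .types import AdjustmentTables, DrugRecord, MoneyPerOutcome


def deflate(ratio: MoneyPerOutcome, tables: AdjustmentTables) -> MoneyPerOutcome:
    """Restate a ratio at target-year price levels within its own currency.

    Identity when the ratio is already at the target year (the index ratio
    is exactly 1). Raises :class:`~drugwelfare.errors.CompletenessError`
    naming the missing (currency, year) cell otherwise undefined.
    """
    source_index = tables.deflator_at(ratio.currency, ratio.price_year)
    factor = tables.deflator_at(ratio.currency, tables.target_year) / source_index
    return replace(ratio, amount=ratio.amount * factor, price_year=tables.target_year)


def ppp_convert(ratio: MoneyPerOutcome, tables: AdjustmentTables) -> MoneyPerOutcome:
    """Convert a target-year ratio into the target currency at PPP.

    Identity for ratios already denominated in the target currency.
    """
    if ratio.price_year != tables.target_year:
        raise WelfareError(
            f"ppp_convert expects a ratio at the target year "
            f"{tables.target_year}, got {ratio.price_year}; deflate first"
        )
    rate = tables.ppp_at(ratio.currency, tables.target_year)
    return replace(
        ratio, amount=ratio.amount * rate, currency=tables.target_currency
    )


def adjust_ratio(ratio: MoneyPerOutcome, tables: AdjustmentTables) -> MoneyPerOutcome:
    """Full harmonization: deflate in the source country, then PPP-convert."""
    return ppp_convert(deflate(ratio, tables), tables)


def adjust_basket(
    records: list[DrugRecord], tables: AdjustmentTables
) -> list[DrugRecord]:
    """Return records with ``ratio_target`` filled from ``ratio_original``."""
    out = []
    for r in records:
        out.append(
            replace(r, ratio_target=adjust_ratio(r.ratio_original, tables))
            if r.ratio_original is not None
            else replace(r)
        )
    return out


def implied_adjustment_factor(record: DrugRecord) -> float:
    """Combined deflator×PPP factor recoverable from a record's paired ratios.

    Diagnostic for baskets that carry both the original and the harmonized
    ratio: the factor is simply adjusted/original, and should be finite and
    positive for any plausibly harmonized record.
    """
    if record.ratio_original is None or record.ratio_target is None:
        raise WelfareError(f"{record.name}: both ratios required")
    if record.ratio_original.amount == 0:
        raise WelfareError(f"{record.name}: zero original amount, factor undefined")
    return record.ratio_target.amount / record.ratio_original.amount
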