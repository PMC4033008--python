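"""Synthetic baskets and adjustment tables with known ground truth.

The generator emulates the statistical structure of the published 31-drug
basket — adjusted ICERs spanning strong dominance (≈ −250,000) through
above-threshold values, incremental effects spanning four orders of
magnitude, time horizons from a few days (an acute-migraine model) to a
lifetime, and user counts from tens to hundreds of thousands — without
attempting epidemiological realism. Effects and horizons are drawn
log-uniformly so every regime is covered; ratios and user counts are
uniform. Every generated record carries its ground-truth user count
(``user_source="synthetic"``), making end-to-end parameter-recovery tests
possible at every pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basket_io import (
    TARGET_CURRENCY,
    TARGET_YEAR,
    load_bundled_basket,
    load_bundled_welfare,
)
from .errors import SpecError
from .types import AdjustmentTables, DrugRecord, MoneyPerOutcome, OutcomeUnit, UserSource

#: Currency areas of the published basket, with the price-year span seen there.
DEFAULT_CURRENCIES = ("CHF", "GBP", "AUD", "CAD", "USD", "EUR")
DEFAULT_YEARS = (2000, 2007)


@dataclass
class BasketSpec:
    """Sampling ranges for a synthetic basket.

    Defaults span the published basket's printed columns: ratios from
    erlotinib-like dominance to cinacalcet-like above-threshold values,
    effects from 1e-4 to 7 QALYs, horizons from ~1 day to 75 years.
    """

    n_drugs: int = 31
    ratio_range: tuple[float, float] = (-250_000.0, 150_000.0)
    delta_effect_range: tuple[float, float] = (1e-4, 7.0)       # log-uniform
    horizon_range: tuple[float, float] = (0.002, 75.0)          # log-uniform
    users_range: tuple[float, float] = (10.0, 500_000.0)
    currencies: tuple[str, ...] = DEFAULT_CURRENCIES
    years: tuple[int, int] = DEFAULT_YEARS
    seed: int = 0

    def __post_init__(self):
        for label, (lo, hi) in (
            ("ratio_range", self.ratio_range),
            ("delta_effect_range", self.delta_effect_range),
            ("horizon_range", self.horizon_range),
            ("users_range", self.users_range),
        ):
            if not (lo < hi):
                raise SpecError(f"{label} must be non-degenerate, got ({lo}, {hi})")
        if self.n_drugs < 1:
            raise SpecError("n_drugs must be >= 1")
        if self.delta_effect_range[0] <= 0 or self.horizon_range[0] <= 0:
            raise SpecError("effect and horizon ranges must be positive (log-uniform)")
        if self.users_range[0] < 0:
            raise SpecError("users_range must be nonnegative")
        if not self.currencies:
            raise SpecError("at least one currency required")


def generate_adjustment_tables(
    currencies: tuple[str, ...] | list[str],
    years: tuple[int, int],
    seed: int,
    target_currency: str = TARGET_CURRENCY,
    target_year: int = TARGET_YEAR,
) -> AdjustmentTables:
    """Random but well-behaved deflator/PPP tables, complete for any basket
    drawn over the same currencies and year span.

    Deflator indices rise monotonically (annual inflation drawn uniformly
    from 0–5%), so deflating an older ratio to the target year never
    shrinks it; PPP rates into the target currency are drawn from
    0.85–1.30, keeping combined adjustment factors inside the 0.8–2.2 band
    the published basket's paired columns imply.
    """
    if not currencies:
        raise SpecError("at least one currency required")
    lo, hi = years
    if not (lo <= hi <= target_year):
        raise SpecError(f"year span ({lo}, {hi}) must precede target {target_year}")
    rng = np.random.default_rng(seed)
    deflator: dict[tuple[str, int], float] = {}
    ppp: dict[tuple[str, int], float] = {}
    for currency in currencies:
        index = 100.0
        deflator[(currency, lo)] = index
        for year in range(lo + 1, target_year + 1):
            index *= 1.0 + rng.uniform(0.0, 0.05)
            deflator[(currency, year)] = index
        if currency != target_currency:
            ppp[(currency, target_year)] = rng.uniform(0.85, 1.30)
    return AdjustmentTables(deflator, ppp, target_currency, target_year)


def _combined_factor(tables: AdjustmentTables, currency: str, year: int) -> float:
    return (
        tables.deflator_at(currency, tables.target_year)
        / tables.deflator_at(currency, year)
        * tables.ppp_at(currency, tables.target_year)
    )


def generate_basket(
    spec: BasketSpec, enforce_regimes: bool | None = None
) -> list[DrugRecord]:
    """Draw a basket with ground-truth users from a :class:`BasketSpec`.

    Reproducible: the same spec (seed included) yields the identical
    basket. Original-currency ratios are constructed to be exactly
    consistent with ``generate_adjustment_tables(spec.currencies,
    spec.years, spec.seed)``, so the currency-adjustment pipeline recovers
    each record's adjusted ratio bit-for-bit.

    For baskets of at least four drugs (``enforce_regimes`` defaulting to
    true there), the draw is patched to contain at least one dominant
    (negative-ratio) drug and one drug priced above 100,000, provided the
    ratio range reaches those regimes; requesting the guarantee for fewer
    than four drugs is a spec error.
    """
    if enforce_regimes is None:
        enforce_regimes = spec.n_drugs >= 4
    if enforce_regimes and spec.n_drugs < 4:
        raise SpecError("regime guarantees need n_drugs >= 4")

    tables = generate_adjustment_tables(spec.currencies, spec.years, spec.seed)
    # separate stream from the tables generator so the two draws are independent
    rng = np.random.default_rng([1, spec.seed])

    lo_r, hi_r = spec.ratio_range
    ratios = rng.uniform(lo_r, hi_r, size=spec.n_drugs)
    if enforce_regimes:
        if lo_r < 0 and not (ratios < 0).any():
            ratios[0] = rng.uniform(lo_r, min(0.0, hi_r))
        if hi_r > 100_000.0 and not (ratios > 100_000.0).any():
            ratios[1] = rng.uniform(max(lo_r, 100_000.0), hi_r)

    deltas = np.exp(rng.uniform(*np.log(spec.delta_effect_range), size=spec.n_drugs))
    horizons = np.exp(rng.uniform(*np.log(spec.horizon_range), size=spec.n_drugs))
    users = rng.uniform(*spec.users_range, size=spec.n_drugs)
    unit_choices = (OutcomeUnit.QALY, OutcomeUnit.LY, OutcomeUnit.MLY)
    units = [
        unit_choices[j]
        for j in rng.choice(3, size=spec.n_drugs, p=[0.8, 0.15, 0.05])
    ]
    currencies = rng.choice(list(spec.currencies), size=spec.n_drugs)
    years = rng.integers(spec.years[0], spec.years[1] + 1, size=spec.n_drugs)

    records = []
    for i in range(spec.n_drugs):
        currency, year = str(currencies[i]), int(years[i])
        factor = _combined_factor(tables, currency, year)
        unit = units[i]
        records.append(DrugRecord(
            name=f"SYN-{i + 1:03d}",
            brand=f"Synthetica-{i + 1}",
            ratio_original=MoneyPerOutcome(float(ratios[i]) / factor, currency, year, unit),
            ratio_target=MoneyPerOutcome(float(ratios[i]), TARGET_CURRENCY, TARGET_YEAR, unit),
            delta_effect=float(deltas[i]),
            time_horizon_years=float(horizons[i]),
            n_users=float(users[i]),
            perspective="synthetic",
            user_source=UserSource.SYNTHETIC,
        ))
    return records


def table2_fixture() -> tuple[list[DrugRecord], dict[str, float]]:
    """The bundled 31-drug published basket and its printed welfare column.

    The welfare column is an *output* of the base-case analysis (threshold
    100,000), returned separately from the input records; it is what user
    inversion consumes. Values are kept exactly as printed, including the
    one figure the source's own running text reports 4 units higher.
    """
    return load_bundled_basket(), load_bundled_welfare()
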