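"""Domain types for the drug-basket welfare analysis.

The analysis values each drug by its annualized net monetary benefit at a
willingness-to-pay threshold λ (CHF per QALY):

    welfare = (λ − ICER) × (Δeffect / time_horizon) × n_users

where the ICER is the incremental cost-effectiveness (or cost-utility)
ratio harmonized to the target country and price year. The types below
carry every input of that formula together with its provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

from .errors import CompletenessError, MissingInputError

#: Calendar-year sanity bounds for price years accepted by default.  The
#: included cost-effectiveness studies span 2000–2007 with a 2010 target;
#: the bounds are deliberately wider and can be overridden per call.
PRICE_YEAR_BOUNDS: tuple[int, int] = (1990, 2015)


class OutcomeUnit(str, Enum):
    """Unit of the incremental health effect in an ICER denominator."""

    QALY = "QALY"  # quality-adjusted life year
    LY = "LY"      # life year gained, unweighted by quality
    MLY = "MLY"    # monosymptomatic life year (one multiple-sclerosis study)

    @classmethod
    def parse(cls, text: str) -> "OutcomeUnit":
        """Normalize the strings found in published tables ("/LYG" → LY)."""
        token = text.strip().lstrip("/").upper()
        if token in ("QALY", "ICUR"):
            return cls.QALY
        if token in ("LY", "LYG"):
            return cls.LY
        if token == "MLY":
            return cls.MLY
        raise ValueError(f"unknown outcome unit {text!r}")


class UserSource(str, Enum):
    """Provenance of a record's number-of-users input."""

    MANUFACTURER_POTENTIAL = "manufacturer_potential"
    INSURER_ACTUAL = "insurer_actual"
    PACKAGES_DERIVED = "packages_derived"
    INVERTED = "inverted"
    SYNTHETIC = "synthetic"


#: Currency codes the reader accepts without complaint.
KNOWN_CURRENCIES = frozenset({"CHF", "GBP", "AUD", "CAD", "USD", "EUR"})


@dataclass(frozen=True)
class MoneyPerOutcome:
    """A cost-effectiveness ratio tagged with currency, price year and unit.

    ``amount`` may be negative: a dominant intervention is both cheaper and
    more effective than its comparator, so its ICER is reported negative.
    """

    amount: float
    currency: str
    price_year: int
    outcome_unit: OutcomeUnit

    def __post_init__(self):
        lo, hi = PRICE_YEAR_BOUNDS
        if not (lo <= self.price_year <= hi):
            raise ValueError(
                f"price_year {self.price_year} outside [{lo}, {hi}]"
            )
        if not math.isfinite(self.amount):
            raise ValueError("amount must be finite")
        if not isinstance(self.outcome_unit, OutcomeUnit):
            object.__setattr__(
                self, "outcome_unit", OutcomeUnit.parse(str(self.outcome_unit))
            )

    def with_amount(self, amount: float) -> "MoneyPerOutcome":
        return replace(self, amount=amount)


@dataclass
class DrugRecord:
    """One basket row: a drug, its harmonized ICER and scaling inputs.

    ``delta_effect`` is the incremental outcome (ΔQALY/ΔLY/ΔMLY) gained per
    treated patient over the model's ``time_horizon_years``; dividing the
    two annualizes the effect. ``n_users`` is ``None`` until supplied or
    back-derived — never 0, which is a valid degenerate count.
    """

    name: str
    brand: str = ""
    ratio_original: MoneyPerOutcome | None = None
    ratio_target: MoneyPerOutcome | None = None
    delta_effect: float = float("nan")
    time_horizon_years: float = float("nan")
    n_users: float | None = None
    perspective: str = ""
    user_source: UserSource | None = None

    def __post_init__(self):
        if not self.name:
            raise ValueError("record must be named")
        if not (self.time_horizon_years > 0):
            raise ValueError(
                f"{self.name}: time_horizon_years must be > 0, "
                f"got {self.time_horizon_years}"
            )
        if not math.isfinite(self.delta_effect) or self.delta_effect == 0:
            raise ValueError(
                f"{self.name}: delta_effect must be finite and nonzero"
            )
        if self.n_users is not None and self.n_users < 0:
            raise ValueError(f"{self.name}: n_users must be >= 0")
        if (
            self.ratio_original is not None
            and self.ratio_target is not None
            and self.ratio_original.outcome_unit != self.ratio_target.outcome_unit
        ):
            raise ValueError(
                f"{self.name}: outcome unit mismatch between original "
                f"({self.ratio_original.outcome_unit.value}) and target "
                f"({self.ratio_target.outcome_unit.value}) ratios"
            )

    @property
    def annual_effect(self) -> float:
        """Outcome units gained per user per year."""
        return self.delta_effect / self.time_horizon_years

    def require_target_ratio(self) -> MoneyPerOutcome:
        if self.ratio_target is None:
            raise MissingInputError(
                f"{self.name}: no target-country ratio; run currency "
                "adjustment (drugwelfare.currency_adjust.adjust_ratio) first"
            )
        return self.ratio_target

    def require_users(self) -> float:
        if self.n_users is None:
            raise MissingInputError(
                f"{self.name}: n_users missing; supply it or derive it "
                "(drugwelfare.users_estimation.populate_users)"
            )
        return self.n_users


@dataclass
class AdjustmentTables:
    """GDP-deflator indices per currency area and PPP rates into the target.

    ``deflator[(currency, year)]`` is a national price index with arbitrary
    base year — only within-currency ratios matter. ``ppp[(currency, year)]``
    is target-currency units per source-currency unit at purchasing-power
    parity. Completeness against a basket is checked lazily at lookup time.
    """

    deflator: dict[tuple[str, int], float] = field(default_factory=dict)
    ppp: dict[tuple[str, int], float] = field(default_factory=dict)
    target_currency: str = "CHF"
    target_year: int = 2010

    def __post_init__(self):
        for table_name, table in (("deflator", self.deflator), ("ppp", self.ppp)):
            for (cur, year), value in table.items():
                if not (value > 0):
                    raise ValueError(
                        f"{table_name} ({cur}, {year}) = {value}: "
                        "must be strictly positive"
                    )

    def deflator_at(self, currency: str, year: int) -> float:
        try:
            return self.deflator[(currency, year)]
        except KeyError:
            raise CompletenessError("deflator", currency, year) from None

    def ppp_at(self, currency: str, year: int) -> float:
        if currency == self.target_currency:
            return 1.0
        try:
            return self.ppp[(currency, year)]
        except KeyError:
            raise CompletenessError("ppp", currency, year) from None


@dataclass
class WelfareResult:
    """Per-drug annual welfare at a stated threshold, with its inputs."""

    name: str
    threshold: float
    adjusted_ratio: float
    annual_effect: float
    n_users: float
    welfare: float
    outcome_unit_caveat: bool = False


@dataclass
class BasketWelfare:
    """Aggregate welfare of a basket at one threshold.

    ``slope`` is Σ(annual_effect × n_users) over the basket, the derivative
    of the total in the threshold: W(λ) = λ·slope − cost_term exactly.
    """

    threshold: float
    per_drug: list[WelfareResult]
    total: float
    slope: float
    cost_term: float

    def at_threshold(self, threshold: float) -> float:
        """Closed-form total at another threshold (W is affine in λ)."""
        return threshold * self.slope - self.cost_term


@dataclass
class TornadoEntry:
    """One univariate-sensitivity bar: a parameter and its scenario totals."""

    parameter: str
    low_total: float
    high_total: float
    range: float = field(init=False)
    rank: int = 0

    def __post_init__(self):
        self.range = abs(self.high_total - self.low_total)
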