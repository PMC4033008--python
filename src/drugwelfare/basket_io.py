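"""Reading, validating and writing drug baskets and adjustment tables.

File formats (all CSV, UTF-8, ``.`` decimal mark, no thousands separators):

* basket — header ``name,brand,ratio_amount,ratio_currency,ratio_price_year,
  ratio_outcome_unit,ratio_target_amount,delta_effect,time_horizon_years,
  n_users,perspective,user_source``; an empty cell is a missing value.
* adjustment tables — long format ``table,currency,year,value`` with
  ``table`` one of ``deflator`` / ``ppp``.
* results — ``name,threshold,adjusted_ratio,annual_effect,n_users,welfare``
  plus a final ``TOTAL`` row (and a ``SLOPE`` row when an aggregate is given).

Column names in basket files can be remapped through ``schema_config``; the
bundled fixture of the 31-drug basket uses the canonical names above.
"""

from __future__ import annotations

import math
from importlib import resources
from os import PathLike

import pandas as pd

from .errors import BasketValidationError, RowValidationError, SchemaError
from .types import (
    KNOWN_CURRENCIES,
    AdjustmentTables,
    BasketWelfare,
    DrugRecord,
    MoneyPerOutcome,
    OutcomeUnit,
    UserSource,
    WelfareResult,
)

BASKET_COLUMNS = [
    "name", "brand", "ratio_amount", "ratio_currency", "ratio_price_year",
    "ratio_outcome_unit", "ratio_target_amount", "delta_effect",
    "time_horizon_years", "n_users", "perspective", "user_source",
]

#: Target-country economic basis of every ``ratio_target_amount`` column.
TARGET_CURRENCY = "CHF"
TARGET_YEAR = 2010


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and not value.strip()
    )


def _parse_row(i: int, row: dict) -> DrugRecord:
    def num(field: str, required: bool = True) -> float | None:
        raw = row.get(field)
        if _is_missing(raw):
            if required:
                raise RowValidationError(i, "value is missing", field)
            return None
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise RowValidationError(
                i, f"unparseable numeric {raw!r}", field
            ) from None

    name = row.get("name")
    if _is_missing(name):
        raise RowValidationError(i, "drug name is missing", "name")

    currency = str(row["ratio_currency"]).strip().upper()
    if currency not in KNOWN_CURRENCIES:
        raise RowValidationError(
            i, f"unknown currency code {currency!r}", "ratio_currency"
        )
    try:
        unit = OutcomeUnit.parse(str(row["ratio_outcome_unit"]))
    except ValueError as exc:
        raise RowValidationError(i, str(exc), "ratio_outcome_unit") from None

    amount = num("ratio_amount")
    year = num("ratio_price_year")
    target_amount = num("ratio_target_amount", required=False)
    source_raw = row.get("user_source")
    try:
        ratio_original = MoneyPerOutcome(amount, currency, int(year), unit)
        ratio_target = (
            None
            if target_amount is None
            else MoneyPerOutcome(target_amount, TARGET_CURRENCY, TARGET_YEAR, unit)
        )
        return DrugRecord(
            name=str(name).strip(),
            brand="" if _is_missing(row.get("brand")) else str(row["brand"]).strip(),
            ratio_original=ratio_original,
            ratio_target=ratio_target,
            delta_effect=num("delta_effect"),
            time_horizon_years=num("time_horizon_years"),
            n_users=num("n_users", required=False),
            perspective=""
            if _is_missing(row.get("perspective"))
            else str(row["perspective"]).strip(),
            user_source=None if _is_missing(source_raw) else UserSource(str(source_raw)),
        )
    except ValueError as exc:
        raise RowValidationError(i, str(exc)) from None


def scan_basket(
    path: str | PathLike, schema_config: dict[str, str] | None = None
) -> tuple[list[DrugRecord], list[RowValidationError]]:
    """Parse a basket file leniently.

    Returns accepted records (in file order) and one diagnostic per rejected
    row, so that ``len(accepted) + len(diagnostics)`` equals the number of
    data rows — no row is dropped silently.

    ``schema_config`` maps canonical column names to the names used in the
    file, e.g. ``{"ratio_amount": "icer"}``.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (schema_config or {}).items()}
    frame = frame.rename(columns=rename)
    required = set(BASKET_COLUMNS) - {"brand", "perspective", "user_source", "n_users"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")

    records: list[DrugRecord] = []
    diagnostics: list[RowValidationError] = []
    for i, row in enumerate(frame.to_dict(orient="records")):
        try:
            records.append(_parse_row(i, row))
        except RowValidationError as exc:
            diagnostics.append(exc)
    return records, diagnostics


def read_basket(
    path: str | PathLike, schema_config: dict[str, str] | None = None
) -> list[DrugRecord]:
    """Parse a basket file strictly: any invalid row aborts the read.

    The raised :class:`BasketValidationError` carries a row-indexed
    diagnostic for every rejected row.
    """
    records, diagnostics = scan_basket(path, schema_config)
    if diagnostics:
        raise BasketValidationError(diagnostics)
    return records


def write_basket(records: list[DrugRecord], path: str | PathLike) -> None:
    """Write records in the canonical basket format (inverse of read)."""
    rows = []
    for r in records:
        rows.append({
            "name": r.name,
            "brand": r.brand,
            "ratio_amount": r.ratio_original.amount,
            "ratio_currency": r.ratio_original.currency,
            "ratio_price_year": r.ratio_original.price_year,
            "ratio_outcome_unit": r.ratio_original.outcome_unit.value,
            "ratio_target_amount": "" if r.ratio_target is None else r.ratio_target.amount,
            "delta_effect": r.delta_effect,
            "time_horizon_years": r.time_horizon_years,
            "n_users": "" if r.n_users is None else r.n_users,
            "perspective": r.perspective,
            "user_source": "" if r.user_source is None else r.user_source.value,
        })
    pd.DataFrame(rows, columns=BASKET_COLUMNS).to_csv(path, index=False)


def read_adjustment_tables(
    path: str | PathLike,
    target_currency: str = TARGET_CURRENCY,
    target_year: int = TARGET_YEAR,
) -> AdjustmentTables:
    """Read deflator/PPP tables from the long CSV format.

    Non-positive values fail immediately naming the cell; completeness
    against a particular basket is only checked at adjustment time.
    """
    frame = pd.read_csv(path)
    missing = {"table", "currency", "year", "value"} - set(frame.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")
    deflator: dict[tuple[str, int], float] = {}
    ppp: dict[tuple[str, int], float] = {}
    for _, row in frame.iterrows():
        key = (str(row["currency"]).upper(), int(row["year"]))
        value = float(row["value"])
        if not (value > 0):
            raise ValueError(
                f"{row['table']} ({key[0]}, {key[1]}) = {value}: "
                "must be strictly positive"
            )
        table = str(row["table"]).strip().lower()
        if table == "deflator":
            deflator[key] = value
        elif table == "ppp":
            ppp[key] = value
        else:
            raise SchemaError(f"unknown table kind {row['table']!r}")
    return AdjustmentTables(deflator, ppp, target_currency, target_year)


def write_adjustment_tables(tables: AdjustmentTables, path: str | PathLike) -> None:
    rows = [
        {"table": "deflator", "currency": c, "year": y, "value": repr(v)}
        for (c, y), v in sorted(tables.deflator.items())
    ] + [
        {"table": "ppp", "currency": c, "year": y, "value": repr(v)}
        for (c, y), v in sorted(tables.ppp.items())
    ]
    pd.DataFrame(rows, columns=["table", "currency", "year", "value"]).to_csv(
        path, index=False
    )


def write_results(
    results: list[WelfareResult],
    path: str | PathLike,
    aggregate: BasketWelfare | None = None,
) -> None:
    """Write per-drug welfare rows plus a final TOTAL row, money to 2 d.p.

    When ``aggregate`` is supplied a SLOPE row (Σ annual_effect × n_users,
    the basket's QALYs per year) is written before the total.
    """
    if not results:
        raise ValueError("results must be non-empty")
    rows = [
        {
            "name": r.name,
            "threshold": f"{r.threshold:.2f}",
            "adjusted_ratio": f"{r.adjusted_ratio:.2f}",
            "annual_effect": repr(r.annual_effect),
            "n_users": repr(r.n_users),
            "welfare": f"{r.welfare:.2f}",
        }
        for r in results
    ]
    if aggregate is not None:
        rows.append({
            "name": "SLOPE", "threshold": "", "adjusted_ratio": "",
            "annual_effect": repr(aggregate.slope), "n_users": "", "welfare": "",
        })
    rows.append({
        "name": "TOTAL", "threshold": "", "adjusted_ratio": "",
        "annual_effect": "", "n_users": "",
        "welfare": f"{sum(r.welfare for r in results):.2f}",
    })
    pd.DataFrame(
        rows,
        columns=["name", "threshold", "adjusted_ratio", "annual_effect",
                 "n_users", "welfare"],
    ).to_csv(path, index=False)


def _data_path(filename: str):
    return resources.files("drugwelfare.data").joinpath(filename)


def load_bundled_basket() -> list[DrugRecord]:
    """The 31-drug basket of published cost-effectiveness results, as printed."""
    with resources.as_file(_data_path("table2_basket.csv")) as p:
        return read_basket(p)


def load_bundled_welfare() -> dict[str, float]:
    """Printed per-drug welfare impacts (CHF/year at the 100,000 threshold)."""
    frame = pd.read_csv(_data_path("table2_welfare.csv"))
    return dict(zip(frame["name"], frame["welfare"].astype(float)))


def load_bundled_adjustment_tables() -> AdjustmentTables:
    """Synthetic deflator/PPP tables calibrated to the basket's implied factors.

    Real national-accounts series are not bundled; these tables reproduce,
    per (currency, price-year) pair, the geometric mean of the combined
    adjustment factors implied by the basket's paired original/adjusted
    columns. Rows sharing a pair can imply slightly different factors
    (country-specific sources), so individual adjusted values are only
    approximated except where the pair is unique to one drug.
    """
    with resources.as_file(_data_path("adjustment_tables_synthetic.csv")) as p:
        return read_adjustment_tables(p)


def load_implied_factors() -> pd.DataFrame:
    """Per-drug combined adjustment factors (adjusted/original), the
    calibration artifact behind the synthetic tables."""
    return pd.read_csv(_data_path("implied_factors.csv"))
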