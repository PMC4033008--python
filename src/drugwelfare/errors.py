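"""Exception hierarchy for the welfare-impact pipeline.

Every error a caller may want to catch programmatically derives from
:class:`WelfareError`; validation failures carry enough context (row
numbers, field names, (currency, year) cells) to locate the offending
input without re-parsing anything.
"""

from __future__ import annotations


class WelfareError(Exception):
    """Base class for all package errors."""


class SchemaError(WelfareError):
    """A required column is missing or the file header cannot be resolved."""


class RowValidationError(WelfareError):
    """A data row violates a record invariant.

    Attributes
    ----------
    row : int
        Zero-based data-row index (header excluded).
    field : str | None
        Offending field, when attributable to one.
    """

    def __init__(self, row: int, message: str, field: str | None = None):
        self.row = row
        self.field = field
        where = f"row {row}" + (f", field {field!r}" if field else "")
        super().__init__(f"{where}: {message}")


class BasketValidationError(WelfareError):
    """One or more rows of a basket file were rejected; carries all diagnostics."""

    def __init__(self, diagnostics: list[RowValidationError]):
        self.diagnostics = diagnostics
        lines = "; ".join(str(d) for d in diagnostics)
        super().__init__(f"{len(diagnostics)} row(s) rejected: {lines}")


class CompletenessError(WelfareError):
    """An adjustment-table lookup failed; names the (table, currency, year) cell."""

    def __init__(self, table: str, currency: str, year: int):
        self.table = table
        self.currency = currency
        self.year = year
        super().__init__(f"no {table} entry for ({currency}, {year})")


class MissingInputError(WelfareError):
    """A record lacks a field the requested computation needs."""


class UnresolvedUsersError(WelfareError):
    """No route (explicit count, package sales, welfare inversion) yields a user count."""


class NoUniqueSolutionError(WelfareError):
    """User inversion is undefined: zero net monetary benefit per user."""


class SpecError(WelfareError):
    """A synthetic-data specification is infeasible or degenerate."""
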