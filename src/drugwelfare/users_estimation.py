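"""Supplying the number-of-users input.

User counts for the published basket are confidential and unprinted, so the
analysis reconstructs them. Two routes:

* **inversion** — the welfare formula is linear in n, so a known welfare
  value pins the count exactly:  n = W / ((λ − c) · Δe / T);
* **package sales** — persons treated per year from units sold:
  n = packages · doses_per_package / (daily_dose · treatment_days).

Inverted counts are kept as reals: the published per-drug welfare figures
imply non-integer counts under exact inversion, and rounding them would
propagate into every downstream total. Round only at reporting, if at all.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

from .errors import NoUniqueSolutionError, UnresolvedUsersError, WelfareError
from .types import DrugRecord, UserSource

#: Days of therapy per year assumed for chronic treatments; episodic
#: therapies must supply their own figure.
DEFAULT_TREATMENT_DAYS = 365.0


def invert_users(welfare: float, threshold: float, record: DrugRecord) -> float:
    """Back-derive the user count that yields ``welfare`` at ``threshold``.

    Exact inverse of the welfare formula in n wherever the per-user annual
    net benefit (λ − c)·Δe/T is nonzero; zero benefit admits no unique
    solution. A negative result is returned, but flagged with a warning —
    it signals mutually inconsistent inputs, since user counts are
    nonnegative by nature.
    """
    ratio = record.require_target_ratio()
    per_user = (threshold - ratio.amount) * record.annual_effect
    if per_user == 0:
        raise NoUniqueSolutionError(
            f"{record.name}: zero net benefit per user at threshold "
            f"{threshold}; any user count yields welfare 0"
        )
    n = welfare / per_user
    if n < 0:
        warnings.warn(
            f"{record.name}: inversion gives negative users ({n:.4g}); "
            "welfare and net-benefit signs are inconsistent",
            stacklevel=2,
        )
    return n


def users_from_packages(
    packages_sold: float,
    doses_per_package: float,
    usual_daily_dose: float,
    treatment_days_per_year: float = DEFAULT_TREATMENT_DAYS,
) -> float:
    """Persons treated per year implied by annual package sales."""
    for label, value in (
        ("packages_sold", packages_sold),
        ("doses_per_package", doses_per_package),
        ("usual_daily_dose", usual_daily_dose),
        ("treatment_days_per_year", treatment_days_per_year),
    ):
        if not (value > 0):
            raise WelfareError(f"{label} must be > 0, got {value}")
    return packages_sold * doses_per_package / (
        usual_daily_dose * treatment_days_per_year
    )


def populate_users(
    basket: list[DrugRecord],
    welfare_by_name: dict[str, float] | None = None,
    threshold: float = 100_000.0,
    packages_by_name: dict[str, dict] | None = None,
) -> list[DrugRecord]:
    """Fill ``n_users`` on every record, tagging its provenance.

    Precedence per record: an explicit count wins; otherwise package-sales
    data (``packages_by_name[name]`` holding the ``users_from_packages``
    keyword arguments); otherwise inversion from ``welfare_by_name[name]``
    at ``threshold``. A record reachable by none of the three routes aborts
    the population, naming the drug.
    """
    welfare_by_name = welfare_by_name or {}
    packages_by_name = packages_by_name or {}
    out: list[DrugRecord] = []
    for record in basket:
        if record.n_users is not None:
            out.append(replace(record))
        elif record.name in packages_by_name:
            n = users_from_packages(**packages_by_name[record.name])
            out.append(replace(record, n_users=n, user_source=UserSource.PACKAGES_DERIVED))
        elif record.name in welfare_by_name:
            n = invert_users(welfare_by_name[record.name], threshold, record)
            out.append(replace(record, n_users=n, user_source=UserSource.INVERTED))
        else:
            raise UnresolvedUsersError(
                f"{record.name}: no explicit count, package data or welfare "
                "value to derive users from"
            )
    return out
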