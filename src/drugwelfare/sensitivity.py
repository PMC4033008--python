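"""Univariate sensitivity analysis with tornado-style parameter ranking.

One parameter class is perturbed at a time across the whole basket — the
ICER, the incremental effect and the time horizon by ±20%, the user count
by ±50%, and the threshold by replacing the base-case value with low/high
alternatives — and the basket total is recomputed for each scenario. The
ranking compares the absolute range each parameter induces in the total.

Perturbations are multiplicative on the signed field value (so a 0.8
factor on a negative, dominant ICER makes it less negative); an
absolute-shift mode for the ratio is available for callers who prefer
shifting toward/away from the threshold instead. A per-drug mode exists
but the default perturbs all drugs at once, matching a one-way analysis
over parameter classes rather than per-drug tornado bars.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from os import PathLike

import pandas as pd
import yaml

from .errors import WelfareError
from .types import DrugRecord, TornadoEntry
from .welfare_engine import total_welfare

PERTURBABLE = ("threshold", "n_users", "adjusted_ratio", "delta_effect", "time_horizon")


@dataclass
class PerturbationPlan:
    """Low/high factors per parameter plus the alternative thresholds.

    Defaults follow the study design: ±20% on the adjusted ratio, the
    effect and the horizon; ±50% on users; thresholds 50,000 and 150,000.
    """

    factors: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "adjusted_ratio": (0.8, 1.2),
        "delta_effect": (0.8, 1.2),
        "time_horizon": (0.8, 1.2),
        "n_users": (0.5, 1.5),
    })
    thresholds: tuple[float, float] = (50_000.0, 150_000.0)

    @classmethod
    def from_yaml(cls, path: str | PathLike) -> "PerturbationPlan":
        """Load a plan from a config file.

        Expected keys: ``thresholds: [low, high]`` and, per parameter,
        ``<parameter>: {low_factor: f, high_factor: f}``.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        plan = cls()
        if "thresholds" in raw:
            lo, hi = raw.pop("thresholds")
            plan.thresholds = (float(lo), float(hi))
        for parameter, spec in raw.items():
            if parameter not in PERTURBABLE or parameter == "threshold":
                raise WelfareError(
                    f"unknown perturbable parameter {parameter!r}; "
                    f"valid: {', '.join(p for p in PERTURBABLE if p != 'threshold')}"
                )
            plan.factors[parameter] = (
                float(spec["low_factor"]), float(spec["high_factor"])
            )
        return plan


def perturb_basket(
    basket: list[DrugRecord], parameter: str, factor: float
) -> list[DrugRecord]:
    """Scale one field by ``factor`` on every record; all else untouched.

    The threshold is not a record field and is perturbed at evaluation
    time, so it is rejected here.
    """
    if not (factor > 0):
        raise WelfareError(f"perturbation factor must be > 0, got {factor}")
    if parameter not in PERTURBABLE or parameter == "threshold":
        raise WelfareError(
            f"cannot perturb {parameter!r} at record level; valid: "
            f"{', '.join(p for p in PERTURBABLE if p != 'threshold')}"
        )
    out = []
    for r in basket:
        if parameter == "adjusted_ratio":
            ratio = r.require_target_ratio()
            out.append(replace(r, ratio_target=ratio.with_amount(ratio.amount * factor)))
        elif parameter == "delta_effect":
            out.append(replace(r, delta_effect=r.delta_effect * factor))
        elif parameter == "time_horizon":
            out.append(replace(r, time_horizon_years=r.time_horizon_years * factor))
        else:  # n_users
            out.append(replace(r, n_users=r.require_users() * factor))
    return out


@dataclass
class SensitivityReport:
    """Ranked tornado entries plus the scenario-wide extremes."""

    base_threshold: float
    base_total: float
    entries: list[TornadoEntry]
    min_total: float
    max_total: float
    min_scenario: str
    max_scenario: str


def run_sensitivity(
    basket: list[DrugRecord],
    base_threshold: float,
    plan: PerturbationPlan | None = None,
    per_drug: bool = False,
) -> SensitivityReport:
    """One-way sensitivity analysis over the plan's parameter classes.

    Returns one tornado entry per parameter, ranked 1..K by descending
    range (ties broken alphabetically), together with the global minimum
    and maximum across all scenario totals. With ``per_drug=True`` the
    report instead contains one entry per (parameter, drug) pair.
    """
    plan = plan or PerturbationPlan()
    base_total = total_welfare(base_threshold, basket).total

    def scenario(parameter: str, factor: float, records: list[DrugRecord]) -> float:
        try:
            return total_welfare(base_threshold, perturb_basket(records, parameter, factor)).total
        except WelfareError as exc:
            raise WelfareError(
                f"scenario {parameter} x{factor}: {exc}"
            ) from exc

    entries: list[TornadoEntry] = []
    lo_thr, hi_thr = plan.thresholds
    entries.append(TornadoEntry(
        parameter="threshold",
        low_total=total_welfare(lo_thr, basket).total,
        high_total=total_welfare(hi_thr, basket).total,
    ))
    if per_drug:
        for parameter, (lo, hi) in sorted(plan.factors.items()):
            for i, record in enumerate(basket):
                def one(factor: float) -> float:
                    varied = list(basket)
                    varied[i] = perturb_basket([record], parameter, factor)[0]
                    return total_welfare(base_threshold, varied).total
                entries.append(TornadoEntry(
                    parameter=f"{parameter}:{record.name}",
                    low_total=one(lo), high_total=one(hi),
                ))
    else:
        for parameter, (lo, hi) in sorted(plan.factors.items()):
            entries.append(TornadoEntry(
                parameter=parameter,
                low_total=scenario(parameter, lo, basket),
                high_total=scenario(parameter, hi, basket),
            ))

    entries.sort(key=lambda e: (-e.range, e.parameter))
    for rank, entry in enumerate(entries, start=1):
        entry.rank = rank

    totals = {}
    for e in entries:
        totals[f"{e.parameter} (low)"] = e.low_total
        totals[f"{e.parameter} (high)"] = e.high_total
    min_scenario = min(totals, key=totals.get)
    max_scenario = max(totals, key=totals.get)
    return SensitivityReport(
        base_threshold=base_threshold,
        base_total=base_total,
        entries=entries,
        min_total=totals[min_scenario],
        max_total=totals[max_scenario],
        min_scenario=min_scenario,
        max_scenario=max_scenario,
    )


def write_tornado(report: SensitivityReport, path: str | PathLike) -> None:
    """Tornado CSV: parameter, low/high scenario totals, range, rank.

    Endpoints are totals, not deltas from base; the deltas are also
    written so bars can be read either way.
    """
    pd.DataFrame([
        {
            "parameter": e.parameter,
            "low_total": f"{e.low_total:.2f}",
            "high_total": f"{e.high_total:.2f}",
            "range": f"{e.range:.2f}",
            "rank": e.rank,
            "low_delta": f"{e.low_total - report.base_total:.2f}",
            "high_delta": f"{e.high_total - report.base_total:.2f}",
        }
        for e in report.entries
    ]).to_csv(path, index=False)


def plot_tornado(report: SensitivityReport, path: str | PathLike) -> None:
    """Horizontal-bar tornado diagram of scenario totals around the base case."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = sorted(report.entries, key=lambda e: e.range)
    labels = [e.parameter for e in entries]
    lows = [e.low_total - report.base_total for e in entries]
    highs = [e.high_total - report.base_total for e in entries]
    fig, ax = plt.subplots(figsize=(7, 0.6 * len(entries) + 1.5))
    ax.barh(labels, highs, color="#4878a8", label="high scenario")
    ax.barh(labels, lows, color="#c44e52", label="low scenario")
    ax.axvline(0.0, color="black", lw=0.8)
    ax.set_xlabel(f"change in annual welfare vs base case "
                  f"(base = {report.base_total:,.0f})")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
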