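"""The welfare-impact formula and its basket aggregates.

Per drug, the annual welfare impact at a willingness-to-pay threshold λ
(target-currency units per QALY) is the population-scaled, annualized net
monetary benefit

    W = (λ − c) · (Δe / T) · n

with c the harmonized ICER/ICUR, Δe the incremental effect per treated
patient over the model's time horizon T (years), and n the number of users.
For dominant interventions c < 0, so the first factor becomes λ + |c| — a
plain consequence of signed arithmetic, not a special case.

The basket total is affine in λ:  W_total(λ) = λ·Σ(Δe/T·n) − Σ(c·Δe/T·n),
which this module exploits to evaluate many thresholds exactly from one
pass over the basket.
"""

from __future__ import annotations

import warnings

from .errors import WelfareError
from .types import BasketWelfare, DrugRecord, OutcomeUnit, WelfareResult

#: Base-case willingness-to-pay threshold, target-currency units per QALY.
DEFAULT_THRESHOLD = 100_000.0


def welfare_impact(threshold: float, record: DrugRecord) -> WelfareResult:
    """Annual welfare of one drug at the given QALY threshold.

    Requires a harmonized ratio and a user count (errors direct the caller
    to the module that supplies the missing piece). Results for effects
    measured in LY or MLY rather than QALY carry ``outcome_unit_caveat``:
    valuing an unweighted life year at the QALY threshold overstates the
    benefit whenever quality of life is imperfect.
    """
    ratio = record.require_target_ratio()
    n = record.require_users()
    k = record.annual_effect
    return WelfareResult(
        name=record.name,
        threshold=threshold,
        adjusted_ratio=ratio.amount,
        annual_effect=k,
        n_users=n,
        welfare=(threshold - ratio.amount) * k * n,
        outcome_unit_caveat=ratio.outcome_unit is not OutcomeUnit.QALY,
    )


def total_welfare(threshold: float, basket: list[DrugRecord]) -> BasketWelfare:
    """Sum per-drug welfare over a basket; empty baskets total zero.

    Besides the total, reports the basket slope Σ(Δe/T·n) and cost term
    Σ(c·Δe/T·n), from which the total at any other threshold follows in
    closed form. A record with negative incremental effect triggers a
    warning: without knowing the cost-effectiveness-plane quadrant, the
    sign of its ICER is ambiguous.
    """
    per_drug: list[WelfareResult] = []
    slope = 0.0
    cost_term = 0.0
    for record in basket:
        if record.delta_effect < 0:
            warnings.warn(
                f"{record.name}: negative incremental effect; ICER sign is "
                "ambiguous without quadrant information",
                stacklevel=2,
            )
        try:
            result = welfare_impact(threshold, record)
        except WelfareError as exc:
            raise WelfareError(f"basket evaluation failed at {record.name}: {exc}") from exc
        per_drug.append(result)
        weight = result.annual_effect * result.n_users
        slope += weight
        cost_term += result.adjusted_ratio * weight
    return BasketWelfare(
        threshold=threshold,
        per_drug=per_drug,
        total=sum(r.welfare for r in per_drug),
        slope=slope,
        cost_term=cost_term,
    )


def welfare_at_thresholds(
    basket: list[DrugRecord], thresholds: list[float]
) -> dict[float, float]:
    """Basket totals at several thresholds via the affine closed form.

    Exactly consistent with re-evaluating the basket at each threshold:
    W(λ2) − W(λ1) = (λ2 − λ1)·Σ(Δe/T·n) holds to machine precision.
    """
    if not thresholds:
        return {}
    base = total_welfare(thresholds[0], basket)
    return {lam: base.at_threshold(lam) for lam in thresholds}
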