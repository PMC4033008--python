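
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import drugwelfare as dw
from drugwelfare.errors import MissingInputError, WelfareError
from drugwelfare.types import DrugRecord, MoneyPerOutcome, OutcomeUnit
from drugwelfare.welfare_engine import total_welfare, welfare_at_thresholds, welfare_impact

LAMBDA = 100_000.0


def record(ratio=30_000.0, delta=0.5, horizon=10.0, users=1_000.0,
           unit=OutcomeUnit.QALY, name="x"):
    return DrugRecord(
        name=name,
        ratio_target=MoneyPerOutcome(ratio, "CHF", 2010, unit),
        delta_effect=delta,
        time_horizon_years=horizon,
        n_users=users,
    )


def test_zero_welfare_when_threshold_equals_ratio():
    assert welfare_impact(LAMBDA, record(ratio=LAMBDA)).welfare == 0.0


def test_hand_arithmetic_on_a_dominant_drug():
    # oseltamivir-like inputs: (100,000 + 5,226.96) × 0.0034 × 10,000
    r = record(ratio=-5_226.96, delta=0.0034, horizon=1.0, users=10_000.0)
    assert welfare_impact(LAMBDA, r).welfare == pytest.approx(3_577_716.64)


def test_dominant_sign_flip_is_plain_arithmetic():
    # (λ − (−c)) must equal (λ + c): the "sign flip" for dominant drugs is
    # a consequence of signed arithmetic, not a separate code path
    c = 5_226.96
    via_formula = welfare_impact(LAMBDA, record(ratio=-c)).welfare
    via_flip = (LAMBDA + c) * record().annual_effect * 1_000.0
    assert via_formula == pytest.approx(via_flip, rel=1e-12)


def test_above_threshold_drug_yields_negative_welfare(populated_basket):
    cinacalcet = next(r for r in populated_basket if r.name == "Cinacalcet")
    result = welfare_impact(LAMBDA, cinacalcet)
    assert result.welfare == pytest.approx(-59_101.0, rel=1e-9)
    assert result.welfare < 0


def test_caveat_flag_for_non_qaly_outcome_units(populated_basket):
    flags = {r.name: welfare_impact(LAMBDA, r).outcome_unit_caveat
             for r in populated_basket}
    assert flags["Bosentan monohydrate"] is True   # LYG study
    assert flags["Interferon beta-1a"] is True     # MLY study
    assert flags["Cinacalcet"] is False
    assert sum(flags.values()) == 6  # five LYG studies + one MLY study


def test_missing_users_error_directs_to_estimation(basket):
    with pytest.raises(MissingInputError, match="populate_users"):
        welfare_impact(LAMBDA, basket[0])


def test_missing_target_ratio_error_directs_to_adjustment():
    r = record()
    r.ratio_target = None
    with pytest.raises(MissingInputError, match="adjust"):
        welfare_impact(LAMBDA, r)


def test_total_is_sum_of_printed_welfare(populated_basket):
    agg = total_welfare(LAMBDA, populated_basket)
    assert agg.total == pytest.approx(781_388_456.0, rel=1e-9)


def test_empty_basket_totals_zero():
    agg = total_welfare(LAMBDA, [])
    assert agg.total == 0.0 and agg.slope == 0.0


def test_single_drug_total_equals_its_welfare():
    r = record()
    assert total_welfare(LAMBDA, [r]).total == welfare_impact(LAMBDA, r).welfare


def test_total_failure_names_the_drug(basket):
    with pytest.raises(WelfareError, match="Bosentan"):
        total_welfare(LAMBDA, basket)  # users never populated


def test_closed_form_agrees_with_per_drug_summation(populated_basket):
    agg = total_welfare(LAMBDA, populated_basket)
    closed = LAMBDA * agg.slope - agg.cost_term
    assert closed == pytest.approx(agg.total, rel=1e-9)


def test_threshold_sweep_is_affine(populated_basket):
    w = welfare_at_thresholds(populated_basket, [50_000.0, 100_000.0, 150_000.0])
    # second difference of an affine function vanishes (up to float roundoff
    # of ~1e9-franc intermediates)
    second_diff = w[150_000.0] - 2 * w[100_000.0] + w[50_000.0]
    assert abs(second_diff) <= 1e6 * np.finfo(float).eps * abs(w[100_000.0])
    agg = total_welfare(LAMBDA, populated_basket)
    assert w[150_000.0] - w[100_000.0] == pytest.approx(50_000.0 * agg.slope, rel=1e-12)


def test_threshold_sweep_matches_direct_re_evaluation(populated_basket):
    w = welfare_at_thresholds(populated_basket, [50_000.0, 150_000.0])
    for lam in (50_000.0, 150_000.0):
        direct = total_welfare(lam, populated_basket).total
        assert w[lam] == pytest.approx(direct, rel=1e-12)


@settings(deadline=None, derandomize=True)
@given(
    ratio=st.floats(-250_000.0, 150_000.0),
    delta=st.floats(1e-4, 7.0),
    horizon=st.floats(0.002, 75.0),
    users=st.floats(0.0, 500_000.0),
    k=st.floats(0.1, 10.0),
)
def test_welfare_scaling_laws(ratio, delta, horizon, users, k):
    """Welfare is linear in users and effect, inversely proportional to the
    horizon, and affine in the threshold."""
    base = welfare_impact(LAMBDA, record(ratio, delta, horizon, users)).welfare
    assert welfare_impact(LAMBDA, record(ratio, delta, horizon, users * k)).welfare \
        == pytest.approx(k * base, rel=1e-9, abs=1e-6)
    assert welfare_impact(LAMBDA, record(ratio, delta * k, horizon, users)).welfare \
        == pytest.approx(k * base, rel=1e-9, abs=1e-6)
    assert welfare_impact(LAMBDA, record(ratio, delta, horizon * k, users)).welfare \
        == pytest.approx(base / k, rel=1e-9, abs=1e-6)


def test_quadrant_correctness_on_a_synthetic_basket():
    spec = dw.BasketSpec(n_drugs=40, seed=11)
    for r in dw.generate_basket(spec):
        w = welfare_impact(LAMBDA, r).welfare
        c = r.ratio_target.amount
        if r.n_users > 0 and r.delta_effect > 0:
            assert (w > 0) == (c < LAMBDA)
    # a dominant drug beats a zero-priced equivalent of itself
    dominant = record(ratio=-10_000.0)
    free = record(ratio=0.0)
    assert welfare_impact(LAMBDA, dominant).welfare > welfare_impact(LAMBDA, free).welfare


def test_welfare_zero_iff_degenerate():
    assert welfare_impact(LAMBDA, record(ratio=LAMBDA)).welfare == 0.0
    assert welfare_impact(LAMBDA, record(users=0.0)).welfare == 0.0
    assert welfare_impact(LAMBDA, record()).welfare != 0.0


def test_negative_effect_warns_at_basket_level():
    r = record(delta=-0.5)
    with pytest.warns(UserWarning, match="ambiguous"):
        total_welfare(LAMBDA, [r])


def test_exactly_one_negative_welfare_drug_in_published_basket(populated_basket):
    agg = total_welfare(LAMBDA, populated_basket)
    negative = [r.name for r in agg.per_drug if r.welfare < 0]
    assert negative == ["Cinacalcet"]
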