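
import pytest

import drugwelfare as dw
from drugwelfare.errors import WelfareError
from drugwelfare.sensitivity import (
    PerturbationPlan,
    perturb_basket,
    run_sensitivity,
    write_tornado,
)
from drugwelfare.types import DrugRecord, MoneyPerOutcome

LAMBDA = 100_000.0


def record(ratio=30_000.0, delta=0.5, horizon=10.0, users=1_000.0, name="x"):
    return DrugRecord(
        name=name,
        ratio_target=MoneyPerOutcome(ratio, "CHF", 2010, "QALY"),
        delta_effect=delta,
        time_horizon_years=horizon,
        n_users=users,
    )


def test_identity_factor_leaves_basket_unchanged(populated_basket):
    for parameter in ("adjusted_ratio", "delta_effect", "time_horizon", "n_users"):
        out = perturb_basket(populated_basket, parameter, 1.0)
        assert out == populated_basket
        assert out[0] is not populated_basket[0]  # deep copy, not aliasing


def test_unknown_parameter_lists_valid_names():
    with pytest.raises(WelfareError, match="n_users"):
        perturb_basket([record()], "price", 1.1)
    with pytest.raises(WelfareError, match="record level"):
        perturb_basket([record()], "threshold", 1.1)


def test_horizon_shrink_inflates_annual_effect(populated_basket):
    out = perturb_basket(populated_basket, "time_horizon", 0.8)
    for a, b in zip(out, populated_basket):
        assert a.annual_effect == pytest.approx(b.annual_effect / 0.8, rel=1e-12)


def test_ratio_perturbation_scales_signed_value():
    dominant = record(ratio=-10_000.0)
    out = perturb_basket([dominant], "adjusted_ratio", 0.8)
    assert out[0].ratio_target.amount == pytest.approx(-8_000.0)  # less negative


def test_effect_and_users_perturbations_coincide(populated_basket):
    """Scaling the per-patient effect and scaling the population enter the
    formula identically, so their scenario totals match exactly."""
    for factor in (0.8, 1.2, 1.5):
        via_effect = dw.total_welfare(
            LAMBDA, perturb_basket(populated_basket, "delta_effect", factor)).total
        via_users = dw.total_welfare(
            LAMBDA, perturb_basket(populated_basket, "n_users", factor)).total
        assert via_effect == pytest.approx(via_users, rel=1e-12)


def test_users_scenarios_scale_base_total_exactly(populated_basket):
    base = dw.total_welfare(LAMBDA, populated_basket).total
    report = run_sensitivity(populated_basket, LAMBDA)
    users_entry = next(e for e in report.entries if e.parameter == "n_users")
    assert users_entry.low_total == pytest.approx(0.5 * base, rel=1e-12)
    assert users_entry.high_total == pytest.approx(1.5 * base, rel=1e-12)


def test_ranks_are_a_permutation_with_largest_range_first(populated_basket):
    report = run_sensitivity(populated_basket, LAMBDA)
    ranks = sorted(e.rank for e in report.entries)
    assert ranks == list(range(1, len(report.entries) + 1))
    ordered = sorted(report.entries, key=lambda e: e.rank)
    assert all(a.range >= b.range for a, b in zip(ordered, ordered[1:]))
    assert all(e.range == abs(e.high_total - e.low_total) for e in report.entries)


def test_published_basket_ranking_threshold_then_users(populated_basket):
    report = run_sensitivity(populated_basket, LAMBDA)
    by_rank = {e.rank: e.parameter for e in report.entries}
    assert by_rank[1] == "threshold"
    assert by_rank[2] == "n_users"


def test_published_basket_scenario_extremes(populated_basket):
    report = run_sensitivity(populated_basket, LAMBDA)
    assert report.min_total == pytest.approx(260.77e6, rel=0.005)
    assert report.max_total == pytest.approx(1.30e9, rel=0.005)
    assert report.min_scenario == "threshold (low)"
    assert report.max_scenario == "threshold (high)"


def test_all_published_scenario_totals_positive(populated_basket):
    report = run_sensitivity(populated_basket, LAMBDA)
    for e in report.entries:
        assert e.low_total > 0 and e.high_total > 0


def test_scenarios_match_independent_re_evaluation(populated_basket):
    plan = PerturbationPlan()
    report = run_sensitivity(populated_basket, LAMBDA, plan)
    for e in report.entries:
        if e.parameter == "threshold":
            lo, hi = plan.thresholds
            assert e.low_total == pytest.approx(
                dw.total_welfare(lo, populated_basket).total, rel=1e-12)
            assert e.high_total == pytest.approx(
                dw.total_welfare(hi, populated_basket).total, rel=1e-12)
        else:
            flo, fhi = plan.factors[e.parameter]
            for factor, got in ((flo, e.low_total), (fhi, e.high_total)):
                oracle = dw.total_welfare(
                    LAMBDA, perturb_basket(populated_basket, e.parameter, factor)).total
                assert got == pytest.approx(oracle, rel=1e-12)


def test_threshold_scenarios_obey_affine_identity(populated_basket):
    agg = dw.total_welfare(LAMBDA, populated_basket)
    report = run_sensitivity(populated_basket, LAMBDA)
    thr = next(e for e in report.entries if e.parameter == "threshold")
    assert thr.low_total == pytest.approx(
        agg.total + (50_000.0 - LAMBDA) * agg.slope, rel=1e-12)
    assert thr.high_total == pytest.approx(
        agg.total + (150_000.0 - LAMBDA) * agg.slope, rel=1e-12)


def test_zero_base_welfare_drug_has_zero_users_range():
    basket = [record(ratio=LAMBDA)]
    report = run_sensitivity(basket, LAMBDA)
    users_entry = next(e for e in report.entries if e.parameter == "n_users")
    assert users_entry.range == 0.0


def test_plan_from_yaml_and_tornado_csv(tmp_path, populated_basket):
    import pandas as pd

    config = tmp_path / "plan.yaml"
    config.write_text(
        "thresholds: [60000, 140000]\n"
        "n_users: {low_factor: 0.7, high_factor: 1.3}\n"
    )
    plan = PerturbationPlan.from_yaml(config)
    assert plan.thresholds == (60_000.0, 140_000.0)
    assert plan.factors["n_users"] == (0.7, 1.3)
    assert plan.factors["delta_effect"] == (0.8, 1.2)  # untouched default

    report = run_sensitivity(populated_basket, LAMBDA, plan)
    out = tmp_path / "tornado.csv"
    write_tornado(report, out)
    frame = pd.read_csv(out)
    assert list(frame.columns[:5]) == ["parameter", "low_total", "high_total",
                                       "range", "rank"]
    assert len(frame) == 5


def test_per_drug_mode_emits_one_entry_per_parameter_drug_pair(populated_basket):
    report = run_sensitivity(populated_basket[:3], LAMBDA, per_drug=True)
    # threshold stays global; 4 record-level parameters × 3 drugs
    assert len(report.entries) == 1 + 4 * 3
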