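"""Deterministic sensitivity analyses: scaling, taper, out-of-pocket."""

import pandas as pd
import pytest

from pactcost import (
    ConfigurationError,
    CostCategory,
    CostConsequenceModel,
    DiscountSpec,
    HoursTaperScenario,
    OutOfPocketComparison,
    ScheduleRules,
    SchoolRecosting,
    UnitCostScaleScenario,
    UnitCostTable,
    apply_hours_taper,
    apply_unit_cost_scale,
    compare_out_of_pocket,
    unit_cost_scale_grid,
)
from pactcost.categories import SOCIETAL_CATEGORIES


def toy_model() -> CostConsequenceModel:
    """Hand-sized deterministic model.

    13-month per-child costs — intervention: delivery 500, hospital 100,
    productivity 100, informal care 100; control: hospital 100, informal
    care 100. Annualization 1, discount 0, 6-year horizon, no school costs.
    """
    table = UnitCostTable(
        country="toyland",
        entries={"delivery": 500.0, "hosp": 20.0, "school_day": 10.0},
        item_category={
            "delivery": CostCategory.PACT_DELIVERY,
            "hosp": CostCategory.HOSPITAL_HEALTH,
            "school_day": CostCategory.EDUCATION_CHILDCARE,
            "work_hours": CostCategory.PARENTAL_PRODUCTIVITY,
            "care_hours": CostCategory.PARENTAL_INFORMAL_CARE,
        },
        wage_per_hour=20.0,
        informal_care_price_per_hour=1.0,
    )
    rows = []
    for child in ("i1", "i2"):
        rows += [
            (child, "intervention", "delivery", 1.0),
            (child, "intervention", "hosp", 5.0),
            (child, "intervention", "work_hours", 5.0),
            (child, "intervention", "care_hours", 100.0),
        ]
    for child in ("c1", "c2"):
        rows += [
            (child, "control", "delivery", 0.0),
            (child, "control", "hosp", 5.0),
            (child, "control", "work_hours", 0.0),
            (child, "control", "care_hours", 100.0),
        ]
    records = pd.DataFrame(rows, columns=["child_id", "arm", "item_id", "quantity"])
    return CostConsequenceModel(
        records,
        table,
        rules=ScheduleRules(annualization_factor=1.0),
        discount=DiscountSpec(annual_rate=0.0),
        school_recosting=SchoolRecosting("school_day", {"intervention": 0.0, "control": 0.0}),
        item_filter_threshold=0.0,
    )


def _incs(model, n_boot=0):
    res = model.fit(n_boot=n_boot)
    return {
        (inc.perspective, inc.horizon): inc.difference
        for inc in res.incrementals.values()
    }


class TestUnitCostScale:
    def test_zero_change_is_exact_identity(self):
        model = toy_model()
        base = _incs(model)
        scenario = UnitCostScaleScenario(
            target_categories=SOCIETAL_CATEGORIES, relative_change=0.0
        )
        assert apply_unit_cost_scale(model, scenario) == base

    def test_single_category_contribution_scales_linearly(self):
        model = toy_model()
        base = _incs(model)
        scenario = UnitCostScaleScenario(
            target_categories={CostCategory.PACT_DELIVERY}, relative_change=0.5
        )
        scaled = apply_unit_cost_scale(model, scenario)
        # delivery difference is 500 at 13 months; x1.5 adds 250 everywhere
        assert scaled[("healthcare_service", "13 months")] == pytest.approx(
            base[("healthcare_service", "13 months")] + 250.0
        )
        assert scaled[("societal", "6 years")] == pytest.approx(
            base[("societal", "6 years")] + 250.0
        )

    def test_scaling_all_categories_scales_every_incremental(self):
        """Homogeneity: +20% on all unit costs -> every incremental x1.2."""
        model = toy_model()
        base = _incs(model)
        scenario = UnitCostScaleScenario(
            target_categories=SOCIETAL_CATEGORIES | {CostCategory.OUT_OF_POCKET},
            relative_change=0.2,
        )
        scaled = apply_unit_cost_scale(model, scenario)
        for key, value in base.items():
            assert scaled[key] == pytest.approx(1.2 * value, rel=1e-12)

    def test_base_model_results_unchanged_after_scenario(self):
        model = toy_model()
        before = _incs(model)
        apply_unit_cost_scale(
            model,
            UnitCostScaleScenario(
                target_categories=SOCIETAL_CATEGORIES, relative_change=0.5
            ),
        )
        assert _incs(model) == before  # bit-identical refit

    def test_change_of_minus_one_rejected(self):
        with pytest.raises(ConfigurationError):
            UnitCostScaleScenario(
                target_categories={CostCategory.HOSPITAL_HEALTH}, relative_change=-1.0
            )

    def test_grid_rows_reproducible_by_single_calls(self):
        model = toy_model()
        grid = unit_cost_scale_grid(
            model,
            changes=(-0.2, 0.2),
            category_groups={"delivery": {CostCategory.PACT_DELIVERY}},
        )
        for row in grid.itertuples(index=False):
            single = apply_unit_cost_scale(
                model,
                UnitCostScaleScenario(
                    target_categories={CostCategory.PACT_DELIVERY},
                    relative_change=row.relative_change,
                ),
            )
            assert single[(row.perspective, row.horizon)] == row.incremental


class TestHoursTaper:
    def test_zero_reduction_is_identity(self):
        model = toy_model()
        base = _incs(model)
        tapered = apply_hours_taper(model, HoursTaperScenario(reduction=0.0))
        for key, value in tapered.items():
            assert value == base[key]

    def test_flat_stream_hand_sum(self):
        """100/yr tapered 20% from year 3 at r=0: 100 x (2 + 4 x 0.8) = 520."""
        model = toy_model()
        tapered = apply_hours_taper(model, HoursTaperScenario(reduction=0.2))
        # base 6-year societal = delivery 500 + productivity diff 600;
        # productivity diff becomes 520, informal care diff stays 0
        assert tapered[("societal", "6 years")] == pytest.approx(500.0 + 520.0)

    def test_full_reduction_keeps_only_first_two_years(self):
        model = toy_model()
        tapered = apply_hours_taper(model, HoursTaperScenario(reduction=1.0))
        # productivity diff = 100 x 2 years; informal care diff remains 0
        assert tapered[("societal", "6 years")] == pytest.approx(500.0 + 200.0)

    def test_untargeted_years_untouched(self):
        model = toy_model()
        tapered = apply_hours_taper(
            model, HoursTaperScenario(reduction=0.5, applies_from_year=6)
        )
        # only year 6 halves: productivity diff 100 x (5 + 0.5)
        assert tapered[("societal", "6 years")] == pytest.approx(500.0 + 550.0)

    def test_invalid_reduction_rejected(self):
        with pytest.raises(ConfigurationError):
            HoursTaperScenario(reduction=1.5)


class TestOutOfPocket:
    def test_published_irish_comparison(self):
        """1,696 vs 9,599 euros: difference -7,903, contrast > 80%."""
        diff, contrast = compare_out_of_pocket(
            OutOfPocketComparison(pact_arm_mean=1696.0, alternative_tau_mean=9599.0)
        )
        assert diff == pytest.approx(-7903.0)
        assert contrast == pytest.approx(100 * (9599 - 1696) / 9599)
        assert contrast > 80.0

    def test_equal_means_give_zero(self):
        diff, contrast = compare_out_of_pocket(
            OutOfPocketComparison(pact_arm_mean=500.0, alternative_tau_mean=500.0)
        )
        assert diff == 0.0
        assert contrast == 0.0

    def test_zero_alternative_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_out_of_pocket(
                OutOfPocketComparison(pact_arm_mean=10.0, alternative_tau_mean=0.0)
            )

    def test_breakdown_must_sum_to_stated_mean(self):
        with pytest.raises(ConfigurationError, match="breakdown"):
            OutOfPocketComparison(
                pact_arm_mean=10.0,
                alternative_tau_mean=100.0,
                category_breakdown={"travel": 30.0, "healthcare": 30.0},
            )

    def test_consistent_breakdown_accepted(self):
        cmp = OutOfPocketComparison(
            pact_arm_mean=10.0,
            alternative_tau_mean=100.0,
            category_breakdown={"travel": 40.0, "healthcare": 60.0},
        )
        assert sum(cmp.category_breakdown.values()) == cmp.alternative_tau_mean
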