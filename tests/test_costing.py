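"""Costing, perspective aggregation, incrementals and waterfalls."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pactcost import (
    BROADER_SERVICE,
    HEALTHCARE_SERVICE,
    SOCIETAL,
    ArmCostSummary,
    ConfigurationError,
    CostCategory,
    CostingError,
    cost_records,
    filter_items,
    incremental,
    inflate_to_2020,
    informal_care_cost,
    productivity_cost,
    summarize_arm,
    waterfall,
)
from pactcost.categories import WATERFALL_ORDER

from conftest import make_summary


class TestFilterItems:
    def test_rare_item_dropped(self):
        rows = [("c%d" % i, "control", "rare", 0.0) for i in range(143)]
        rows[0] = ("c0", "control", "rare", 1.0)
        df = pd.DataFrame(rows, columns=["child_id", "arm", "item_id", "quantity"])
        assert filter_items(df, threshold=0.5) == []

    def test_mean_above_half_retained(self):
        df = pd.DataFrame(
            {
                "child_id": ["a", "b", "c", "d"],
                "arm": ["intervention"] * 2 + ["control"] * 2,
                "item_id": ["svc"] * 4,
                "quantity": [0.0, 1.0, 1.0, 1.0],
            }
        )
        assert filter_items(df, threshold=0.5) == ["svc"]  # mean 0.75 > 0.5

    def test_threshold_zero_keeps_any_use(self):
        df = pd.DataFrame(
            {
                "child_id": ["a", "b"],
                "arm": ["intervention", "control"],
                "item_id": ["svc", "svc"],
                "quantity": [0.1, 0.0],
            }
        )
        assert filter_items(df, threshold=0.0) == ["svc"]

    def test_boundary_is_strict(self):
        df = pd.DataFrame(
            {
                "child_id": ["a", "b"],
                "arm": ["intervention", "control"],
                "item_id": ["svc", "svc"],
                "quantity": [0.5, 0.5],
            }
        )
        assert filter_items(df, threshold=0.5) == []


class TestCostRecords:
    def test_two_items_one_category_hand_sum(self, simple_table):
        df = pd.DataFrame(
            {
                "child_id": ["c1", "c1"],
                "arm": ["intervention", "intervention"],
                "item_id": ["visit_a", "visit_b"],
                "quantity": [2.0, 4.0],
            }
        )
        costs = cost_records(df, simple_table)
        assert costs.loc["c1", "community_health_social"] == pytest.approx(120.0)

    def test_zero_quantities_cost_nothing(self, simple_table):
        df = pd.DataFrame(
            {
                "child_id": ["c1"],
                "arm": ["control"],
                "item_id": ["therapy"],
                "quantity": [0.0],
            }
        )
        costs = cost_records(df, simple_table)
        assert costs.drop(columns="arm").loc["c1"].sum() == 0.0

    def test_hour_items_priced_by_wage_and_care_price(self, simple_table):
        df = pd.DataFrame(
            {
                "child_id": ["c1", "c1"],
                "arm": ["control", "control"],
                "item_id": ["work_hours", "care_hours"],
                "quantity": [10.0, 100.0],
            }
        )
        costs = cost_records(df, simple_table)
        assert costs.loc["c1", "parental_productivity"] == pytest.approx(200.0)
        assert costs.loc["c1", "parental_informal_care"] == pytest.approx(1500.0)

    def test_unknown_item_named_in_error(self, simple_table):
        df = pd.DataFrame(
            {
                "child_id": ["c1"],
                "arm": ["control"],
                "item_id": ["mystery"],
                "quantity": [1.0],
            }
        )
        with pytest.raises(CostingError, match="mystery"):
            cost_records(df, simple_table)

    def test_pipeline_equals_spreadsheet_oracle(self, five_child_records, simple_table):
        """Per-child costs match a brute-force row-by-row sum, exactly."""
        costs = cost_records(five_child_records, simple_table)
        prices = {"visit_a": 10.0, "visit_b": 25.0, "therapy": 50.0}
        cats = {
            "visit_a": "community_health_social",
            "visit_b": "community_health_social",
            "therapy": "speech_language_therapy",
        }
        expected: dict = {}
        for row in five_child_records.itertuples(index=False):
            key = (row.child_id, cats[row.item_id])
            expected[key] = expected.get(key, 0.0) + row.quantity * prices[row.item_id]
        for (child, cat), value in expected.items():
            assert costs.loc[child, cat] == value  # exact, no tolerance


class TestScalarCosting:
    def test_productivity_is_hours_times_wage(self, simple_table):
        assert productivity_cost(0.0, simple_table) == 0.0
        assert productivity_cost(10.0, simple_table) == 200.0

    def test_informal_care_is_hours_times_market_price(self, simple_table):
        assert informal_care_cost(100.0, simple_table) == 1500.0

    def test_negative_hours_rejected(self, simple_table):
        with pytest.raises(ConfigurationError):
            productivity_cost(-1.0, simple_table)
        with pytest.raises(ConfigurationError):
            informal_care_cost(-1.0, simple_table)

    def test_inflation_is_multiplicative(self, simple_table):
        from dataclasses import replace

        t = replace(simple_table, inflation_index=1.10)
        assert inflate_to_2020(100.0, t) == pytest.approx(110.0)
        a = replace(simple_table, inflation_index=1.2)
        b = replace(simple_table, inflation_index=1.5)
        ab = replace(simple_table, inflation_index=1.2 * 1.5)
        assert inflate_to_2020(inflate_to_2020(100.0, a), b) == pytest.approx(
            inflate_to_2020(100.0, ab)
        )


class TestSummaries:
    def test_arm_mean_is_hand_mean(self, five_child_records, simple_table):
        costs = cost_records(five_child_records, simple_table)
        summary = summarize_arm(costs, "control")
        # therapy: children c3,c4,c5 used 2,0,0 sessions at 50
        assert summary.mean(CostCategory.SPEECH_LANGUAGE_THERAPY) == pytest.approx(
            (100.0 + 0.0 + 0.0) / 3
        )
        assert summary.n_children == 3

    def test_permutation_invariance(self, five_child_records, simple_table):
        costs = cost_records(five_child_records, simple_table)
        shuffled = cost_records(
            five_child_records.sample(frac=1.0, random_state=0), simple_table
        )
        a = summarize_arm(costs, "intervention")
        b = summarize_arm(shuffled, "intervention")
        assert a.mean_cost_by_category == b.mean_cost_by_category

    def test_empty_arm_rejected(self, five_child_records, simple_table):
        costs = cost_records(five_child_records, simple_table)
        only_ctrl = costs[costs["arm"] == "control"]
        with pytest.raises(ConfigurationError):
            summarize_arm(only_ctrl, "intervention")


class TestIncremental:
    def test_published_england_aggregates(self, england_13m_summaries):
        """Healthcare +5,928; broader +4,510; societal -3,619 euros."""
        s = england_13m_summaries
        health = incremental(s["intervention"], s["control"], HEALTHCARE_SERVICE)
        broader = incremental(s["intervention"], s["control"], BROADER_SERVICE)
        societal = incremental(s["intervention"], s["control"], SOCIETAL)
        assert health.difference == pytest.approx(5928.0)
        assert broader.difference == pytest.approx(4510.0)
        assert societal.difference == pytest.approx(-3619.0)
        # and the arm totals behind them
        assert s["intervention"].total(HEALTHCARE_SERVICE.categories) == pytest.approx(7651.0)
        assert s["control"].total(HEALTHCARE_SERVICE.categories) == pytest.approx(1723.0)
        assert s["intervention"].total(SOCIETAL.categories) == pytest.approx(95689.0)
        assert s["control"].total(SOCIETAL.categories) == pytest.approx(99308.0)

    def test_identical_summaries_give_zero(self, england_13m_summaries):
        s = england_13m_summaries["intervention"]
        for perspective in (HEALTHCARE_SERVICE, BROADER_SERVICE, SOCIETAL):
            assert incremental(s, s, perspective).difference == 0.0

    def test_missing_category_counts_as_zero_with_warning(self, caplog):
        a = make_summary("intervention", pact_delivery=100.0)
        b = make_summary("control")
        import logging

        with caplog.at_level(logging.WARNING, logger="pactcost.costing"):
            inc = incremental(a, b, HEALTHCARE_SERVICE)
        assert inc.difference == pytest.approx(100.0)
        assert any("missing" in rec.message for rec in caplog.records)


@st.composite
def summaries(draw):
    means = {
        cat: draw(st.floats(min_value=0, max_value=1e5, allow_nan=False))
        for cat in CostCategory
    }
    return ArmCostSummary(
        arm=draw(st.sampled_from(["intervention", "control"])),
        n_children=draw(st.integers(min_value=1, max_value=100)),
        mean_cost_by_category=means,
    )


class TestIncrementalProperties:
    @settings(max_examples=50, derandomize=True)
    @given(a=summaries(), b=summaries())
    def test_antisymmetry(self, a, b):
        for perspective in (HEALTHCARE_SERVICE, BROADER_SERVICE, SOCIETAL):
            ab = incremental(a, b, perspective).difference
            ba = incremental(b, a, perspective).difference
            assert ab == pytest.approx(-ba, abs=1e-6)

    @settings(max_examples=50, derandomize=True)
    @given(a=summaries(), b=summaries())
    def test_nested_perspective_additivity(self, a, b):
        """societal = broader + productivity diff + informal-care diff."""
        broader = incremental(a, b, BROADER_SERVICE).difference
        societal = incremental(a, b, SOCIETAL).difference
        family = (
            a.mean(CostCategory.PARENTAL_PRODUCTIVITY)
            - b.mean(CostCategory.PARENTAL_PRODUCTIVITY)
            + a.mean(CostCategory.PARENTAL_INFORMAL_CARE)
            - b.mean(CostCategory.PARENTAL_INFORMAL_CARE)
        )
        assert societal == pytest.approx(broader + family, abs=1e-6)


class TestWaterfall:
    def test_first_bar_is_delivery_difference(self, england_13m_summaries):
        s = england_13m_summaries
        steps = waterfall(s["intervention"], s["control"])
        cat, diff, cum = steps[0]
        assert cat is CostCategory.PACT_DELIVERY
        assert diff == pytest.approx(6198.0)
        assert cum == pytest.approx(6198.0)

    def test_final_cumulative_equals_societal_incremental(self, england_13m_summaries):
        s = england_13m_summaries
        steps = waterfall(s["intervention"], s["control"])
        societal = incremental(s["intervention"], s["control"], SOCIETAL)
        assert steps[-1][2] == pytest.approx(societal.difference)

    def test_middle_reordering_preserves_final_total(self):
        """Brute force over all middle-category permutations of a 4-step toy."""
        a = make_summary(
            "intervention",
            pact_delivery=500.0,
            speech_language_therapy=100.0,
            education_childcare=50.0,
            parental_informal_care=10.0,
        )
        b = make_summary(
            "control",
            speech_language_therapy=300.0,
            education_childcare=80.0,
            parental_informal_care=90.0,
        )
        middle = [
            CostCategory.SPEECH_LANGUAGE_THERAPY,
            CostCategory.EDUCATION_CHILDCARE,
            CostCategory.PARENTAL_INFORMAL_CARE,
        ]
        finals = set()
        for perm in itertools.permutations(middle):
            order = [CostCategory.PACT_DELIVERY, *perm]
            steps = waterfall(a, b, order)
            finals.add(round(steps[-1][2], 9))
        assert finals == {round(500 - 200 - 30 - 80, 9)}

    def test_order_must_start_with_delivery(self, england_13m_summaries):
        s = england_13m_summaries
        with pytest.raises(ConfigurationError):
            waterfall(s["intervention"], s["control"], list(WATERFALL_ORDER[::-1]))

    def test_omitting_nonzero_category_rejected(self, england_13m_summaries):
        s = england_13m_summaries
        with pytest.raises(ConfigurationError, match="omits"):
            waterfall(s["intervention"], s["control"], list(WATERFALL_ORDER[:-1]))
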