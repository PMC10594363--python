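import pandas as pd
import pytest

from pactcost import ArmCostSummary, CostCategory, UnitCostTable


@pytest.fixture
def simple_table() -> UnitCostTable:
    """Minimal unit-cost table: two priced items in one category, plus hours."""
    return UnitCostTable(
        country="toyland",
        entries={"visit_a": 10.0, "visit_b": 25.0, "therapy": 50.0},
        item_category={
            "visit_a": CostCategory.COMMUNITY_HEALTH_SOCIAL,
            "visit_b": CostCategory.COMMUNITY_HEALTH_SOCIAL,
            "therapy": CostCategory.SPEECH_LANGUAGE_THERAPY,
            "work_hours": CostCategory.PARENTAL_PRODUCTIVITY,
            "care_hours": CostCategory.PARENTAL_INFORMAL_CARE,
        },
        wage_per_hour=20.0,
        informal_care_price_per_hour=15.0,
    )


def make_summary(arm: str, n: int = 10, **means_by_name) -> ArmCostSummary:
    """Build an ArmCostSummary from category-name keyword arguments."""
    means = {CostCategory(name): value for name, value in means_by_name.items()}
    return ArmCostSummary(arm=arm, n_children=n, mean_cost_by_category=means)


@pytest.fixture
def england_13m_summaries() -> dict:
    """Arm summaries whose totals match the published England aggregates."""
    intervention = make_summary(
        "intervention",
        n=74,
        pact_delivery=6198.0,
        speech_language_therapy=600.0,
        community_health_social=450.0,
        hospital_health=403.0,
        education_childcare=9000.0,
        social_care=1000.0,
        parental_productivity=18038.0,
        parental_informal_care=60000.0,
    )
    control = make_summary(
        "control",
        n=69,
        pact_delivery=0.0,
        speech_language_therapy=800.0,
        community_health_social=500.0,
        hospital_health=423.0,
        education_childcare=10200.0,
        social_care=1218.0,
        parental_productivity=19000.0,
        parental_informal_care=67167.0,
    )
    return {"intervention": intervention, "control": control}


@pytest.fixture
def five_child_records() -> pd.DataFrame:
    """Tiny cohort for spreadsheet-style oracle checks."""
    rows = [
        ("c1", "intervention", "visit_a", 2.0),
        ("c1", "intervention", "visit_b", 4.0),
        ("c1", "intervention", "therapy", 1.0),
        ("c2", "intervention", "visit_a", 0.0),
        ("c2", "intervention", "visit_b", 1.0),
        ("c2", "intervention", "therapy", 3.0),
        ("c3", "control", "visit_a", 5.0),
        ("c3", "control", "visit_b", 0.0),
        ("c3", "control", "therapy", 2.0),
        ("c4", "control", "visit_a", 1.0),
        ("c4", "control", "visit_b", 1.0),
        ("c4", "control", "therapy", 0.0),
        ("c5", "control", "visit_a", 0.0),
        ("c5", "control", "visit_b", 0.0),
        ("c5", "control", "therapy", 0.0),
    ]
    return pd.DataFrame(rows, columns=["child_id", "arm", "item_id", "quantity"])
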