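"""Costing of resource-use records at 2020 euro prices.

Resource-use quantities (service events or hours over the 13-month trial
window) are turned into per-child costs by multiplying by country-specific
unit costs. Two categories are hour-denominated and priced by dedicated rules
rather than an item-level price: parental productivity losses are valued at
the national average wage (human capital approach) and informal-care hours at
the market price of a formal caregiver (proxy good approach). Costs are then
averaged per arm and differenced under a perspective to give incremental
costs (intervention minus control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .categories import (
    HOURLY_CATEGORIES,
    SOCIETAL_CATEGORIES,
    WATERFALL_ORDER,
    CostCategory,
    PerspectiveSpec,
)
from .errors import ConfigurationError, CostingError, ParseError

logger = logging.getLogger(__name__)

DEFAULT_ITEM_FILTER_THRESHOLD = 0.5


@dataclass(frozen=True)
class UnitCostTable:
    """Country-specific euro-per-unit prices at 2020 price levels.

    Parameters
    ----------
    country : str
        Country identifier (e.g. ``"england"``).
    entries : mapping of item_id -> euros per unit
        Prices for event-denominated items.
    item_category : mapping of item_id -> CostCategory
        Category membership of every known item.
    wage_per_hour : float
        National average wage, used to value parental time off work.
    informal_care_price_per_hour : float
        Market price of one hour of formal (paid) care, used to value
        informal-care hours.
    inflation_index : float
        Multiplicative index bringing nominal costs to 2020 prices.
    """

    country: str
    entries: Mapping[str, float] = field(default_factory=dict)
    item_category: Mapping[str, CostCategory] = field(default_factory=dict)
    wage_per_hour: float = 0.0
    informal_care_price_per_hour: float = 0.0
    inflation_index: float = 1.0

    def __post_init__(self) -> None:
        if self.inflation_index <= 0:
            raise ConfigurationError("inflation_index must be positive")
        for item, price in self.entries.items():
            if price < 0:
                raise ConfigurationError(f"negative unit cost for item {item!r}")
        if self.wage_per_hour < 0 or self.informal_care_price_per_hour < 0:
            raise ConfigurationError("hourly prices must be nonnegative")

    def category_of(self, item_id: str) -> CostCategory:
        try:
            return self.item_category[item_id]
        except KeyError:
            raise CostingError(f"unknown item id {item_id!r}: no category mapping")

    def unit_price(self, item_id: str) -> float:
        """Effective euro price of one unit of *item_id*.

        Hour-denominated parental items resolve to the wage / formal-care
        price; everything else to its table entry.
        """
        category = self.category_of(item_id)
        if category is CostCategory.PARENTAL_PRODUCTIVITY:
            return self.wage_per_hour
        if category is CostCategory.PARENTAL_INFORMAL_CARE:
            return self.informal_care_price_per_hour
        try:
            return self.entries[item_id]
        except KeyError:
            raise CostingError(f"unknown item id {item_id!r}: no unit cost entry")

    def scaled(self, categories: Iterable[CostCategory], factor: float) -> "UnitCostTable":
        """Return a copy with prices of *categories* multiplied by *factor*."""
        categories = set(categories)
        entries = {
            item: price * factor if self.item_category.get(item) in categories else price
            for item, price in self.entries.items()
        }
        wage = self.wage_per_hour * (
            factor if CostCategory.PARENTAL_PRODUCTIVITY in categories else 1.0
        )
        care = self.informal_care_price_per_hour * (
            factor if CostCategory.PARENTAL_INFORMAL_CARE in categories else 1.0
        )
        return replace(
            self,
            entries=entries,
            wage_per_hour=wage,
            informal_care_price_per_hour=care,
        )

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def from_files(cls, csv_path: str | Path, config_path: str | Path) -> "UnitCostTable":
        """Build a table from an item CSV and a country YAML config.

        The CSV has columns ``item_id, category, euro_per_unit``; the YAML
        supplies ``country, wage_per_hour, informal_care_price_per_hour,
        inflation_index``.
        """
        df = pd.read_csv(csv_path)
        required = {"item_id", "category", "euro_per_unit"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"unit-cost CSV missing columns: {sorted(missing)}")
        entries: dict[str, float] = {}
        item_category: dict[str, CostCategory] = {}
        for row in df.itertuples(index=False):
            try:
                category = CostCategory(row.category)
            except ValueError:
                raise ParseError(
                    f"unit-cost CSV row for item {row.item_id!r}: "
                    f"unknown category {row.category!r}"
                )
            item_category[str(row.item_id)] = category
            if category not in HOURLY_CATEGORIES:
                entries[str(row.item_id)] = float(row.euro_per_unit)
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(
            country=cfg.get("country", "unknown"),
            entries=entries,
            item_category=item_category,
            wage_per_hour=float(cfg.get("wage_per_hour", 0.0)),
            informal_care_price_per_hour=float(
                cfg.get("informal_care_price_per_hour", 0.0)
            ),
            inflation_index=float(cfg.get("inflation_index", 1.0)),
        )

    def to_files(self, csv_path: str | Path, config_path: str | Path) -> None:
        rows = [
            {
                "item_id": item,
                "category": self.item_category[item].value,
                "euro_per_unit": self.unit_price(item),
            }
            for item in sorted(self.item_category)
        ]
        pd.DataFrame(rows).to_csv(csv_path, index=False)
        with open(config_path, "w") as fh:
            yaml.safe_dump(
                {
                    "country": self.country,
                    "wage_per_hour": self.wage_per_hour,
                    "informal_care_price_per_hour": self.informal_care_price_per_hour,
                    "inflation_index": self.inflation_index,
                },
                fh,
            )


@dataclass(frozen=True)
class ArmCostSummary:
    """Per-arm mean cost per child by category (euros, 2020)."""

    arm: str
    n_children: int
    mean_cost_by_category: Mapping[CostCategory, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ConfigurationError("arm summary requires at least one child")
        for cat, mean in self.mean_cost_by_category.items():
            if mean < 0:
                raise ConfigurationError(f"negative mean cost for category {cat}")

    def mean(self, category: CostCategory) -> float:
        """Mean cost for *category*; absent categories count as zero."""
        return float(self.mean_cost_by_category.get(category, 0.0))

    def total(self, categories: Iterable[CostCategory] | None = None) -> float:
        cats = SOCIETAL_CATEGORIES if categories is None else categories
        return float(sum(self.mean(c) for c in cats))


@dataclass(frozen=True)
class IncrementalCost:
    """Mean per-child cost difference, intervention minus control."""

    perspective: str
    horizon: str
    difference: float
    by_category: Mapping[CostCategory, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations


def filter_items(records: pd.DataFrame, threshold: float = DEFAULT_ITEM_FILTER_THRESHOLD) -> list[str]:
    """Item ids whose mean quantity per child exceeds *threshold*.

    The mean is taken over all children in both arms, zeros included, and the
    comparison is strict (``mean > threshold``). The default of 0.5 events
    drops rarely used services before country-specific costing.
    """
    if records.empty:
        raise ConfigurationError("cannot filter an empty record set")
    if threshold < 0:
        raise ConfigurationError("filter threshold must be nonnegative")
    n_children = records["child_id"].nunique()
    totals = records.groupby("item_id")["quantity"].sum()
    means = totals / n_children
    return sorted(means.index[means > threshold])


def cost_records(
    records: pd.DataFrame,
    table: UnitCostTable,
    items: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-child cost by category.

    Parameters
    ----------
    records : DataFrame with columns child_id, arm, item_id, quantity.
    table : UnitCostTable
    items : optional subset of item ids to retain (e.g. from `filter_items`).

    Returns
    -------
    DataFrame indexed by child_id with an ``arm`` column and one float column
    per cost category (euros per child over the 13-month window). Every child
    appears even if all their retained quantities are zero.
    """
    df = records.copy()
    if items is not None:
        df = df[df["item_id"].isin(set(items))]
    arms = records.drop_duplicates("child_id").set_index("child_id")["arm"]

    prices = {item: table.unit_price(item) for item in df["item_id"].unique()}
    cats = {item: table.category_of(item).value for item in df["item_id"].unique()}
    df = df.assign(
        cost=df["quantity"] * df["item_id"].map(prices),
        category=df["item_id"].map(cats),
    )
    wide = df.pivot_table(
        index="child_id", columns="category", values="cost", aggfunc="sum", fill_value=0.0
    )
    wide = wide.reindex(arms.index, fill_value=0.0)
    for cat in CostCategory:
        if cat.value not in wide.columns:
            wide[cat.value] = 0.0
    wide = wide[[c.value for c in CostCategory]]
    wide.insert(0, "arm", arms)
    return wide


def productivity_cost(hours_off_work: float, table: UnitCostTable) -> float:
    """Value parental time off work at the national average wage."""
    if hours_off_work < 0:
        raise ConfigurationError("hours off work must be nonnegative")
    return hours_off_work * table.wage_per_hour


def informal_care_cost(care_hours: float, table: UnitCostTable) -> float:
    """Value unpaid care hours at the formal-caregiver market price."""
    if care_hours < 0:
        raise ConfigurationError("care hours must be nonnegative")
    return care_hours * table.informal_care_price_per_hour


def inflate_to_2020(cost: float, table: UnitCostTable) -> float:
    """Bring a nominal cost to 2020 prices via the table's inflation index."""
    return cost * table.inflation_index


def summarize_arm(per_child_costs: pd.DataFrame, arm: str) -> ArmCostSummary:
    """Arithmetic mean cost per category over the arm's children (zeros in)."""
    sub = per_child_costs[per_child_costs["arm"] == arm]
    if sub.empty:
        raise ConfigurationError(f"no children in arm {arm!r}")
    means = {
        cat: float(sub[cat.value].mean()) for cat in CostCategory if cat.value in sub
    }
    return ArmCostSummary(arm=arm, n_children=len(sub), mean_cost_by_category=means)


def incremental(
    int_summary: ArmCostSummary,
    ctrl_summary: ArmCostSummary,
    perspective: PerspectiveSpec,
    horizon: str = "13 months",
) -> IncrementalCost:
    """Incremental cost under *perspective*: intervention minus control.

    A category missing from either summary is treated as zero with a logged
    warning (this supports partial analyses).
    """
    by_category: dict[CostCategory, float] = {}
    for cat in perspective.categories:
        for summary in (int_summary, ctrl_summary):
            if cat not in summary.mean_cost_by_category:
                logger.warning(
                    "category %s missing from %s arm summary; treated as 0",
                    cat.value,
                    summary.arm,
                )
        by_category[cat] = int_summary.mean(cat) - ctrl_summary.mean(cat)
    return IncrementalCost(
        perspective=perspective.name,
        horizon=horizon,
        difference=float(sum(by_category.values())),
        by_category=by_category,
    )


def waterfall(
    int_summary: ArmCostSummary,
    ctrl_summary: ArmCostSummary,
    category_order: Sequence[CostCategory] = WATERFALL_ORDER,
) -> list[tuple[CostCategory, float, float]]:
    """Cumulative decomposition of the societal incremental cost.

    Returns ``(category, per-category difference, running cumulative total)``
    tuples in *category_order*; the last cumulative value equals the societal
    incremental exactly. The order must start with the intervention-delivery
    category and must not omit any category with a nonzero difference.
    """
    order = list(category_order)
    if not order or order[0] is not CostCategory.PACT_DELIVERY:
        raise ConfigurationError("waterfall order must begin with pact_delivery")
    omitted = SOCIETAL_CATEGORIES - set(order)
    for cat in omitted:
        if abs(int_summary.mean(cat) - ctrl_summary.mean(cat)) > 0:
            raise ConfigurationError(
                f"waterfall order omits category {cat.value} with nonzero difference"
            )
    steps: list[tuple[CostCategory, float, float]] = []
    running = 0.0
    for cat in order:
        diff = int_summary.mean(cat) - ctrl_summary.mean(cat)
        running += diff
        steps.append((cat, diff, running))
    return steps
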