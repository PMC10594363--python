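"""Temporal extrapolation of 13-month trial costs over a 6-year horizon.

Long-term resource-use data are unavailable, so the 13-month trial-window
costs are projected forward under fixed yearly-cost assumptions:

* intervention delivery costs are limited to the first modelled year (the
  13-month delivery window);
* education/childcare uses nursery-derived yearly costs for the first two
  years; from year 3 onward all children are assumed to be in primary school
  and the time previously in nursery is recosted as school time;
* every other category repeats its annualized yearly cost each year.

Future costs are discounted at an annual rate (default 3.5%) to reflect time
preference. By default the first modelled year is undiscounted (the usual
health-technology-assessment convention); an end-of-year convention is also
available because published totals rarely disambiguate the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .categories import SOCIETAL_CATEGORIES, CostCategory
from .costing import ArmCostSummary
from .errors import ConfigurationError

#: Months in the trial follow-up window; 13-month costs x 12/13 = yearly rate.
TRIAL_WINDOW_MONTHS = 13

DISCOUNT_CONVENTIONS = ("start_undiscounted", "end_of_year")


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting of future costs.

    ``start_undiscounted`` (default): year 1 carries factor 1, year t carries
    ``1/(1+r)^(t-1)``. ``end_of_year``: year t carries ``1/(1+r)^t``.
    """

    annual_rate: float = 0.035
    convention: str = "start_undiscounted"

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ConfigurationError("discount rate must be nonnegative")
        if self.convention not in DISCOUNT_CONVENTIONS:
            raise ConfigurationError(
                f"unknown discount convention {self.convention!r}; "
                f"expected one of {DISCOUNT_CONVENTIONS}"
            )


@dataclass(frozen=True)
class ScheduleRules:
    """Rules mapping 13-month costs onto the multi-year horizon."""

    pact_first_period_only: bool = True
    nursery_years: tuple[int, ...] = (1, 2)
    school_years: tuple[int, ...] = (3, 4, 5, 6)
    horizon_years: int = 6
    annualization_factor: float = 12 / 13

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ConfigurationError("horizon must be at least one year")
        if self.annualization_factor <= 0:
            raise ConfigurationError("annualization factor must be positive")
        covered = sorted(set(self.nursery_years) | set(self.school_years))
        if covered != list(range(1, self.horizon_years + 1)):
            raise ConfigurationError(
                "nursery_years and school_years must partition years "
                f"1..{self.horizon_years} without overlap"
            )
        if set(self.nursery_years) & set(self.school_years):
            raise ConfigurationError("nursery and school years overlap")


@dataclass(frozen=True)
class YearlyCostSchedule:
    """Per (arm, category) vector of yearly euros over the horizon."""

    streams: Mapping[tuple[str, CostCategory], np.ndarray]
    horizon_years: int
    discounted: bool = False
    n_children: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, vec in self.streams.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.horizon_years,):
                raise ConfigurationError(
                    f"stream {key} has length {vec.shape}, expected {self.horizon_years}"
                )
            if (vec < 0).any():
                raise ConfigurationError(f"negative yearly cost in stream {key}")

    def stream(self, arm: str, category: CostCategory) -> np.ndarray:
        return np.asarray(
            self.streams.get((arm, category), np.zeros(self.horizon_years)), dtype=float
        )

    def to_frame(self, spec: "DiscountSpec | None" = None) -> pd.DataFrame:
        """Long-format export: arm, category, year, cost[, discounted_cost]."""
        rows = []
        for (arm, cat), vec in sorted(
            self.streams.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        ):
            for year, cost in enumerate(np.asarray(vec, dtype=float), start=1):
                row = {"arm": arm, "category": cat.value, "year": year, "cost": cost}
                if spec is not None:
                    row["discounted_cost"] = cost * discount_factor(year, spec)
                rows.append(row)
        return pd.DataFrame(rows)


def annualize(cost_13m: float, rules: ScheduleRules) -> float:
    """Convert a 13-month trial-window cost to a yearly rate."""
    if cost_13m < 0:
        raise ConfigurationError("cost must be nonnegative")
    return cost_13m * rules.annualization_factor


def build_schedule(
    arm_summaries: Mapping[str, ArmCostSummary],
    rules: ScheduleRules,
    school_yearly_cost: Mapping[str, float] | None = None,
) -> YearlyCostSchedule:
    """Lay 13-month arm summaries out as undiscounted yearly cost streams.

    Parameters
    ----------
    arm_summaries : mapping arm -> ArmCostSummary (13-month costs).
    rules : ScheduleRules
    school_yearly_cost : mapping arm -> euros per year, the recosting of
        former nursery time as primary-school time from year 3 onward.
        Required whenever ``rules.school_years`` is nonempty.

    Notes
    -----
    Intervention delivery appears only in year 1 when
    ``pact_first_period_only`` (year 1 spans the 13-month delivery window, so
    the delivery cost enters un-annualized); all other categories repeat
    their annualized yearly cost every year.
    """
    if rules.school_years and school_yearly_cost is None:
        raise ConfigurationError(
            "school_yearly_cost is required when school years are modelled"
        )
    horizon = rules.horizon_years
    streams: dict[tuple[str, CostCategory], np.ndarray] = {}
    for arm, summary in arm_summaries.items():
        for cat in SOCIETAL_CATEGORIES:
            cost_13m = summary.mean(cat)
            vec = np.zeros(horizon)
            if cat is CostCategory.PACT_DELIVERY and rules.pact_first_period_only:
                vec[0] = cost_13m
            elif cat is CostCategory.EDUCATION_CHILDCARE:
                nursery_yearly = annualize(cost_13m, rules)
                school_yearly = (
                    float(school_yearly_cost.get(arm, 0.0))
                    if school_yearly_cost is not None
                    else 0.0
                )
                for year in rules.nursery_years:
                    vec[year - 1] = nursery_yearly
                for year in rules.school_years:
                    vec[year - 1] = school_yearly
            else:
                vec[:] = annualize(cost_13m, rules)
            streams[(arm, cat)] = vec
    return YearlyCostSchedule(
        streams=streams,
        horizon_years=horizon,
        discounted=False,
        n_children={arm: s.n_children for arm, s in arm_summaries.items()},
    )


def discount_factor(year_index: int, spec: DiscountSpec) -> float:
    """Discount factor for a 1-based model year."""
    if year_index < 1:
        raise ConfigurationError("year index must be >= 1")
    exponent = year_index - 1 if spec.convention == "start_undiscounted" else year_index
    return float(1.0 / (1.0 + spec.annual_rate) ** exponent)


def project(
    schedule: YearlyCostSchedule, spec: DiscountSpec
) -> dict[str, ArmCostSummary]:
    """Discounted cumulative cost per (arm, category) at the horizon.

    Returns one ArmCostSummary per arm holding present-value totals; 6-year
    incrementals and waterfalls are then computed from these by the costing
    module, exactly as at 13 months.
    """
    if schedule.discounted:
        raise ConfigurationError("schedule is already discounted")
    factors = np.array(
        [discount_factor(t, spec) for t in range(1, schedule.horizon_years + 1)]
    )
    arms = sorted({arm for arm, _ in schedule.streams})
    out: dict[str, ArmCostSummary] = {}
    for arm in arms:
        means = {
            cat: float(np.dot(schedule.stream(arm, cat), factors))
            for cat in SOCIETAL_CATEGORIES
        }
        out[arm] = ArmCostSummary(
            arm=arm,
            n_children=int(schedule.n_children.get(arm, 1)),
            mean_cost_by_category=means,
        )
    return out
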