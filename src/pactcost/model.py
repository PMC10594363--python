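"""Cost-consequence model: data in, fitted results out.

`CostConsequenceModel` bundles a two-arm resource-use cohort with a country
unit-cost table and the extrapolation/discounting rules; `fit()` runs the
full analysis and returns a `CostConsequenceResults` carrying arm-level mean
costs at 13 months and 6 years, incremental costs under each perspective,
waterfall decompositions, and bootstrap uncertainty.

Example
-------
>>> from pactcost import datasets
>>> model = datasets.country_model("england", seed=7)
>>> res = model.fit(n_boot=500, seed=7)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .categories import (
    DEFAULT_PERSPECTIVES,
    WATERFALL_ORDER,
    CostCategory,
    PerspectiveSpec,
)
from .costing import (
    DEFAULT_ITEM_FILTER_THRESHOLD,
    ArmCostSummary,
    IncrementalCost,
    UnitCostTable,
    cost_records,
    filter_items,
    incremental,
    summarize_arm,
    waterfall,
)
from .errors import ConfigurationError
from .extrapolation import (
    DiscountSpec,
    ScheduleRules,
    YearlyCostSchedule,
    build_schedule,
    project,
)
from .uncertainty import BootstrapResult, bootstrap_incremental


def _per_arm_units(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {str(k): float(v) for k, v in value.items()}
    return {"intervention": float(value), "control": float(value)}


@dataclass(frozen=True)
class SchoolRecosting:
    """Recosting of former nursery time as primary-school time (years 3+).

    The yearly school cost per arm is ``units_per_year[arm] *
    unit_price(item_id)``, so it is priced through the unit-cost table and
    scales with education unit costs in sensitivity analyses.
    """

    item_id: str
    units_per_year: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "units_per_year", _per_arm_units(self.units_per_year))
        for arm, units in self.units_per_year.items():
            if units < 0:
                raise ConfigurationError(f"negative school units for arm {arm!r}")

    def yearly_cost(self, arm: str, table: UnitCostTable) -> float:
        return self.units_per_year.get(arm, 0.0) * table.unit_price(self.item_id)


class CostConsequenceModel:
    """Two-arm cost-consequence model over 13-month and multi-year horizons.

    Parameters
    ----------
    records : DataFrame with columns child_id, arm, item_id, quantity —
        per-child resource use over the 13-month trial window.
    unit_costs : UnitCostTable at 2020 euro prices.
    rules : ScheduleRules for the multi-year projection (default: 6 years,
        nursery in years 1-2, school from year 3, annualization 12/13).
    discount : DiscountSpec (default 3.5%/year, first year undiscounted).
    perspectives : mapping name -> PerspectiveSpec; defaults to the
        healthcare-service, broader-service and societal perspectives.
    school_recosting : SchoolRecosting; required when the schedule includes
        school years.
    item_filter_threshold : drop items with pooled mean use <= this many
        events per child (default 0.5).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        unit_costs: UnitCostTable,
        rules: ScheduleRules | None = None,
        discount: DiscountSpec | None = None,
        perspectives: Mapping[str, PerspectiveSpec] | None = None,
        school_recosting: SchoolRecosting | None = None,
        item_filter_threshold: float = DEFAULT_ITEM_FILTER_THRESHOLD,
    ) -> None:
        missing = {"child_id", "arm", "item_id", "quantity"} - set(records.columns)
        if missing:
            raise ConfigurationError(f"records missing columns: {sorted(missing)}")
        self.records = records.reset_index(drop=True)
        self.unit_costs = unit_costs
        self.rules = rules if rules is not None else ScheduleRules()
        self.discount = discount if discount is not None else DiscountSpec()
        self.perspectives = (
            dict(perspectives) if perspectives is not None else dict(DEFAULT_PERSPECTIVES)
        )
        self.school_recosting = school_recosting
        self.item_filter_threshold = item_filter_threshold

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, unit_costs: UnitCostTable, **kwargs):
        """Build a model from a long-format resource-use DataFrame."""
        return cls(records, unit_costs, **kwargs)

    @classmethod
    def from_cohort_config(cls, config, unit_costs: UnitCostTable, **kwargs):
        """Generate a synthetic cohort from *config* and build a model on it."""
        from .cohort import generate_cohort

        return cls(generate_cohort(config), unit_costs, **kwargs)

    # -- functional updates (scenarios never mutate the base model) ---------

    def with_unit_costs(self, unit_costs: UnitCostTable) -> "CostConsequenceModel":
        return CostConsequenceModel(
            self.records,
            unit_costs,
            rules=self.rules,
            discount=self.discount,
            perspectives=self.perspectives,
            school_recosting=self.school_recosting,
            item_filter_threshold=self.item_filter_threshold,
        )

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        n_boot: int = 1000,
        seed: int | None = None,
        ci_level: float = 0.95,
    ) -> "CostConsequenceResults":
        """Run the full analysis.

        ``n_boot = 0`` skips the bootstrap (point estimates only); otherwise
        each perspective's 13-month incremental is bootstrapped by resampling
        children within arms.
        """
        retained = filter_items(self.records, self.item_filter_threshold)
        per_child = cost_records(self.records, self.unit_costs, items=retained)
        summaries_13m = {
            arm: summarize_arm(per_child, arm) for arm in ("intervention", "control")
        }

        horizon_13m = "13 months"
        incrementals: dict[tuple[str, str], IncrementalCost] = {}
        for name, perspective in self.perspectives.items():
            incrementals[(name, horizon_13m)] = incremental(
                summaries_13m["intervention"],
                summaries_13m["control"],
                perspective,
                horizon=horizon_13m,
            )
        waterfall_13m = waterfall(
            summaries_13m["intervention"], summaries_13m["control"], WATERFALL_ORDER
        )

        # multi-year projection
        if self.rules.school_years and self.school_recosting is None:
            raise ConfigurationError(
                "school_recosting is required when the schedule includes school years"
            )
        school_yearly = (
            {
                arm: self.school_recosting.yearly_cost(arm, self.unit_costs)
                for arm in ("intervention", "control")
            }
            if self.school_recosting is not None
            else None
        )
        schedule = build_schedule(summaries_13m, self.rules, school_yearly)
        projected = project(schedule, self.discount)
        horizon_long = f"{self.rules.horizon_years} years"
        for name, perspective in self.perspectives.items():
            incrementals[(name, horizon_long)] = incremental(
                projected["intervention"],
                projected["control"],
                perspective,
                horizon=horizon_long,
            )
        waterfall_long = waterfall(
            projected["intervention"], projected["control"], WATERFALL_ORDER
        )

        bootstrap: dict[str, BootstrapResult] = {}
        if n_boot > 0:
            for name, perspective in self.perspectives.items():
                bootstrap[name] = bootstrap_incremental(
                    per_child,
                    perspective,
                    n_replicates=n_boot,
                    seed=seed,
                    ci_level=ci_level,
                )

        return CostConsequenceResults(
            model=self,
            retained_items=retained,
            per_child_costs=per_child,
            arm_summaries=summaries_13m,
            projected_summaries=projected,
            schedule=schedule,
            incrementals=incrementals,
            waterfalls={horizon_13m: waterfall_13m, horizon_long: waterfall_long},
            bootstrap=bootstrap,
            seed=seed,
        )


@dataclass
class CostConsequenceResults:
    """Fitted results of a `CostConsequenceModel`."""

    model: CostConsequenceModel
    retained_items: list[str]
    per_child_costs: pd.DataFrame
    arm_summaries: Mapping[str, ArmCostSummary]
    projected_summaries: Mapping[str, ArmCostSummary]
    schedule: YearlyCostSchedule
    incrementals: Mapping[tuple[str, str], IncrementalCost]
    waterfalls: Mapping[str, list]
    bootstrap: Mapping[str, BootstrapResult]
    seed: int | None = None

    @property
    def horizons(self) -> list[str]:
        return list(self.waterfalls.keys())

    def incremental(self, perspective: str, horizon: str) -> IncrementalCost:
        try:
            return self.incrementals[(perspective, horizon)]
        except KeyError:
            raise ConfigurationError(
                f"no incremental for perspective {perspective!r} at {horizon!r}"
            )

    # -- tabular views -------------------------------------------------------

    def mean_cost_table(self, horizon: str) -> pd.DataFrame:
        """Arm x category mean-cost table (euros per child) with totals."""
        summaries = (
            self.arm_summaries if horizon == "13 months" else self.projected_summaries
        )
        rows = []
        for cat in CostCategory:
            rows.append(
                {
                    "category": cat.value,
                    "intervention": summaries["intervention"].mean(cat),
                    "control": summaries["control"].mean(cat),
                }
            )
        df = pd.DataFrame(rows)
        total = {
            "category": "total_societal",
            "intervention": summaries["intervention"].total(),
            "control": summaries["control"].total(),
        }
        df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
        df["difference"] = df["intervention"] - df["control"]
        return df

    def incremental_table(self) -> pd.DataFrame:
        rows = [
            {
                "perspective": inc.perspective,
                "horizon": inc.horizon,
                "incremental": inc.difference,
            }
            for inc in self.incrementals.values()
        ]
        return pd.DataFrame(rows)

    def waterfall_table(self, horizon: str) -> pd.DataFrame:
        steps = self.waterfalls[horizon]
        return pd.DataFrame(
            [
                {"category": cat.value, "difference": diff, "cumulative": cum}
                for cat, diff, cum in steps
            ]
        )

    def to_dict(self) -> dict:
        """JSON-serialisable view of every reported number."""
        out = {
            "country": self.model.unit_costs.country,
            "seed": self.seed,
            "retained_items": list(self.retained_items),
            "mean_costs": {
                h: self.mean_cost_table(h).to_dict(orient="records")
                for h in self.horizons
            },
            "incrementals": [
                {
                    "perspective": inc.perspective,
                    "horizon": inc.horizon,
                    "incremental": inc.difference,
                    "by_category": {c.value: v for c, v in sorted(
                        inc.by_category.items(), key=lambda kv: kv[0].value
                    )},
                }
                for inc in self.incrementals.values()
            ],
            "waterfalls": {
                h: self.waterfall_table(h).to_dict(orient="records")
                for h in self.horizons
            },
            "bootstrap": {
                name: {
                    "point_estimate": br.point_estimate,
                    "ci_low": br.ci_low,
                    "ci_high": br.ci_high,
                    "n_replicates": br.n_replicates,
                    "ci_level": br.ci_level,
                }
                for name, br in self.bootstrap.items()
            },
        }
        return out

    def summary(self) -> str:
        """Human-readable report: mean costs, incrementals, bootstrap CIs."""
        lines = [
            "Cost-consequence analysis"
            f" — country: {self.model.unit_costs.country}",
            "=" * 64,
        ]
        for horizon in self.horizons:
            lines.append(f"\nMean costs per child, euros 2020 ({horizon})")
            lines.append(
                self.mean_cost_table(horizon).to_string(
                    index=False, float_format=lambda v: f"{v:,.0f}"
                )
            )
        lines.append("\nIncremental costs (intervention minus control)")
        lines.append(
            self.incremental_table().to_string(
                index=False, float_format=lambda v: f"{v:,.0f}"
            )
        )
        if self.bootstrap:
            lines.append("\nBootstrap (13 months, percentile CIs)")
            rows = []
            for name, br in self.bootstrap.items():
                rows.append(
                    {
                        "perspective": name,
                        "point": br.point_estimate,
                        "ci_low": br.ci_low,
                        "ci_high": br.ci_high,
                        "replicates": br.n_replicates,
                    }
                )
            lines.append(
                pd.DataFrame(rows).to_string(
                    index=False, float_format=lambda v: f"{v:,.0f}"
                )
            )
        return "\n".join(lines)

    # -- plotting --------------------------------------------------------------

    def plot_waterfall(self, horizon: str = "13 months", ax=None):
        """Waterfall chart of the societal incremental-cost decomposition."""
        import matplotlib.pyplot as plt

        steps = self.waterfalls[horizon]
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4.5))
        start = 0.0
        for i, (cat, diff, cum) in enumerate(steps):
            color = "#1f77b4" if diff >= 0 else "#ff7f0e"
            ax.bar(i, diff, bottom=start, color=color, width=0.7)
            start = cum
        ax.axhline(0, color="black", lw=0.8)
        final = steps[-1][2]
        ax.axhline(final, color="gray", lw=1.2, ls="--", label=f"total {final:,.0f}")
        ax.set_xticks(range(len(steps)))
        ax.set_xticklabels([cat.value for cat, _, _ in steps], rotation=45, ha="right")
        ax.set_ylabel("euros per child")
        ax.set_title(f"Incremental societal cost decomposition ({horizon})")
        ax.legend()
        return ax
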