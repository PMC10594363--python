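"""Deterministic sensitivity analyses as pure scenario transforms.

Three one-way analyses probe the robustness of the incremental-cost results:

* **Unit-cost scaling** — unit costs of chosen categories are varied by a
  relative amount (the usual grid is +/-20%, +/-30% and +/-50%) and every
  downstream quantity is recomputed.
* **Hours taper** — parental productivity-loss hours and informal-care hours
  are assumed to fall by a fraction (default 20%) from year 3 of the model
  onward (children aged 6+), leaving the first two years at trial levels.
* **Out-of-pocket substitution** — the intervention arm's mean out-of-pocket
  spend is contrasted with an external usual-care estimate built from
  family expense categories (living costs, care and assistance, education,
  healthcare, travel, training/support, autism assistance dog).

Every transform leaves the base model untouched: scenarios recompute on a
modified copy, and base results are re-obtainable bit-identically afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import (
    SOCIETAL_CATEGORIES,
    CostCategory,
)
from .costing import incremental
from .errors import ConfigurationError
from .extrapolation import YearlyCostSchedule, project

if TYPE_CHECKING:  # pragma: no cover
    from .model import CostConsequenceModel

#: Relative changes used in the standard one-way grid.
DEFAULT_SCALE_GRID = (-0.5, -0.3, -0.2, 0.2, 0.3, 0.5)

HOURS_CATEGORIES = frozenset(
    {CostCategory.PARENTAL_PRODUCTIVITY, CostCategory.PARENTAL_INFORMAL_CARE}
)


@dataclass(frozen=True)
class UnitCostScaleScenario:
    """Scale the unit costs of *target_categories* by (1 + relative_change)."""

    target_categories: frozenset = field(default_factory=frozenset)
    relative_change: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_categories", frozenset(self.target_categories))
        if self.relative_change <= -1.0:
            raise ConfigurationError("relative_change must exceed -1 (costs stay >= 0)")


@dataclass(frozen=True)
class HoursTaperScenario:
    """Reduce parental hours by *reduction* from *applies_from_year* onward."""

    reduction: float = 0.20
    applies_from_year: int = 3
    target_categories: frozenset = HOURS_CATEGORIES

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_categories", frozenset(self.target_categories))
        if not 0.0 <= self.reduction <= 1.0:
            raise ConfigurationError("reduction must lie in [0, 1]")
        if self.applies_from_year < 1:
            raise ConfigurationError("applies_from_year must be >= 1")


@dataclass(frozen=True)
class OutOfPocketComparison:
    """Arm-level mean out-of-pocket spends from two sources (euros, 2020)."""

    pact_arm_mean: float
    alternative_tau_mean: float
    category_breakdown: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pact_arm_mean < 0 or self.alternative_tau_mean < 0:
            raise ConfigurationError("out-of-pocket means must be nonnegative")
        if self.category_breakdown:
            total = sum(self.category_breakdown.values())
            if any(v < 0 for v in self.category_breakdown.values()):
                raise ConfigurationError("breakdown entries must be nonnegative")
            if not math.isclose(total, self.alternative_tau_mean, rel_tol=1e-9, abs_tol=1e-6):
                raise ConfigurationError(
                    f"breakdown sums to {total}, not the stated mean "
                    f"{self.alternative_tau_mean}"
                )


# ---------------------------------------------------------------------------
# scenario applications


def apply_unit_cost_scale(
    model: "CostConsequenceModel", scenario: UnitCostScaleScenario
) -> dict[tuple[str, str], float]:
    """Recompute all incrementals with scaled unit costs.

    Returns ``{(perspective_name, horizon): incremental_euros}`` for both the
    13-month and 6-year horizons. The base model is not mutated.
    """
    factor = 1.0 + scenario.relative_change
    scaled = model.with_unit_costs(
        model.unit_costs.scaled(scenario.target_categories, factor)
    )
    results = scaled.fit(n_boot=0)
    return {
        (inc.perspective, inc.horizon): inc.difference
        for inc in results.incrementals.values()
    }


def apply_hours_taper(
    model: "CostConsequenceModel", scenario: HoursTaperScenario
) -> dict[tuple[str, str], float]:
    """Recompute 6-year incrementals with tapered parental hours.

    Yearly costs of the target categories (hours x fixed hourly price, so
    cost scales with hours) are multiplied by ``1 - reduction`` from
    ``applies_from_year`` onward; earlier years keep trial-level hours.
    """
    base = model.fit(n_boot=0)
    schedule = base.schedule
    streams = {}
    for (arm, cat), vec in schedule.streams.items():
        vec = np.asarray(vec, dtype=float).copy()
        if cat in scenario.target_categories:
            start = scenario.applies_from_year - 1
            vec[start:] *= 1.0 - scenario.reduction
        streams[(arm, cat)] = vec
    tapered = YearlyCostSchedule(
        streams=streams,
        horizon_years=schedule.horizon_years,
        discounted=False,
        n_children=schedule.n_children,
    )
    projected = project(tapered, model.discount)
    horizon = f"{schedule.horizon_years} years"
    out: dict[tuple[str, str], float] = {}
    for name, perspective in model.perspectives.items():
        inc = incremental(
            projected["intervention"], projected["control"], perspective, horizon=horizon
        )
        out[(name, horizon)] = inc.difference
    return out


def compare_out_of_pocket(cmp: OutOfPocketComparison) -> tuple[float, float]:
    """Difference and percentage contrast between out-of-pocket means.

    Returns ``(difference, contrast)`` where difference is the intervention
    arm mean minus the alternative usual-care mean (euros) and contrast is
    ``100 * (alternative - intervention) / alternative`` (percent saved
    relative to the alternative).
    """
    if cmp.alternative_tau_mean == 0:
        raise ConfigurationError(
            "contrast undefined: alternative usual-care mean is zero"
        )
    difference = cmp.pact_arm_mean - cmp.alternative_tau_mean
    contrast = 100.0 * (cmp.alternative_tau_mean - cmp.pact_arm_mean) / cmp.alternative_tau_mean
    return difference, contrast


def unit_cost_scale_grid(
    model: "CostConsequenceModel",
    changes: Sequence[float] = DEFAULT_SCALE_GRID,
    category_groups: Mapping[str, Iterable[CostCategory]] | None = None,
) -> pd.DataFrame:
    """One-way grid over relative changes x category groups.

    Each row is individually reproducible by a single
    ``apply_unit_cost_scale`` call with the same parameters.
    """
    if category_groups is None:
        category_groups = {cat.value: {cat} for cat in sorted(SOCIETAL_CATEGORIES, key=lambda c: c.value)}
    rows = []
    for group_name, cats in category_groups.items():
        for change in changes:
            scenario = UnitCostScaleScenario(
                target_categories=frozenset(cats), relative_change=change
            )
            incs = apply_unit_cost_scale(model, scenario)
            for (perspective, horizon), diff in sorted(incs.items()):
                rows.append(
                    {
                        "scenario": "unit_cost_scale",
                        "category_group": group_name,
                        "relative_change": change,
                        "perspective": perspective,
                        "horizon": horizon,
                        "incremental": diff,
                    }
                )
    return pd.DataFrame(rows)
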