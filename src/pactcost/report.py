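"""End-to-end pipeline: config in, report bundle out.

`run_pipeline` loads or generates a cohort, fits the cost-consequence model
and writes a reproducible bundle: mean-cost tables at both horizons,
incrementals per perspective, waterfall series, the yearly cost schedule,
the sensitivity-analysis grid, bootstrap summaries and a JSON manifest
carrying the config hash and seed. Identical config + seed produces a
byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import datasets
from .cohort import read_cohort
from .costing import UnitCostTable
from .errors import ConfigurationError, PactCostError
from .extrapolation import DiscountSpec, ScheduleRules
from .model import CostConsequenceModel, SchoolRecosting
from .sensitivity import (
    DEFAULT_SCALE_GRID,
    HoursTaperScenario,
    OutOfPocketComparison,
    apply_hours_taper,
    compare_out_of_pocket,
    unit_cost_scale_grid,
)

PIPELINE_STAGES = ("load", "cost", "project", "sensitivity", "report")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (one country)."""

    country: str = "england"
    cohort_csv: str | None = None  # None -> synthetic built-in cohort
    unit_cost_csv: str | None = None  # with country_config_yaml, else built-in
    country_config_yaml: str | None = None
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    rules: ScheduleRules = field(default_factory=ScheduleRules)
    n_boot: int = 1000
    sa1_changes: tuple[float, ...] = DEFAULT_SCALE_GRID
    sa2_reduction: float = 0.20
    sa2_from_year: int = 3
    sa3_pact_mean: float = datasets.OOP_PACT_ARM_MEAN
    sa3_alternative_mean: float = datasets.OOP_ALTERNATIVE_TAU_MEAN
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        cohort = raw.get("cohort", {}) or {}
        unit_costs = raw.get("unit_costs", {}) or {}
        discount = raw.get("discount", {}) or {}
        schedule = raw.get("schedule", {}) or {}
        sa = raw.get("sensitivity", {}) or {}
        kwargs: dict[str, Any] = dict(
            country=raw.get("country", "england"),
            cohort_csv=cohort.get("csv"),
            unit_cost_csv=unit_costs.get("csv"),
            country_config_yaml=unit_costs.get("config"),
            discount=DiscountSpec(**discount),
            rules=ScheduleRules(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in schedule.items()
            }),
            n_boot=int(raw.get("bootstrap", {}).get("n_replicates", 1000)),
            seed=int(raw.get("seed", 0)),
        )
        if "sa1_changes" in sa:
            kwargs["sa1_changes"] = tuple(float(c) for c in sa["sa1_changes"])
        if "sa2_reduction" in sa:
            kwargs["sa2_reduction"] = float(sa["sa2_reduction"])
        if "sa2_from_year" in sa:
            kwargs["sa2_from_year"] = int(sa["sa2_from_year"])
        if "sa3_pact_mean" in sa:
            kwargs["sa3_pact_mean"] = float(sa["sa3_pact_mean"])
        if "sa3_alternative_mean" in sa:
            kwargs["sa3_alternative_mean"] = float(sa["sa3_alternative_mean"])
        if (kwargs["unit_cost_csv"] is None) != (kwargs["country_config_yaml"] is None):
            raise ConfigurationError(
                "unit_costs requires both 'csv' and 'config' paths (or neither)"
            )
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "country": self.country,
                "cohort_csv": self.cohort_csv,
                "unit_cost_csv": self.unit_cost_csv,
                "country_config_yaml": self.country_config_yaml,
                "discount": [self.discount.annual_rate, self.discount.convention],
                "rules": [
                    self.rules.horizon_years,
                    self.rules.annualization_factor,
                    list(self.rules.nursery_years),
                    list(self.rules.school_years),
                    self.rules.pact_first_period_only,
                ],
                "n_boot": self.n_boot,
                "sa1_changes": list(self.sa1_changes),
                "sa2": [self.sa2_reduction, self.sa2_from_year],
                "sa3": [self.sa3_pact_mean, self.sa3_alternative_mean],
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise PactCostError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def build_model(config: RunConfig) -> CostConsequenceModel:
    """Assemble the model described by *config* (no fitting)."""
    with _stage("load"):
        if config.unit_cost_csv is not None:
            for path in (config.unit_cost_csv, config.country_config_yaml):
                if not Path(path).exists():
                    raise ConfigurationError(f"missing input file: {path}")
            table = UnitCostTable.from_files(
                config.unit_cost_csv, config.country_config_yaml
            )
            recosting: SchoolRecosting | None = (
                datasets.school_recosting(config.country)
                if "primary_school_day" in table.item_category
                else None
            )
        else:
            table = datasets.unit_cost_table(config.country)
            recosting = datasets.school_recosting(config.country)
        if config.cohort_csv is not None:
            if not Path(config.cohort_csv).exists():
                raise ConfigurationError(f"missing cohort file: {config.cohort_csv}")
            records = read_cohort(config.cohort_csv)
        else:
            cohort_config = datasets.country_cohort_config(
                config.country, seed=config.seed
            )
            from .cohort import generate_cohort

            records = generate_cohort(cohort_config)
        return CostConsequenceModel(
            records,
            table,
            rules=config.rules,
            discount=config.discount,
            school_recosting=recosting,
        )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full analysis and write the report bundle to *out_dir*.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = build_model(config)

    with _stage("cost"):
        results = model.fit(n_boot=config.n_boot, seed=config.seed)

    with _stage("sensitivity"):
        sa_grid = unit_cost_scale_grid(model, changes=config.sa1_changes)
        taper = apply_hours_taper(
            model,
            HoursTaperScenario(
                reduction=config.sa2_reduction, applies_from_year=config.sa2_from_year
            ),
        )
        oop_diff, oop_contrast = compare_out_of_pocket(
            OutOfPocketComparison(
                pact_arm_mean=config.sa3_pact_mean,
                alternative_tau_mean=config.sa3_alternative_mean,
            )
        )

    with _stage("report"):
        horizons = results.horizons
        for horizon, stem in zip(horizons, ("mean_costs_13m", "mean_costs_6y")):
            results.mean_cost_table(horizon).to_csv(out / f"{stem}.csv", index=False)
            results.waterfall_table(horizon).to_csv(
                out / f"waterfall_{stem.split('_')[-1]}.csv", index=False
            )
        results.incremental_table().to_csv(out / "incrementals.csv", index=False)
        results.schedule.to_frame(model.discount).to_csv(
            out / "schedule.csv", index=False
        )
        sa_grid.to_csv(out / "sa1_grid.csv", index=False)

        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "country": config.country,
            "results": results.to_dict(),
            "sensitivity": {
                "sa1_rows": sa_grid.to_dict(orient="records"),
                "sa2_hours_taper": {
                    f"{persp}@{horizon}": diff
                    for (persp, horizon), diff in sorted(taper.items())
                },
                "sa3_out_of_pocket": {
                    "pact_arm_mean": config.sa3_pact_mean,
                    "alternative_tau_mean": config.sa3_alternative_mean,
                    "difference": oop_diff,
                    "contrast_percent": oop_contrast,
                },
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        with open(out / "summary.txt", "w") as fh:
            fh.write(results.summary() + "\n")
    return manifest
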