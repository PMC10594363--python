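"""Synthetic two-arm resource-use cohorts.

The original trial's per-child microdata are not deposited, so analyses run on
synthetic cohorts that emulate its structure: 74 intervention and 69 control
children, one quantity per child per cost item over the 13-month follow-up
window, with zero-inflated right-skewed usage distributions (many children
never touch a given service; users are heavily right-skewed).

Quantities are drawn from a zero-inflated gamma: with probability
``zero_prob`` the quantity is 0, otherwise it is gamma-distributed with the
configured conditional mean and shape (``dispersion``; shape 1 gives an
exponential). Intervention delivery is a deterministic per-child item
(quantity fixed at its mean) present only in the intervention arm.

``calibrate_to_means`` rescales item means so the *expected* per-child cost
per (arm, category) matches user-supplied targets exactly — e.g. arm-level
category means printed in a published evaluation — allocating a category
target across its items in proportion to their prior expected costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import CostCategory
from .costing import UnitCostTable
from .errors import CalibrationError, ConfigurationError, ParseError

ARMS = ("intervention", "control")

#: Arm sizes of the trial this generator emulates.
DEFAULT_N_INTERVENTION = 74
DEFAULT_N_CONTROL = 69


def _per_arm(value) -> dict[str, float]:
    """Broadcast a scalar to both arms; pass dicts through (validated)."""
    if isinstance(value, Mapping):
        unknown = set(value) - set(ARMS)
        if unknown:
            raise ConfigurationError(f"unknown arm(s) {sorted(unknown)}")
        return {arm: float(value.get(arm, 0.0)) for arm in ARMS}
    return {arm: float(value) for arm in ARMS}


@dataclass(frozen=True)
class ItemSpec:
    """Distributional spec for one resource-use item.

    ``zero_prob`` and ``mean_quantity`` may be scalars (same in both arms) or
    ``{"intervention": x, "control": y}`` mappings. ``mean_quantity`` is the
    mean *conditional on nonzero use*; ``dispersion`` is the gamma shape
    parameter (1 = exponential). ``deterministic`` items take their mean
    exactly, with no sampling — used for intervention delivery, which is a
    fixed per-child cost.
    """

    item_id: str
    category: CostCategory
    unit: str = "event"  # "event" or "hour"
    zero_prob: Mapping[str, float] | float = 0.0
    mean_quantity: Mapping[str, float] | float = 0.0
    dispersion: float = 1.0
    deterministic: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "zero_prob", _per_arm(self.zero_prob))
        object.__setattr__(self, "mean_quantity", _per_arm(self.mean_quantity))
        if self.unit not in ("event", "hour"):
            raise ConfigurationError(f"item {self.item_id!r}: unit must be event|hour")
        for arm in ARMS:
            if not 0.0 <= self.zero_prob[arm] <= 1.0:
                raise ConfigurationError(f"item {self.item_id!r}: zero_prob outside [0,1]")
            if self.mean_quantity[arm] < 0:
                raise ConfigurationError(f"item {self.item_id!r}: negative mean quantity")
        if self.dispersion <= 0:
            raise ConfigurationError(f"item {self.item_id!r}: dispersion must be positive")

    def expected_quantity(self, arm: str) -> float:
        """Unconditional mean quantity per child in *arm*."""
        return (1.0 - self.zero_prob[arm]) * self.mean_quantity[arm]


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic two-arm cohort."""

    n_intervention: int = DEFAULT_N_INTERVENTION
    n_control: int = DEFAULT_N_CONTROL
    items: Sequence[ItemSpec] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if self.n_intervention < 1 or self.n_control < 1:
            raise ConfigurationError("both arm sizes must be at least 1")
        ids = [it.item_id for it in self.items]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("item ids must be unique")

    def arm_size(self, arm: str) -> int:
        return self.n_intervention if arm == "intervention" else self.n_control


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort: one row per child x item.

    Returns a DataFrame with columns ``child_id, arm, item_id, quantity``.
    Each arm uses an independent random stream derived from the config seed,
    so resizing one arm leaves the other arm's draws untouched. Fully
    reproducible for a fixed (config, seed).
    """
    # child 0 of SeedSequence -> intervention stream, child 1 -> control
    streams = np.random.SeedSequence(config.seed).spawn(2)
    frames = []
    for arm, seq in zip(ARMS, streams):
        rng = np.random.default_rng(seq)
        n = config.arm_size(arm)
        child_ids = [f"{arm[:3]}_{i:04d}" for i in range(n)]
        for item in config.items:
            mu = item.mean_quantity[arm]
            zp = item.zero_prob[arm]
            if item.deterministic:
                q = np.full(n, mu * (1.0 - zp))
            elif mu == 0.0 or zp >= 1.0:
                q = np.zeros(n)
            else:
                nonzero = rng.random(n) >= zp
                shape = item.dispersion
                draws = rng.gamma(shape, mu / shape, size=n)
                q = np.where(nonzero, draws, 0.0)
            frames.append(
                pd.DataFrame(
                    {
                        "child_id": child_ids,
                        "arm": arm,
                        "item_id": item.item_id,
                        "quantity": q,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["child_id", "arm", "item_id", "quantity"])
    return pd.concat(frames, ignore_index=True)


def calibrate_to_means(
    config: CohortConfig,
    target_arm_category_means: Mapping[tuple[str, CostCategory], float],
    unit_costs: UnitCostTable,
) -> CohortConfig:
    """Rescale item means so expected per-child category costs hit targets.

    For each targeted (arm, category), item means are rescaled so that
    ``sum_i (1 - zero_prob_i) * mean_i * price_i`` equals the target exactly.
    The target is allocated across the category's items in proportion to
    their prior expected costs; if all priors are zero the target is split
    equally over items with a positive price and zero_prob < 1.
    """
    new_items = {it.item_id: it for it in config.items}
    for (arm, category), target in target_arm_category_means.items():
        if target < 0:
            raise CalibrationError(f"negative target for ({arm}, {category.value})")
        members = [it for it in config.items if it.category is category]
        if target == 0.0:
            for it in members:
                cur = new_items[it.item_id]
                mq = dict(cur.mean_quantity)
                mq[arm] = 0.0
                new_items[it.item_id] = replace(cur, mean_quantity=mq)
            continue
        priced = [
            it
            for it in members
            if unit_costs.unit_price(it.item_id) > 0 and it.zero_prob[arm] < 1.0
        ]
        if not priced:
            raise CalibrationError(
                f"target {target} for ({arm}, {category.value}) but no item in the "
                "category has a positive unit cost and nonzero use probability"
            )
        prior = {
            it.item_id: new_items[it.item_id].expected_quantity(arm)
            * unit_costs.unit_price(it.item_id)
            for it in priced
        }
        prior_total = sum(prior.values())
        for it in priced:
            share = (
                target * prior[it.item_id] / prior_total
                if prior_total > 0
                else target / len(priced)
            )
            cur = new_items[it.item_id]
            price = unit_costs.unit_price(it.item_id)
            mq = dict(cur.mean_quantity)
            mq[arm] = share / ((1.0 - cur.zero_prob[arm]) * price)
            new_items[it.item_id] = replace(cur, mean_quantity=mq)
        # zero out unpriced members so they cannot perturb the target
        for it in members:
            if it not in priced:
                cur = new_items[it.item_id]
                mq = dict(cur.mean_quantity)
                mq[arm] = 0.0
                new_items[it.item_id] = replace(cur, mean_quantity=mq)
    return replace(config, items=tuple(new_items[it.item_id] for it in config.items))


def expected_category_costs(
    config: CohortConfig, unit_costs: UnitCostTable
) -> dict[tuple[str, CostCategory], float]:
    """Analytic expected per-child cost per (arm, category) under a config."""
    out: dict[tuple[str, CostCategory], float] = {}
    for arm in ARMS:
        for it in config.items:
            key = (arm, it.category)
            out[key] = out.get(key, 0.0) + it.expected_quantity(arm) * unit_costs.unit_price(
                it.item_id
            )
    return out


# ---------------------------------------------------------------------------
# CSV round-trip

COHORT_COLUMNS = ["child_id", "arm", "item_id", "quantity"]


def write_cohort(records: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort to CSV (columns child_id, arm, item_id, quantity)."""
    records[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; errors name the offending row."""
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"cohort CSV missing columns: {sorted(missing)}")
    if df.empty:
        return df[COHORT_COLUMNS]
    bad_arm = ~df["arm"].isin(ARMS)
    if bad_arm.any():
        row = int(df.index[bad_arm][0])
        raise ParseError(f"cohort CSV row {row}: unknown arm {df.loc[row, 'arm']!r}")
    qty = pd.to_numeric(df["quantity"], errors="coerce")
    bad_qty = qty.isna() | (qty < 0)
    if bad_qty.any():
        row = int(df.index[bad_qty][0])
        raise ParseError(
            f"cohort CSV row {row}: invalid quantity {df.loc[row, 'quantity']!r}"
        )
    dup = df.duplicated(subset=["child_id", "item_id"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ParseError(
            f"cohort CSV row {row}: duplicate (child_id, item_id) pair "
            f"({df.loc[row, 'child_id']!r}, {df.loc[row, 'item_id']!r})"
        )
    df = df.assign(quantity=qty)
    return df[COHORT_COLUMNS]
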