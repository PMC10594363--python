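"""Non-parametric bootstrap of incremental costs.

Cost data from trials are heavily right-skewed, so uncertainty around mean
costs is summarised by resampling children with replacement *within each arm
independently* (the child is the unit of independence) and recomputing the
incremental cost on each replicate. Percentile intervals are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import PerspectiveSpec
from .errors import ConfigurationError

DEFAULT_N_REPLICATES = 1000


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate and percentile confidence interval for a cost difference."""

    point_estimate: float
    ci_low: float | None
    ci_high: float | None
    n_replicates: int
    seed: int | None
    ci_level: float = 0.95
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise ConfigurationError("ci_low exceeds ci_high")


def _perspective_totals(per_child_costs: pd.DataFrame, perspective: PerspectiveSpec) -> pd.Series:
    cols = [c.value for c in perspective.categories if c.value in per_child_costs.columns]
    return per_child_costs[cols].sum(axis=1)


def bootstrap_incremental(
    per_child_costs: pd.DataFrame,
    perspective: PerspectiveSpec,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int | None = None,
    ci_level: float = 0.95,
    keep_replicates: bool = False,
) -> BootstrapResult:
    """Bootstrap the incremental cost under *perspective*.

    Parameters
    ----------
    per_child_costs : DataFrame indexed by child with an ``arm`` column and
        one column per cost category (the output of ``costing.cost_records``).
    perspective : which categories to total per child.
    n_replicates : bootstrap replicates; percentile CIs require >= 100.
    seed, ci_level : reproducibility and interval coverage.
    keep_replicates : retain the replicate vector (for diagnostics/tests).

    Returns
    -------
    BootstrapResult. The point estimate is always the incremental computed on
    the original (unresampled) data; CI bounds are ``None`` when fewer than
    100 replicates are requested.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if not 0 < ci_level < 1:
        raise ConfigurationError("ci_level must be in (0, 1)")
    totals = _perspective_totals(per_child_costs, perspective)
    arms = per_child_costs["arm"]
    x_int = totals[arms == "intervention"].to_numpy(dtype=float)
    x_ctl = totals[arms == "control"].to_numpy(dtype=float)
    if len(x_int) == 0 or len(x_ctl) == 0:
        raise ConfigurationError("both arms must contain children")
    want_ci = n_replicates >= 100
    if want_ci and (len(x_int) < 2 or len(x_ctl) < 2):
        raise ConfigurationError(
            "confidence intervals require at least 2 children per arm"
        )
    point = float(x_int.mean() - x_ctl.mean())

    rng = np.random.default_rng(seed)
    # resample within each arm independently: arm labels never mix
    idx_int = rng.integers(0, len(x_int), size=(n_replicates, len(x_int)))
    idx_ctl = rng.integers(0, len(x_ctl), size=(n_replicates, len(x_ctl)))
    reps = x_int[idx_int].mean(axis=1) - x_ctl[idx_ctl].mean(axis=1)

    if want_ci:
        alpha = 1.0 - ci_level
        lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
        ci_low, ci_high = float(lo), float(hi)
    else:
        ci_low = ci_high = None
    return BootstrapResult(
        point_estimate=point,
        ci_low=ci_low,
        ci_high=ci_high,
        n_replicates=n_replicates,
        seed=seed,
        ci_level=ci_level,
        replicates=reps if keep_replicates else None,
    )
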