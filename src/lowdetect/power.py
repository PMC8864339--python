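"""Monte-Carlo power analysis of the LOW assay.

Answers the design question the field assay leaves open: what is the
smallest mosaic-loss fraction f the targeted-sequencing design can
detect? Each replicate simulates a full cohort with loss f planted in
one age group, runs the complete pipeline (counts -> autosomal
correction -> nestling calibration -> pairwise tests), and scores a
detection when the BH-adjusted calibration-vs-affected comparison on the
W marker is significant. Power is the detection rate with a
Clopper–Pearson 95% interval. Grid evaluations share per-replicate
seeds (common random numbers) so monotonicity in f is low-variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .copynum import copy_number_table
from .errors import ParameterError
from .simulate import (
    CALIBRATION_GROUP,
    SimulationParams,
    default_params,
    make_cohort,
    make_reference,
    simulate_counts,
)
from .stats import DEFAULT_ALPHA, compare_groups


@dataclass(frozen=True)
class PowerResult:
    loss_fraction: float
    design: str
    n_reps: int
    alpha: float
    power: float
    ci_low: float
    ci_high: float
    seed: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.power <= self.ci_high:
            raise ParameterError("confidence bounds must bracket the power estimate")


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(sps.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def run_power(
    design: str,
    affected_group: str,
    f: float,
    params: SimulationParams | None = None,
    alpha: float = DEFAULT_ALPHA,
    n_reps: int = 200,
    seed: int = 0,
    calibration_group: str = CALIBRATION_GROUP,
) -> PowerResult:
    """Detection power for mosaic-loss fraction f in one group.

    Detection criterion: BH-adjusted p < alpha for the
    (calibration group, affected group) pairwise comparison on cn_W.
    """
    if not 0.0 <= f <= 1.0:
        raise ParameterError("f must lie in [0, 1]")
    if n_reps < 100:
        raise ParameterError("n_reps must be at least 100")
    if affected_group == calibration_group:
        raise ParameterError("affected group equals calibration group: confounded design")
    if params is None:
        params = default_params(design)
    panel = make_reference(design, seed=seed)

    detections = 0
    for rep in range(n_reps):
        rep_seed = int(np.random.default_rng([seed, rep]).integers(2**31 - 1))
        cohort = make_cohort(design, loss_profile={affected_group: f}, seed=rep_seed)
        rep_params = replace(params, seed=rep_seed)
        counts = simulate_counts(cohort, panel, rep_params)
        table = copy_number_table(counts, cohort, panel, calibration_group=calibration_group)
        report = compare_groups(table["cn_W"], table["group"].to_dict(), alpha=alpha)
        ga, gb = sorted((calibration_group, affected_group))
        row = report[(report["group_a"] == ga) & (report["group_b"] == gb)]
        if row.empty:
            raise ParameterError(f"comparison {ga} vs {gb} missing from report")
        if float(row["p_adj"].iloc[0]) < alpha:
            detections += 1

    power = detections / n_reps
    lo, hi = _clopper_pearson(detections, n_reps)
    return PowerResult(
        loss_fraction=f,
        design=design,
        n_reps=n_reps,
        alpha=alpha,
        power=power,
        ci_low=lo,
        ci_high=hi,
        seed=seed,
    )


def power_curve(
    design: str,
    affected_group: str,
    f_grid: Sequence[float],
    params: SimulationParams | None = None,
    alpha: float = DEFAULT_ALPHA,
    n_reps: int = 200,
    seed: int = 0,
    calibration_group: str = CALIBRATION_GROUP,
) -> list[PowerResult]:
    """run_power over a grid of loss fractions with shared seeds."""
    if len(f_grid) == 0:
        raise ParameterError("f_grid must be non-empty")
    if any(not 0.0 <= f <= 1.0 for f in f_grid):
        raise ParameterError("grid values must lie in [0, 1]")
    return [
        run_power(
            design,
            affected_group,
            float(f),
            params=params,
            alpha=alpha,
            n_reps=n_reps,
            seed=seed,
            calibration_group=calibration_group,
        )
        for f in f_grid
    ]


def curve_to_frame(results: Sequence[PowerResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "f": [r.loss_fraction for r in results],
            "power": [r.power for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "n_reps": [r.n_reps for r in results],
            "alpha": [r.alpha for r in results],
            "design": [r.design for r in results],
        }
    )
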