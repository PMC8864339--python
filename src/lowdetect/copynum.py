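"""Autosomal-corrected coverage and nestling-calibrated copy numbers.

The core normalization: per-sample sequencing depth is removed by the
ratio of each sample's autosomal count to the cross-sample median
autosomal count (every sample carries two autosomal copies, so any
deviation is depth, not biology); corrected W and Z coverages are then
anchored to chromosome-copy units by dividing by the median corrected
coverage of the calibration group — nestlings, which have had no time to
accumulate mosaic loss and carry exactly one W and one Z. After
calibration the calibration-group median is exactly 1 by construction,
and a group mean of 1 - f indicates a mosaic-loss fraction f.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import CountMatrix
from .errors import ParameterError
from .simulate import AUTOSOMAL, CALIBRATION_GROUP, Cohort, ReferencePanel, W, Z

logger = logging.getLogger(__name__)


def autosomal_correct(
    counts: CountMatrix,
    autosomal_locus: str,
    w_locus: str,
    z_locus: str,
    mode: str = "ratio",
) -> pd.DataFrame:
    """Remove per-sample depth using the autosomal marker.

    Returns a DataFrame indexed by sample id with columns ``factor``
    (the sample's autosomal count over the cross-sample median),
    ``corrected_W`` and ``corrected_Z``. Samples with zero autosomal
    counts have an undefined factor and are excluded with a warning.

    ``mode='ratio'`` (default) divides W/Z counts by the factor, which
    cancels multiplicative depth exactly; ``mode='additive'`` subtracts
    the autosomal deviation from the median instead, offered only for
    sensitivity analysis.
    """
    if mode not in ("ratio", "additive"):
        raise ParameterError(f"unknown correction mode {mode!r}")
    for name in (autosomal_locus, w_locus, z_locus):
        if name not in counts.locus_names:
            raise ParameterError(f"locus {name!r} absent from count matrix")
    if len(counts.sample_ids) < 2:
        raise ParameterError("need at least two samples to define a median")

    df = counts.df
    a = df[autosomal_locus].astype(float)
    usable = a > 0
    dropped = list(df.index[~usable])
    if dropped:
        logger.warning("excluding %d sample(s) with zero autosomal counts: %s", len(dropped), dropped)
    a = a[usable]
    med = float(np.median(a))
    factor = a / med
    if mode == "ratio":
        corrected_w = df.loc[usable, w_locus] / factor
        corrected_z = df.loc[usable, z_locus] / factor
    else:
        corrected_w = df.loc[usable, w_locus] - (a - med)
        corrected_z = df.loc[usable, z_locus] - (a - med)
    return pd.DataFrame(
        {"factor": factor, "corrected_W": corrected_w, "corrected_Z": corrected_z}
    )


def calibrate(
    norm: pd.DataFrame,
    groups: Mapping[str, str],
    marker: str,
    calibration_group: str = CALIBRATION_GROUP,
) -> pd.Series:
    """Convert corrected coverage to chromosome copies.

    Divides ``corrected_<marker>`` by the median corrected coverage over
    the calibration group, whose members carry exactly one copy; the
    calibration-group median of the result is exactly 1.
    """
    if marker not in ("W", "Z"):
        raise ParameterError("marker must be 'W' or 'Z'")
    col = norm[f"corrected_{marker}"]
    anchor_ids = [sid for sid in col.index if groups.get(sid) == calibration_group]
    if not anchor_ids:
        raise ParameterError(
            f"calibration group {calibration_group!r} empty among samples with defined coverage"
        )
    anchor = float(np.median(col.loc[anchor_ids]))
    if anchor <= 0:
        raise ParameterError("calibration-group median coverage must be positive")
    cn = col / anchor
    cn.name = f"cn_{marker}"
    return cn


def copy_number_table(
    counts: CountMatrix,
    cohort: Cohort,
    panel: ReferencePanel,
    calibration_group: str = CALIBRATION_GROUP,
    mode: str = "ratio",
) -> pd.DataFrame:
    """End-to-end normalization: counts -> corrected coverage -> copy number.

    Convenience wrapper returning sample_id-indexed columns: group,
    age_years, factor, corrected_W, corrected_Z, cn_W, cn_Z.
    """
    norm = autosomal_correct(
        counts,
        panel.by_class(AUTOSOMAL).name,
        panel.by_class(W).name,
        panel.by_class(Z).name,
        mode=mode,
    )
    groups = cohort.groups()
    ages = cohort.ages()
    out = norm.copy()
    out.insert(0, "group", [groups[sid] for sid in out.index])
    out.insert(1, "age_years", [ages[sid] for sid in out.index])
    out["cn_W"] = calibrate(norm, groups, "W", calibration_group)
    out["cn_Z"] = calibrate(norm, groups, "Z", calibration_group)
    out.attrs["calibration_group"] = calibration_group
    return out


@dataclass(frozen=True)
class LossEstimate:
    """Group mosaic-loss fraction with a bootstrap percentile interval."""

    f_hat: float
    ci_low: float
    ci_high: float
    n_boot: int
    group: str


def estimate_loss(
    table: pd.DataFrame,
    group: str,
    marker: str = "W",
    calibration_group: str | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> LossEstimate:
    """Invert the copy-number model: f = max(0, 1 - mean copy number).

    ``table`` is a copy-number table (see :func:`copy_number_table`).
    The bootstrap resamples the target group and the calibration group
    jointly, re-deriving the calibration median per resample, so the
    interval reflects the shared uncertainty of the one-copy anchor as
    well as the group's sampling noise.
    """
    if calibration_group is None:
        calibration_group = table.attrs.get("calibration_group", CALIBRATION_GROUP)
    cn = table[f"cn_{marker}"]
    target = cn[table["group"] == group].to_numpy(float)
    anchor = cn[table["group"] == calibration_group].to_numpy(float)
    if target.size == 0:
        raise ParameterError(f"group {group!r} is empty")
    if anchor.size == 0:
        raise ParameterError(f"calibration group {calibration_group!r} is empty")

    f_hat = float(np.clip(1.0 - target.mean(), 0.0, 1.0))
    rng = np.random.default_rng([seed, 0xB007])
    reps = np.empty(n_boot)
    for b in range(n_boot):
        t = rng.choice(target, size=target.size, replace=True)
        a = rng.choice(anchor, size=anchor.size, replace=True)
        med = np.median(a)
        if med <= 0:
            reps[b] = 1.0
            continue
        reps[b] = np.clip(1.0 - t.mean() / med, 0.0, 1.0)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return LossEstimate(f_hat=f_hat, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot, group=group)
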