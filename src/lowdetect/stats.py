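"""Group-wise inference on copy numbers.

Pairwise Mann–Whitney U tests across age groups with Benjamini–Hochberg
correction, and a linear age trend (OLS of copy number on age) with
1.5x-IQR outlier exclusion. A significant deficit of W copy number in
older groups, or a negative age slope, would indicate age-related mosaic
loss of the W chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

DEFAULT_ALPHA = 0.05

#: exact enumeration is used when the smaller sample is at most this size
EXACT_MAX_N = 8


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test of x vs y.

    Returns the rank-sum statistic U (for x, midranks on ties) and the
    two-sided p-value: exact by enumeration of rank assignments when
    min(n_x, n_y) <= 8 and there are no ties, otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in p_adj]


def compare_groups(
    cn: pd.Series,
    groups: Mapping[str, str],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """All pairwise group comparisons with BH correction across the family.

    ``cn`` is indexed by sample id; ``groups`` maps sample id to group
    label. Returns one row per unordered pair, sorted by (group_a,
    group_b), with columns U, p_raw, p_adj and significant (p_adj < alpha).
    """
    labels = pd.Series({sid: groups[sid] for sid in cn.index})
    by_group = {g: cn[labels == g].to_numpy(float) for g in sorted(labels.unique())}
    if len(by_group) < 2:
        raise ParameterError("need at least two groups")
    for g, vals in by_group.items():
        if vals.size == 0:
            raise ParameterError(f"group {g!r} is empty")

    rows = []
    for ga, gb in combinations(sorted(by_group), 2):
        u, p = mann_whitney(by_group[ga], by_group[gb])
        rows.append({"group_a": ga, "group_b": gb, "U": u, "p_raw": p})
    report = pd.DataFrame(rows)
    report["p_adj"] = bh_adjust(report["p_raw"].tolist())
    report["significant"] = report["p_adj"] < alpha
    return report.sort_values(["group_a", "group_b"], ignore_index=True)


@dataclass(frozen=True)
class TrendResult:
    """OLS age trend of copy number, after outlier exclusion."""

    slope: float  # copy-number units per year
    intercept: float
    p_slope: float
    n_used: int
    outlier_ids: tuple[str, ...]


def iqr_outliers(values: pd.Series) -> list[str]:
    """Ids outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of the values."""
    q1, q3 = np.percentile(values.to_numpy(float), [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return [str(i) for i in values.index[(values < lo) | (values > hi)]]


def age_trend(
    cn: pd.Series,
    ages: Mapping[str, float] | Sequence[float],
    outlier_rule: str = "iqr",
) -> TrendResult:
    """Linear model of copy number on age, excluding response outliers.

    Outliers are flagged on the copy numbers by the 1.5x-IQR rule (or not
    at all with ``outlier_rule='none'``); the slope p-value is the
    two-sided t-test. A zero-variance response yields slope 0 with p = 1.
    """
    if outlier_rule not in ("iqr", "none"):
        raise ParameterError(f"unknown outlier rule {outlier_rule!r}")
    if isinstance(ages, Mapping):
        age_vec = pd.Series({sid: ages[sid] for sid in cn.index})
    else:
        age_vec = pd.Series(list(ages), index=cn.index)

    outliers = iqr_outliers(cn) if outlier_rule == "iqr" else []
    keep = cn.index.difference(pd.Index(outliers))
    if len(keep) < 3:
        raise ParameterError("fewer than 3 samples remain after outlier exclusion")
    yv = cn.loc[keep].to_numpy(float)
    xv = age_vec.loc[keep].to_numpy(float)
    if np.allclose(yv, yv[0]):
        return TrendResult(0.0, float(yv[0]), 1.0, len(keep), tuple(outliers))
    fit = sps.linregress(xv, yv)
    p = 1.0 if np.isnan(fit.pvalue) else float(fit.pvalue)
    return TrendResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_slope=p,
        n_used=len(keep),
        outlier_ids=tuple(outliers),
    )


@dataclass(frozen=True)
class TestReport:
    """Pairwise group tests plus the age trend for one marker."""

    pairwise: pd.DataFrame
    trend: TrendResult | None
    alpha: float = DEFAULT_ALPHA

    @property
    def n_significant(self) -> int:
        return int(self.pairwise["significant"].sum())


def test_marker(
    table: pd.DataFrame,
    marker: str = "W",
    alpha: float = DEFAULT_ALPHA,
    outlier_rule: str = "iqr",
) -> TestReport:
    """Full inference for one marker from a copy-number table."""
    cn = table[f"cn_{marker}"]
    groups = table["group"].to_dict()
    pairwise = compare_groups(cn, groups, alpha=alpha)
    trend = age_trend(cn, table["age_years"].to_dict(), outlier_rule=outlier_rule)
    return TestReport(pairwise=pairwise, trend=trend, alpha=alpha)
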