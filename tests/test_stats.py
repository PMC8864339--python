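"""Rank tests, BH correction and the age trend, against hand oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lowdetect.errors import ParameterError
from lowdetect.stats import (
    age_trend,
    bh_adjust,
    compare_groups,
    iqr_outliers,
    mann_whitney,
)


def enumerate_mwu_p(x, y):
    """Independent exact oracle: U and two-sided p by full enumeration of
    all C(n+m, n) assignments of the pooled values to the x sample."""
    pooled = sorted(x) + sorted(y)
    n = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
        1 for xi in x for yi in y if xi == yi
    )
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(
            sum(1 for xi in xs for yi in ys if xi > yi)
            + 0.5 * sum(1 for xi in xs for yi in ys if xi == yi)
        )
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(p_low, p_high))


def bh_stepup_by_hand(p):
    """Independent step-up oracle: sort, scale by m/i, enforce
    monotonicity from the top, cap at 1, restore input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    scaled = [p[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = min(1.0, scaled[rank])
    return out


class TestMannWhitney:
    def test_separated_pairs_full_enumeration(self):
        # C(4,2) = 6 assignments; U = 0 sits in a tail of mass 1/6
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_branch_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 7, size=2)
        x = rng.permutation(np.arange(1.0, nx + ny + 1))[:nx]
        y = np.setdiff1d(np.arange(1.0, nx + ny + 1), x)
        u_exp, p_exp = enumerate_mwu_p(list(x), list(y))
        u, p = mann_whitney(x, y)
        assert u == pytest.approx(u_exp)
        assert p == pytest.approx(p_exp)

    def test_exact_and_asymptotic_branches_agree(self):
        # tie-free 8x8 samples: the normal approximation with continuity
        # correction tracks the exact p closely; the correction itself
        # can shift mid-range p by ~0.01, hence the 0.02 bound
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(7)
        for _ in range(20):
            pooled = rng.permutation(np.arange(16.0)) + rng.random(16) * 0.01
            x, y = pooled[:8], pooled[8:]
            p_exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            p_approx = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(p_exact - p_approx) <= 0.02

    def test_rejection_rate_matches_reference_implementation(self):
        # location shift of 1 SD at n = 19 vs 13: rejection rates of our
        # branching rule and the published reference implementation agree
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(11)
        ours = ref = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(0, 1, size=19)
            y = rng.normal(1, 1, size=13)
            _, p = mann_whitney(x, y)
            ours += p < 0.05
            ref += mannwhitneyu(x, y, alternative="two-sided").pvalue < 0.05
        assert abs(ours - ref) / reps <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney([], [1.0])


class TestBHAdjust:
    def test_hand_applied_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]

    def test_all_ones_stay_capped(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    def test_matches_hand_stepup_and_dominates_raw(self, p):
        adj = bh_adjust(p)
        assert adj == pytest.approx(bh_stepup_by_hand(p))
        assert all(a >= r for a, r in zip(adj, p))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=10),
           st.randoms(use_true_random=False))
    def test_order_invariance(self, p, rnd):
        idx = list(range(len(p)))
        rnd.shuffle(idx)
        shuffled = [p[i] for i in idx]
        adj_shuffled = bh_adjust(shuffled)
        adj = bh_adjust(p)
        assert [adj[i] for i in idx] == pytest.approx(adj_shuffled)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.5])


class TestCompareGroups:
    def _cn(self, values, groups):
        ids = [f"s{i}" for i in range(len(values))]
        return pd.Series(values, index=ids), dict(zip(ids, groups))

    def test_four_groups_give_six_comparisons(self):
        rng = np.random.default_rng(3)
        cn, groups = self._cn(
            rng.normal(1, 0.1, 40),
            ["nestling"] * 10 + ["young"] * 10 + ["middle"] * 10 + ["old"] * 10,
        )
        report = compare_groups(cn, groups)
        assert len(report) == 6
        assert (report.p_adj >= report.p_raw - 1e-12).all()

    def test_two_groups_bh_is_identity(self):
        rng = np.random.default_rng(4)
        cn, groups = self._cn(rng.normal(1, 0.1, 20), ["nestling"] * 12 + ["adult"] * 8)
        report = compare_groups(cn, groups)
        assert len(report) == 1
        assert report.p_adj.iloc[0] == report.p_raw.iloc[0]

    def test_report_sorted_by_group_pair(self):
        rng = np.random.default_rng(5)
        cn, groups = self._cn(rng.normal(1, 0.1, 30),
                              ["c"] * 10 + ["a"] * 10 + ["b"] * 10)
        report = compare_groups(cn, groups)
        pairs = list(zip(report.group_a, report.group_b))
        assert pairs == sorted(pairs)

    def test_single_group_rejected(self):
        cn, groups = self._cn([1.0, 1.1], ["a", "a"])
        with pytest.raises(ParameterError):
            compare_groups(cn, groups)


class TestAgeTrend:
    def test_constant_response_degenerates_cleanly(self):
        cn = pd.Series([1.0] * 6, index=[f"s{i}" for i in range(6)])
        res = age_trend(cn, dict(zip(cn.index, [0, 2, 4, 8, 12, 16])), outlier_rule="none")
        assert res.slope == 0.0
        assert res.p_slope == 1.0

    def test_hand_computed_ols_slope(self):
        # (age, cn) = (0, 1), (5, 0.9), (10, 0.8): closed-form OLS slope
        # = cov/var = -0.02 per year
        cn = pd.Series([1.0, 0.9, 0.8], index=["a", "b", "c"])
        res = age_trend(cn, {"a": 0.0, "b": 5.0, "c": 10.0}, outlier_rule="none")
        assert res.slope == pytest.approx(-0.02)
        assert res.intercept == pytest.approx(1.0)

    def test_iqr_rule_flags_planted_outlier(self):
        rng = np.random.default_rng(8)
        values = list(rng.normal(1.0, 0.02, 19)) + [3.0]
        cn = pd.Series(values, index=[f"s{i}" for i in range(20)])
        ages = dict(zip(cn.index, np.linspace(0, 18, 20)))
        res = age_trend(cn, ages, outlier_rule="iqr")
        assert res.outlier_ids == ("s19",)
        assert res.n_used == 19

    def test_too_few_points_rejected(self):
        cn = pd.Series([1.0, 0.9], index=["a", "b"])
        with pytest.raises(ParameterError):
            age_trend(cn, {"a": 0.0, "b": 5.0}, outlier_rule="none")

    def test_planted_decline_detected_with_power(self, booby_panel):
        # loss rising linearly to 0.3 at age 18 at field depths: the
        # negative age slope reaches p < 0.05 in most replicates
        from lowdetect.copynum import copy_number_table
        from lowdetect.simulate import Cohort, Sample, default_params, make_cohort, simulate_counts
        from dataclasses import replace

        detected = 0
        reps = 60
        for rep in range(reps):
            base = make_cohort("booby", seed=900 + rep)
            samples = tuple(
                Sample(
                    id=s.id, species=s.species, sex=s.sex, age_years=s.age_years,
                    group=s.group, loss_fraction=0.3 * s.age_years / 18.0,
                )
                for s in base.samples
            )
            cohort = Cohort(samples=samples, design="booby")
            counts = simulate_counts(cohort, booby_panel, default_params("booby", seed=950 + rep))
            table = copy_number_table(counts, cohort, booby_panel)
            res = age_trend(table["cn_W"], table["age_years"].to_dict())
            detected += res.slope < 0 and res.p_slope < 0.05
        assert detected / reps >= 0.8

    def test_iqr_outliers_helper_matches_definition(self):
        s = pd.Series([1, 2, 3, 4, 100.0], index=list("abcde"))
        assert iqr_outliers(s) == ["e"]
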