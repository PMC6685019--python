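import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from epiclone.stats import (
    IncompleteMomentCurve,
    average_curves,
    constrained_lfim_r2,
    dnds_ratio,
    first_incomplete_moment,
    lfim_tail_deviation,
    rank_sum_one_sided,
    roc_auc,
    size_interval_composition,
)

# ---------------------------------------------------------------------------
# independent oracles


def oracle_mu1(sizes, n):
    """Direct double summation of the first incomplete moment."""
    sizes = list(sizes)
    total = sum(m * sizes.count(m) for m in set(sizes))
    tail = sum(m * sizes.count(m) for m in set(sizes) if m >= n)
    return tail / total


def oracle_constrained_fit(sizes):
    """Normal-equation solution of the anchored straight-line fit, written
    independently of the implementation (explicit loops)."""
    curve = first_incomplete_moment(sizes)
    xs = [n - curve.m for n in curve.n]
    ys = [np.log(v) for v in curve.mu1]
    slope = sum(x * y for x, y in zip(xs, ys)) / sum(x * x for x in xs)
    ybar = sum(ys) / len(ys)
    ss_res = sum((y - slope * x) ** 2 for x, y in zip(xs, ys))
    ss_tot = sum((y - ybar) ** 2 for y in ys)
    return slope, 1 - ss_res / ss_tot


def oracle_auc(scores0, scores1):
    """All-pairs counting with lower scores voting for class 1; ties half."""
    wins = 0.0
    for a in scores0:
        for b in scores1:
            if b < a:
                wins += 1.0
            elif b == a:
                wins += 0.5
    return wins / (len(scores0) * len(scores1))


def oracle_exact_mw_p(a, b):
    """Exact one-sided Mann-Whitney p by full enumeration of group
    assignments of the pooled values."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += (x > y) + 0.5 * (x == y)
        return u

    observed = u_stat(a, b)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        count += u_stat(ga, gb) >= observed
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# first incomplete moment


class TestFirstIncompleteMoment:
    def test_sizes_1_2_3(self):
        curve = first_incomplete_moment([1, 2, 3])
        assert curve.n.tolist() == [1, 2, 3]
        assert curve.mu1 == pytest.approx([1.0, 5 / 6, 0.5])
        assert curve.m == 1

    def test_single_atom_is_flat_one(self):
        curve = first_incomplete_moment([4, 4, 4])
        assert curve.n.tolist() == [4]
        assert curve.mu1.tolist() == [1.0]

    def test_empty_and_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            first_incomplete_moment([])
        with pytest.raises(ValueError):
            first_incomplete_moment([0, 2])

    @given(hst.lists(hst.integers(1, 500), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_direct_summation_and_is_monotone(self, sizes):
        curve = first_incomplete_moment(sizes)
        assert curve.mu1[0] == pytest.approx(1.0)
        assert np.all(np.diff(curve.mu1) <= 1e-12)
        assert np.all(curve.mu1 > 0)
        for n, v in zip(curve.n, curve.mu1):
            assert v == pytest.approx(oracle_mu1(sizes, n))

    @given(hst.lists(hst.integers(1, 100), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_duplicating_the_multiset_leaves_curve_unchanged(self, sizes):
        c1 = first_incomplete_moment(sizes)
        c2 = first_incomplete_moment(sizes + sizes)
        assert c1.n.tolist() == c2.n.tolist()
        assert c1.mu1 == pytest.approx(c2.mu1)

    def test_step_evaluation_between_support_points(self):
        curve = first_incomplete_moment([1, 2, 4])
        assert curve.at(np.array([0.5, 1.0, 3.0, 4.0, 9.0])) == pytest.approx(
            [1.0, 1.0, curve.mu1[1], curve.mu1[2], 0.0]
        )


# ---------------------------------------------------------------------------
# constrained straight-line fit


class TestConstrainedFit:
    def test_two_distinct_sizes_fit_exactly(self):
        fit = constrained_lfim_r2([2, 2, 5])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.m == 2

    def test_exactly_exponential_curve_fits_with_r2_one(self):
        # counts chosen so the size-weighted tail halves at each support
        # point: mu1 = (1, 1/2, 1/4), exactly linear in log space
        sizes = [1] * 12 + [2] * 3 + [3] * 2
        curve = first_incomplete_moment(sizes)
        assert curve.mu1 == pytest.approx([1.0, 0.5, 0.25])
        assert constrained_lfim_r2(sizes).r2 == pytest.approx(1.0)

    def test_single_distinct_size_rejected(self):
        with pytest.raises(ValueError):
            constrained_lfim_r2([3, 3, 3])

    @given(hst.lists(hst.integers(1, 200), min_size=2, max_size=80).filter(
        lambda s: len(set(s)) >= 2))
    @settings(deadline=None, max_examples=80, derandomize=True)
    def test_matches_normal_equation_oracle(self, sizes):
        fit = constrained_lfim_r2(sizes)
        slope, r2 = oracle_constrained_fit(sizes)
        assert fit.slope == pytest.approx(slope)
        assert fit.r2 == pytest.approx(r2)

    def test_r2_can_be_negative_for_kinked_curves(self):
        # steep initial drop followed by a long flat stretch: the anchored
        # line fits worse than the horizontal mean, so R² goes negative
        sizes = [1] * 500 + list(range(2, 30)) + [2000] * 2
        assert constrained_lfim_r2(sizes).r2 < 0

    def test_smallest_75pct_restriction_ignores_the_tail(self):
        bulk = [1] * 30 + [2] * 15 + [3] * 8 + [4] * 4 + [5] * 2
        tail = [400, 500]
        full = constrained_lfim_r2(bulk + tail)
        partial = constrained_lfim_r2(bulk + tail, fraction_used=0.75)
        assert partial.n_points < full.n_points
        assert partial.r2 > full.r2  # the bulk alone is nearly exponential

    def test_geometric_sizes_give_nearly_straight_lfim(self):
        """Neutral-theory shape: i.i.d. geometric clone sizes have an
        exponential size distribution, hence a straight-line LFIM."""
        rng = np.random.default_rng(11)
        r2s = [
            constrained_lfim_r2(rng.geometric(0.2, size=400)).r2 for _ in range(20)
        ]
        assert np.median(r2s) > 0.9


def test_tail_deviation_grows_with_an_emerging_second_mode():
    bulk = [1] * 12 + [2] * 3 + [3] * 2  # exactly exponential: deviation 0
    assert lfim_tail_deviation(bulk, fraction_used=0.75) == pytest.approx(0.0)
    assert lfim_tail_deviation(bulk + [50] * 3, fraction_used=0.75) > 1.0
    with pytest.raises(ValueError):
        lfim_tail_deviation([5, 5, 5], min_size=4)


# ---------------------------------------------------------------------------
# curve averaging


class TestAverageCurves:
    def test_single_and_identical_curves_are_identity(self):
        c = first_incomplete_moment([1, 2, 5])
        avg = average_curves([c, c])
        assert avg.n.tolist() == c.n.tolist()
        assert avg.mu1 == pytest.approx(c.mu1)

    def test_two_hand_built_curves_average_pointwise(self):
        c1 = IncompleteMomentCurve(n=np.array([1.0, 3.0]), mu1=np.array([1.0, 0.4]), m=1)
        c2 = IncompleteMomentCurve(n=np.array([2.0, 4.0]), mu1=np.array([1.0, 0.2]), m=2)
        avg = average_curves([c1, c2])
        assert avg.n.tolist() == [1.0, 2.0, 3.0, 4.0]
        # c1 at grid: 1, 1, .4, .4(<=max support 3? beyond -> 0) ; c2: 1, 1, 1, .2
        assert avg.mu1 == pytest.approx([1.0, 1.0, 0.7, (0.0 + 0.2) / 2])


# ---------------------------------------------------------------------------
# dN/dS


class TestDnds:
    def test_known_ratio_examples(self):
        assert dnds_ratio(10, 30, 1 / 3) == pytest.approx(1.0)
        assert dnds_ratio(6, 2, 1.0) == pytest.approx(3.0)
        assert dnds_ratio(0, 5, 0.5) == 0.0

    def test_no_neutral_clones_or_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            dnds_ratio(3, 0, 1.0)
        with pytest.raises(ValueError):
            dnds_ratio(3, 3, 0.0)

    def test_random_labelling_calibrates_to_one(self):
        """Labels assigned at random with intake ratio a give dN/dS ~ 1."""
        rng = np.random.default_rng(2024)
        a = 1 / 3
        n_clones = 40_000
        labels = rng.random(n_clones) < a / (1 + a)
        n, s = int(labels.sum()), int((~labels).sum())
        assert dnds_ratio(n, s, a) == pytest.approx(1.0, abs=0.03)


# ---------------------------------------------------------------------------
# ROC / AUC


class TestRocAuc:
    def test_perfect_separation_and_identical_distributions(self):
        assert roc_auc([0.9, 0.8], [0.1, 0.2]).auc == pytest.approx(1.0)
        x = [0.3, 0.5, 0.7]
        assert roc_auc(x, list(x)).auc == pytest.approx(0.5)

    def test_small_list_example_with_ties(self):
        res = roc_auc([0.9, 0.8], [0.7, 0.85])
        assert res.auc == pytest.approx(oracle_auc([0.9, 0.8], [0.7, 0.85]))

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(1)
        res = roc_auc(rng.normal(1, 1, 50), rng.normal(0, 1, 50))
        assert np.all(np.diff(res.fpr) >= 0)
        assert np.all(np.diff(res.tpr) >= 0)

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            n0, n1 = rng.integers(1, 9, size=2)
            # coarse grid to force ties
            s0 = rng.integers(0, 5, size=n0) / 4
            s1 = rng.integers(0, 5, size=n1) / 4
            got = roc_auc(s0, s1).auc
            assert got == pytest.approx(oracle_auc(s0, s1)), (s0, s1)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])


# ---------------------------------------------------------------------------
# rank-sum test


class TestRankSum:
    def test_maximal_separation_exact_p(self):
        # U is maximal; p = 1 / C(5,2) = 0.1 by full enumeration
        assert rank_sum_one_sided([3, 4, 5], [1, 2]) == pytest.approx(0.1)

    def test_identical_multisets_give_p_about_half(self):
        a = [1, 2, 3, 4, 5, 6, 7, 8]
        assert rank_sum_one_sided(a, list(a)) == pytest.approx(0.5, abs=0.1)

    def test_matches_enumeration_oracle_on_small_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n_a = int(rng.integers(2, 5))
            n_b = int(rng.integers(2, 5))
            # continuous values: no ties, scipy uses the exact distribution
            a = rng.normal(0.5, 1, n_a)
            b = rng.normal(0.0, 1, n_b)
            assert rank_sum_one_sided(a, b) == pytest.approx(
                oracle_exact_mw_p(a, b)
            ), (a, b)

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(3)
        b = rng.normal(0, 1, 200)
        ps = [rank_sum_one_sided(b + shift, b) for shift in (0.2, 0.6, 1.2)]
        assert ps[0] > ps[1] > ps[2]


# ---------------------------------------------------------------------------
# size-interval composition


class TestSizeIntervalComposition:
    @staticmethod
    def _table(sizes, labels):
        import pandas as pd

        return pd.DataFrame({"size_cells": sizes, "label": labels})

    def test_all_neutral_and_all_non_neutral(self):
        t = self._table([1, 5, 20], ["neutral"] * 3)
        out = size_interval_composition(t, [1, 10, 100])
        assert out["non_neutral_fraction"].tolist() == [0.0, 0.0]
        t2 = self._table([1, 5, 20], ["non_neutral"] * 3)
        out2 = size_interval_composition(t2, [1, 10, 100])
        assert out2["non_neutral_fraction"].tolist() == [1.0, 1.0]

    def test_hand_built_fractions_and_empty_interval(self):
        t = self._table(
            [1, 2, 3, 15, 20, 200],
            ["neutral", "non_neutral", "neutral", "non_neutral", "non_neutral", "neutral"],
        )
        out = size_interval_composition(t, [1, 10, 100, 1000])
        assert out["non_neutral_fraction"].iloc[0] == pytest.approx(1 / 3)
        assert out["non_neutral_fraction"].iloc[1] == pytest.approx(1.0)
        assert out["non_neutral_fraction"].iloc[2] == pytest.approx(0.0)
        empty = size_interval_composition(t, [500, 1000])
        assert np.isnan(empty["non_neutral_fraction"].iloc[0])
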