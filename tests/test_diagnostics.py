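"""Tests for ROC/AUC, Youden, confusion metrics, rank tests and ICC.

The AUC and Youden implementations are checked against brute-force
oracles (O(n^2) pair counting, exhaustive threshold scans) and against
independent libraries (scikit-learn for the AUC, pingouin for ICC(1)).
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lsvar import (
    ConfusionMatrix,
    auc_ci95,
    bootstrap_auc_ci95,
    confusion_at_cutoff,
    empirical_roc,
    fisher_exact,
    icc_oneway,
    mann_whitney_u,
    round_half_up_pct,
    sensitivity_pct,
    specificity_pct,
    youden_cutoff,
)
from lsvar.diagnostics import icc_band
from lsvar.exceptions import (
    DegenerateRocError,
    UndefinedIccError,
    UndefinedMetricError,
    UndefinedVarianceError,
)
from conftest import random_roc_instance


def auc_brute_force(scores, labels):
    """O(n^2) pair-counting oracle: ties count one half."""
    s = np.asarray(scores, float)
    pos, neg = s[np.asarray(labels, bool)], s[~np.asarray(labels, bool)]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_brute_force(scores, labels):
    """Exhaustive scan over observed thresholds; smallest wins ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    best_t, best_j = None, -np.inf
    for t in np.unique(s):
        cm = confusion_at_cutoff(s, y, t)
        j = cm.tp / (cm.tp + cm.fn) + cm.tn / (cm.tn + cm.fp) - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = t, j
    return best_t, best_j


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        roc = empirical_roc([2, 3, 0, 1], [True, True, False, False])
        assert roc.auc == 1.0

    def test_all_ties_give_half(self):
        roc = empirical_roc([5.0] * 6, [True, False] * 3)
        assert roc.auc == 0.5

    def test_hand_counted_pairs(self):
        # positives {3,5}, negatives {1,4}: 3 of 4 pairs concordant
        roc = empirical_roc([3, 5, 1, 4], [True, True, False, False])
        assert roc.auc == 0.75

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateRocError):
            empirical_roc([1, 2], [True, True])

    def test_curve_monotone_in_threshold(self, default_panels, default_labels):
        roc = empirical_roc([p.lsvar for p in default_panels], default_labels)
        assert np.all(np.diff(roc.sensitivity) <= 0)
        assert np.all(np.diff(roc.specificity) >= 0)
        assert roc.auc_ci95[0] <= roc.auc <= roc.auc_ci95[1]

    def test_matches_brute_force_and_sklearn_on_random_instances(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(123)
        for _ in range(100):
            scores, labels = random_roc_instance(rng)
            auc = empirical_roc(scores, labels).auc
            assert abs(auc - auc_brute_force(scores, labels)) <= 1e-12
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            scores, labels = random_roc_instance(rng)
            a = empirical_roc(scores, labels).auc
            b = empirical_roc(scores, ~labels).auc
            assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(99)
        scores, labels = random_roc_instance(rng)
        base = empirical_roc(scores, labels)
        transformed = empirical_roc(np.exp(scores / 3.0), labels)
        assert transformed.auc == pytest.approx(base.auc, abs=1e-12)
        assert transformed.youden_j == pytest.approx(base.youden_j, abs=1e-12)


class TestYouden:
    def test_tie_broken_toward_smallest_threshold(self):
        # J = 0.5 attained at cutoffs 3 and 5; the smaller wins
        roc = empirical_roc([3, 5, 1, 4], [True, True, False, False])
        t, j = youden_cutoff(roc)
        assert (t, j) == (3.0, pytest.approx(0.5))

    def test_perfect_separation_cutoff(self):
        roc = empirical_roc([2, 3, 0, 1], [True, True, False, False])
        t, j = youden_cutoff(roc)
        assert (t, j) == (2.0, 1.0)

    def test_degenerate_ties_only(self):
        roc = empirical_roc([5.0] * 4, [True, False, True, False])
        _, j = youden_cutoff(roc)
        assert j == 0.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(321)
        for _ in range(100):
            scores, labels = random_roc_instance(rng)
            roc = empirical_roc(scores, labels)
            t, j = youden_cutoff(roc)
            t_ref, j_ref = youden_brute_force(scores, labels)
            assert j == pytest.approx(j_ref, abs=1e-12)
            assert t == t_ref


class TestDelongCI:
    def test_perfect_separation_clips_to_one(self):
        pos = np.linspace(10, 11, 50)
        neg = np.linspace(0, 1, 50)
        lo, hi = auc_ci95(np.r_[pos, neg], np.r_[[True] * 50, [False] * 50])
        assert hi == 1.0

    def test_symmetric_about_half_for_identical_groups(self):
        s = np.array([1.0, 2, 3, 1, 2, 3])
        y = np.array([True] * 3 + [False] * 3)
        lo, hi = auc_ci95(s, y)
        assert (lo + hi) / 2 == pytest.approx(0.5, abs=1e-9)

    def test_two_per_class_gives_ordered_interval(self):
        lo, hi = auc_ci95([1, 3, 2, 4], [True, True, False, False])
        assert lo <= 0.75 <= hi

    def test_fewer_than_two_per_class_rejected(self):
        with pytest.raises(UndefinedVarianceError):
            auc_ci95([1, 2, 3], [True, False, False])

    def test_frozen_cross_check_against_pROC(self):
        """Value frozen from R pROC ci.auc(..., method='delong')."""
        rng = np.random.default_rng(42)
        neg = rng.normal(0, 1, 60)
        pos = rng.normal(1.2, 1, 25)
        s = np.concatenate([neg, pos])
        y = np.array([False] * 60 + [True] * 25)
        lo, hi = auc_ci95(s, y)
        assert empirical_roc(s, y).auc == pytest.approx(0.814, abs=1e-9)
        assert lo == pytest.approx(0.7139, abs=5e-5)
        assert hi == pytest.approx(0.9141, abs=5e-5)

    def test_bootstrap_interval_brackets_auc(self):
        rng = np.random.default_rng(0)
        neg = rng.normal(0, 1, 40)
        pos = rng.normal(1, 1, 20)
        s, y = np.r_[neg, pos], np.r_[[False] * 40, [True] * 20]
        lo, hi = bootstrap_auc_ci95(s, y, n_boot=500, seed=1)
        auc = empirical_roc(s, y).auc
        assert lo <= auc <= hi
        # seedable and deterministic
        assert bootstrap_auc_ci95(s, y, n_boot=500, seed=1) == (lo, hi)


class TestConfusionMetrics:
    def test_example_patient_pair(self):
        cm = confusion_at_cutoff([0.8, 0.22], [True, False], 0.67)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)
        assert sensitivity_pct(cm) == 100.0 and specificity_pct(cm) == 100.0

    def test_cutoff_below_all_scores(self):
        cm = confusion_at_cutoff([1, 2, 3], [True, False, True], 0.0)
        assert cm.fn == 0 and cm.tn == 0

    def test_cutoff_above_all_scores(self):
        cm = confusion_at_cutoff([1, 2, 3], [True, False, True], 10.0)
        assert cm.tp == 0 and cm.fp == 0

    @pytest.mark.parametrize(
        "cm,sens,spec",
        [
            (ConfusionMatrix(10, 107, 15, 9), 53, 88),
            (ConfusionMatrix(18, 109, 13, 1), 95, 89),
        ],
    )
    def test_reported_percentages_round_half_up(self, cm, sens, spec):
        assert round_half_up_pct(sensitivity_pct(cm)) == sens
        assert round_half_up_pct(specificity_pct(cm)) == spec

    def test_half_up_rounding_convention(self):
        assert round_half_up_pct(52.5) == 53
        assert round_half_up_pct(52.49) == 52

    def test_undefined_metric_raises(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity_pct(ConfusionMatrix(0, 5, 2, 0))
        with pytest.raises(UndefinedMetricError):
            specificity_pct(ConfusionMatrix(3, 0, 0, 1))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 0)


class TestMannWhitney:
    def test_identical_groups_give_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_enumeration_small_sample(self):
        _, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_large_separated_samples(self):
        rng = np.random.default_rng(5)
        _, p = mann_whitney_u(rng.normal(0, 1, 60), rng.normal(3, 1, 60))
        assert p < 0.001

    def test_exact_close_to_normal_approximation(self):
        """At 6+6 without ties the two branches agree within 0.02."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.5, 1, 6)
            _, p_exact = mann_whitney_u(a, b)
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic", use_continuity=True)
            assert abs(p_exact - res.pvalue) <= 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])


def fisher_enumeration(table):
    """Oracle: enumerate all tables with the observed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = stats.hypergeom.pmf(x, n, c1, r1)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[1, 0], [0, 1]], 1.0),
            ([[5, 0], [0, 5]], 2 / 252),
            ([[3, 0], [2, 0]], 1.0),  # zero margin
        ],
    )
    def test_known_tables(self, table, expected):
        assert fisher_exact(table) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_on_small_tables(self):
        """All 2x2 tables with total N <= 12."""
        for n in range(1, 13):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                table = [[a, b], [c, d]]
                assert fisher_exact(table) == pytest.approx(
                    fisher_enumeration(table), abs=1e-9
                ), table

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(0, 10), min_size=4, max_size=4).filter(
        lambda x: 0 < sum(x) <= 20))
    def test_matches_enumeration_up_to_twenty(self, flat):
        table = [flat[:2], flat[2:]]
        assert fisher_exact(table) == pytest.approx(
            fisher_enumeration(table), abs=1e-9
        )


class TestIcc:
    def test_perfect_agreement(self):
        r = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert icc_oneway(r).value == pytest.approx(1.0)

    def test_pure_disagreement_closed_form(self):
        # MSB = 0, k = 2 -> ICC = -1
        assert icc_oneway([[1, 2], [2, 1]]).value == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedIccError):
            icc_oneway([[5.0, 5.0], [5.0, 5.0]])

    def test_band_boundaries(self):
        assert icc_band(0.92) == "excellent"
        assert icc_band(0.75) == "excellent"
        assert icc_band(0.74) == "good"
        assert icc_band(0.60) == "good"
        assert icc_band(0.59) == "fair"
        assert icc_band(0.40) == "fair"
        assert icc_band(0.39) == "poor"

    def test_matches_pingouin_icc1(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(8)
        r = rng.normal(0, 1, (15, 1)) + rng.normal(0, 0.4, (15, 3))
        ours = icc_oneway(r).value
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(15), 3),
                "rater": np.tile(np.arange(3), 15),
                "y": r.ravel(),
            }
        )
        theirs = pg.intraclass_corr(
            df, targets="subj", raters="rater", ratings="y"
        ).set_index("Type").loc["ICC(1,1)", "ICC"]
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            icc_oneway([[1.0, 2.0]])
        with pytest.raises(ValueError):
            icc_oneway([[1.0, np.nan], [2.0, 3.0]])
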