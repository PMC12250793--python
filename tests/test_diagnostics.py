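"""Diagnostic-statistics tests against independent oracles.

The rank-based AUC is checked against brute-force pair counting (and
sklearn), the Youden cutoff against an exhaustive threshold scan, the
DeLong paired p against a permutation test, and the chi-square against
scipy's contingency implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedmets.diagnostics import (ScoredCohort, auc_rank, chi2_2x2,
                                 clopper_pearson_ci, confusion_metrics,
                                 cutoff_trend, delong_compare, evaluate_index,
                                 ks_normality, prevalence_percent,
                                 rank_sum_test, roc_points, spearman_rho,
                                 tukey_outliers, wald_ci, youden_cutoff)
from pedmets.errors import DegenerateInputError, DomainError


def pair_counting_auc(scores, labels):
    """Brute-force concordance probability over all positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Scan every observed score as threshold (positive at >= t)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    best = (-2.0, None)
    for t in sorted(set(scores)):
        sens = sum(p >= t for p in pos) / len(pos)
        spec = sum(n < t for n in neg) / len(neg)
        j = sens + spec - 1
        if j > best[0] + 1e-15:
            best = (j, t)
    return best[1], best[0]


def random_cohort(rng, n_max=50):
    n = int(rng.integers(4, n_max + 1))
    labels = np.zeros(n, dtype=bool)
    labels[: int(rng.integers(1, n))] = True
    rng.shuffle(labels)
    # coarse grid ensures frequent ties
    scores = rng.choice(np.linspace(0, 5, 11), size=n)
    return scores, labels


class TestAuc:
    def test_perfect_separation(self):
        c = ScoredCohort([0.1, 0.2, 0.3, 0.4], [0, 0, 1, 1])
        assert auc_rank(c).value == 1.0

    def test_interleaved_brute_force(self):
        # 4 positive-negative pairs: (2>1), (2<3), (4>1), (4>3) -> 3/4
        c = ScoredCohort([1, 2, 3, 4], [0, 1, 0, 1])
        assert auc_rank(c).value == pytest.approx(0.75)

    def test_label_inversion_symmetry(self, rng):
        scores, labels = random_cohort(rng)
        a = auc_rank(ScoredCohort(scores, labels)).value
        b = auc_rank(ScoredCohort(scores, ~labels)).value
        assert a + b == pytest.approx(1.0)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            scores, labels = random_cohort(rng)
            got = auc_rank(ScoredCohort(scores, labels)).value
            assert got == pytest.approx(pair_counting_auc(scores, labels),
                                        rel=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(25):
            scores, labels = random_cohort(rng)
            got = auc_rank(ScoredCohort(scores, labels)).value
            assert got == pytest.approx(roc_auc_score(labels, scores), rel=1e-12)

    def test_ci_brackets_estimate(self, rng):
        scores, labels = random_cohort(rng)
        res = auc_rank(ScoredCohort(scores, labels))
        assert 0.0 <= res.lo <= res.value <= res.hi <= 1.0

    def test_single_class_degenerate(self):
        with pytest.raises(DegenerateInputError):
            auc_rank(ScoredCohort([1, 2, 3], [1, 1, 1]))


class TestRocPoints:
    def test_passes_through_perfect_corner(self):
        pts = roc_points(ScoredCohort([1, 2, 3, 4], [0, 0, 1, 1]))
        assert (1.0, 0.0) in {(s, f) for _, s, f in pts}
        assert pts[0][1:] == (0.0, 0.0) and pts[-1][1:] == (1.0, 1.0)

    def test_all_scores_equal_only_trivial_points(self):
        c = ScoredCohort([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
        pts = roc_points(c)
        assert [(s, f) for _, s, f in pts] == [(0, 0), (1, 1), (1, 1)]
        assert auc_rank(c).value == pytest.approx(0.5)

    def test_monotone_as_threshold_decreases(self, rng):
        for _ in range(20):
            scores, labels = random_cohort(rng)
            pts = roc_points(ScoredCohort(scores, labels))
            sens = [s for _, s, _ in pts]
            fpr = [f for _, _, f in pts]
            assert sens == sorted(sens) and fpr == sorted(fpr)


class TestYouden:
    def test_perfect_separation_j_one(self):
        t, j = youden_cutoff(ScoredCohort([1, 2, 3, 4], [0, 0, 1, 1]))
        assert j == 1.0 and t == 3

    def test_tie_broken_to_lower_threshold(self):
        t, j = youden_cutoff(ScoredCohort([1, 2, 3, 4], [0, 1, 0, 1]))
        assert (t, j) == (2, 0.5)

    def test_degenerate_equal_scores(self):
        t, j = youden_cutoff(ScoredCohort([5.0] * 6, [0, 1] * 3))
        assert j == 0.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(200):
            scores, labels = random_cohort(rng)
            got_t, got_j = youden_cutoff(ScoredCohort(scores, labels))
            exp_t, exp_j = exhaustive_youden(scores, labels)
            assert got_j == pytest.approx(exp_j, abs=1e-12)
            assert got_t == exp_t

    def test_j_equals_sens_plus_spec_minus_one_at_cutoff(self, rng):
        for _ in range(50):
            scores, labels = random_cohort(rng)
            rep = evaluate_index(ScoredCohort(scores, labels))
            m = rep.metrics
            assert rep.youden == pytest.approx(
                m["sens"].value + m["spec"].value - 1.0, abs=1e-12)


class TestConfusionMetrics:
    def test_reconstructed_screening_row(self):
        # 24 positives / 100 negatives; cutoff catching 17 with 2 false alarms
        m = confusion_metrics(17, 7, 2, 98)
        assert m["sens"].value == pytest.approx(0.7083, abs=5e-5)
        assert m["spec"].value == pytest.approx(0.9800, abs=5e-5)
        assert m["ppv"].value == pytest.approx(0.8947, abs=5e-5)
        assert m["npv"].value == pytest.approx(0.9333, abs=5e-5)
        assert m["sens"].lo == pytest.approx(0.5265, abs=1e-4)
        assert m["sens"].hi == pytest.approx(0.8902, abs=1e-4)
        assert m["spec"].lo == pytest.approx(0.9526, abs=1e-4)
        assert m["spec"].hi == 1.0

    def test_hand_arithmetic(self):
        m = confusion_metrics(8, 2, 1, 9)
        assert m["sens"].value == pytest.approx(0.8)
        assert m["spec"].value == pytest.approx(0.9)
        assert m["ppv"].value == pytest.approx(8 / 9)
        assert m["npv"].value == pytest.approx(9 / 11)
        assert m["plr"].value == pytest.approx(8.0)
        assert m["nlr"].value == pytest.approx(0.2 / 0.9)

    def test_zero_margin_is_explicit_undefined(self):
        m = confusion_metrics(0, 0, 3, 7)
        assert m["sens"] is None and m["plr"] is None and m["nlr"] is None
        assert m["spec"] is not None

    def test_ppv_odds_identity(self, rng):
        # ppv/(1-ppv) == plr * prevalence-odds for all valid tables
        for _ in range(100):
            tp, fn, fp, tn = rng.integers(1, 30, size=4)
            m = confusion_metrics(int(tp), int(fn), int(fp), int(tn))
            if m["ppv"] is None or m["plr"] is None or m["ppv"].value == 1.0:
                continue
            odds_ppv = m["ppv"].value / (1 - m["ppv"].value)
            prev_odds = (tp + fn) / (fp + tn)
            assert odds_ppv == pytest.approx(m["plr"].value * prev_odds, rel=1e-9)

    def test_nonint_counts_rejected(self):
        with pytest.raises(DomainError):
            confusion_metrics(-1, 2, 3, 4)


class TestIntervals:
    def test_wald_examples(self):
        lo, hi = wald_ci(17 / 24, 24)
        assert (lo, hi) == (pytest.approx(0.5265, abs=1e-4),
                            pytest.approx(0.8902, abs=1e-4))
        lo, hi = wald_ci(0.98, 100)
        assert lo == pytest.approx(0.9526, abs=1e-4)
        assert hi == 1.0  # clipped
        assert wald_ci(1.0, 30) == (1.0, 1.0)

    def test_wald_degenerate(self):
        with pytest.raises(DegenerateInputError):
            wald_ci(0.5, 0)

    def test_clopper_pearson_brackets_wald(self):
        wlo, whi = wald_ci(17 / 24, 24)
        clo, chi = clopper_pearson_ci(17, 24)
        assert 0 <= clo <= 17 / 24 <= chi <= 1
        assert clo < wlo  # exact interval is wider at this n

    def test_prevalence_percent(self):
        assert prevalence_percent(24, 124) == pytest.approx(19.35, abs=0.01)
        with pytest.raises(DegenerateInputError):
            prevalence_percent(1, 0)


class TestDelong:
    def test_identical_scores(self, rng):
        scores, labels = random_cohort(rng, n_max=30)
        a, b, p = delong_compare(ScoredCohort(scores, labels), scores, scores)
        assert a == b and p == 1.0

    def test_negated_score_symmetry(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        if labels.all() or not labels.any():
            labels[:2] = [True, False]
        a, b, _ = delong_compare(ScoredCohort(scores, labels), scores, -scores)
        assert abs(a - b) == pytest.approx(abs(2 * a - 1), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores_a = rng.normal(size=50)
        scores_b = scores_a + rng.normal(scale=0.7, size=50)
        labels = rng.random(50) < 0.4
        labels[:2] = [True, False]
        c = ScoredCohort(scores_a, labels)
        _, _, p1 = delong_compare(c, scores_a, scores_b)
        _, _, p2 = delong_compare(c, np.exp(scores_a), np.exp(scores_b))
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(7)
        n = 60
        labels = np.zeros(n, dtype=bool)
        labels[:20] = True
        signal = labels.astype(float)
        score_a = signal + rng.normal(scale=1.0, size=n)
        score_b = 0.6 * signal + rng.normal(scale=1.0, size=n)
        cohort = ScoredCohort(score_a, labels)
        auc_a, auc_b, p_delong = delong_compare(cohort, score_a, score_b)
        obs = abs(auc_a - auc_b)
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            swap = rng.random(n) < 0.5
            pa = np.where(swap, score_b, score_a)
            pb = np.where(swap, score_a, score_b)
            da = auc_rank(ScoredCohort(pa, labels)).value
            db = auc_rank(ScoredCohort(pb, labels)).value
            if abs(da - db) >= obs - 1e-12:
                hits += 1
        p_perm = hits / n_perm
        assert p_delong == pytest.approx(p_perm, abs=0.08)


class TestGenericTests:
    def test_spearman_examples(self):
        assert spearman_rho([1, 2, 3, 4], [2, 4, 6, 9])[0] == 1.0
        assert spearman_rho([1, 2, 3, 4], [9, 6, 4, 2])[0] == -1.0
        assert spearman_rho([1, 2, 3], [1, 3, 2])[0] == pytest.approx(0.5)

    def test_spearman_constant_undefined(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_ranksum_exact_small_sample(self):
        _, p = rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3, rel=1e-9)

    def test_ranksum_identical_singletons(self):
        _, p = rank_sum_test([5.0], [5.0])
        assert p == 1.0

    def test_ranksum_empty_group(self):
        with pytest.raises(DegenerateInputError):
            rank_sum_test([], [1.0])

    def test_ranksum_detects_shift(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(40):
            a = rng.normal(0, 1, 30)
            b = rng.normal(1.0, 1, 30)
            rejections += rank_sum_test(a, b)[1] < 0.05
        assert rejections >= 32  # ~96% power at this shift/size

    def test_chi2_yates_reproduces_published_value(self):
        # MetS-by-obesity table 19/5 vs 51/49
        chi2, p = chi2_2x2(19, 5, 51, 49, correction="yates")
        assert p == pytest.approx(0.0232, abs=5e-4)

    def test_chi2_uncorrected_reproduces_published_value(self):
        # MetS-by-sex table 9/52 vs 15/48
        chi2, p = chi2_2x2(9, 52, 15, 48, correction="none")
        assert p == pytest.approx(0.2020, abs=5e-4)

    def test_chi2_null_table(self):
        chi2, p = chi2_2x2(10, 10, 10, 10, correction="none")
        assert chi2 == 0.0 and p == 1.0

    def test_chi2_matches_scipy(self, rng):
        from scipy.stats import chi2_contingency
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(1, 40, size=4))
            for correction, flag in (("none", False), ("yates", True)):
                chi2, p = chi2_2x2(a, b, c, d, correction)
                ref = chi2_contingency([[a, b], [c, d]], correction=flag)
                assert chi2 == pytest.approx(ref.statistic, rel=1e-9)
                assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_chi2_requires_explicit_correction(self):
        with pytest.raises(DomainError):
            chi2_2x2(1, 2, 3, 4, correction="auto")

    def test_chi2_zero_margin(self):
        with pytest.raises(DegenerateInputError):
            chi2_2x2(0, 0, 3, 4, correction="none")


class TestNormality:
    def test_normal_samples_mostly_pass(self):
        rng = np.random.default_rng(3)
        passes = sum(ks_normality(rng.normal(size=200))[1] > 0.05
                     for _ in range(100))
        assert passes >= 90

    def test_exponential_samples_mostly_fail(self):
        rng = np.random.default_rng(4)
        fails = sum(ks_normality(rng.exponential(size=200))[1] < 0.05
                    for _ in range(100))
        assert fails >= 95

    def test_statistic_in_unit_interval(self, rng):
        d, _ = ks_normality(rng.normal(size=50))
        assert 0.0 <= d <= 1.0

    def test_plain_ks_less_conservative_than_lilliefors(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        _, p_lill = ks_normality(x)
        _, p_plain = ks_normality(x, lilliefors=False)
        assert p_plain >= p_lill - 0.3  # naive p inflated when params estimated

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            ks_normality([1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            ks_normality([3.0] * 10)


class TestTukey:
    def test_single_gross_outlier(self):
        x = list(range(1, 10)) + [100]
        flags = tukey_outliers(x)
        assert flags.sum() == 1 and flags[-1]

    def test_clean_symmetric_sample(self, rng):
        assert tukey_outliers(rng.normal(size=9)).sum() == 0

    def test_constant_vector_no_flags(self):
        assert tukey_outliers([4.0] * 8).sum() == 0


class TestCutoffTrend:
    def _cohort(self, rng, n=1200):
        risk = rng.random(n) < 0.3
        scores = rng.normal(risk.astype(float), 1.0)
        ages = rng.uniform(7, 18, n)
        sexes = np.where(rng.random(n) < 0.5, "F", "M")
        return ScoredCohort(scores, risk, sex=sexes, age=ages)

    def test_window_covering_cohort_equals_global(self, rng):
        c = self._cohort(rng, n=400)
        global_t, _ = youden_cutoff(ScoredCohort(c.score, c.label))
        pts = cutoff_trend(c, sex=None, window=40.0, min_n=5)
        assert all(t == global_t for _, t in pts)

    def test_min_n_larger_than_cohort_all_undefined(self, rng):
        c = self._cohort(rng, n=50)
        pts = cutoff_trend(c, sex="F", window=2.0, min_n=10_000)
        assert all(t is None for _, t in pts)

    def test_age_invariant_generator_gives_flat_trend(self):
        rng = np.random.default_rng(21)
        c = self._cohort(rng, n=4000)
        pts = cutoff_trend(c, sex=None, window=4.0, min_n=30)
        cuts = [t for _, t in pts if t is not None]
        assert len(cuts) >= 8
        # true optimum is 0.5 at every age; estimates scatter around it
        assert max(abs(t - 0.5) for t in cuts) < 0.45

    def test_requires_age(self):
        with pytest.raises(DegenerateInputError):
            cutoff_trend(ScoredCohort([1, 2], [0, 1]), sex=None)


@given(st.data())
@settings(max_examples=60, derandomize=True, deadline=None)
def test_auc_and_youden_property(data):
    n = data.draw(st.integers(4, 30))
    n_pos = data.draw(st.integers(1, n - 1))
    labels = np.array([True] * n_pos + [False] * (n - n_pos))
    scores = np.array(data.draw(st.lists(
        st.sampled_from([0.0, 0.5, 1.0, 1.5, 2.0]), min_size=n, max_size=n)))
    c = ScoredCohort(scores, labels)
    assert auc_rank(c).value == pytest.approx(
        pair_counting_auc(scores, labels), rel=1e-12)
    t, j = youden_cutoff(c)
    et, ej = exhaustive_youden(list(scores), list(labels))
    assert j == pytest.approx(ej, abs=1e-12) and t == et
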