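"""Oracle tests for confusion metrics, ROC/AUC, CIs, cut-offs and DCA."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from dmil.evaluation import (
    ScoredCohort,
    auc_ci,
    confusion_metrics,
    decision_curve,
    evaluate_cohort,
    optimal_cutoffs,
    roc_auc,
)


def make_cohort(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    ids = [f"b{i}" for i in range(len(scores))]
    return ScoredCohort(ids, scores, labels)


def mann_whitney_auc(scores, labels):
    """Exhaustive pairwise statistic: wins + half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def counts_cohort(tp, fn, tn, fp):
    """Cohort realizing given confusion counts at cutoff 0.5."""
    scores = [0.9] * tp + [0.1] * fn + [0.1] * tn + [0.9] * fp
    labels = [1] * tp + [1] * fn + [0] * tn + [0] * fp
    return make_cohort(scores, labels)


class TestConfusionMetrics:
    def test_perfect_separation(self):
        cohort = make_cohort([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        cm = confusion_metrics(cohort, 0.5)
        assert (cm.accuracy, cm.sensitivity, cm.specificity, cm.f1) == (1, 1, 1, 1)

    def test_study_test_cohort_counts(self):
        # 26/30 response detected, 27/30 nonresponse detected
        cm = confusion_metrics(counts_cohort(tp=26, fn=4, tn=27, fp=3), 0.5)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (26, 4, 27, 3)
        assert cm.accuracy == pytest.approx(53 / 60)
        assert round(cm.accuracy, 3) == 0.883

    def test_external_cohort_counts(self):
        cm = confusion_metrics(counts_cohort(tp=18, fn=4, tn=17, fp=3), 0.5)
        assert cm.accuracy == pytest.approx(35 / 42)
        assert round(cm.accuracy, 3) == 0.833

    def test_counts_sum_and_identities(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 40))
            cohort = make_cohort(rng.random(n), rng.integers(0, 2, n))
            cm = confusion_metrics(cohort, float(rng.random()))
            assert cm.tp + cm.fp + cm.tn + cm.fn == n
            assert cm.accuracy * n == pytest.approx(cm.tp + cm.tn)

    def test_cutoff_is_closed_on_the_left(self):
        cohort = make_cohort([0.5, 0.49], [1, 0])
        cm = confusion_metrics(cohort, 0.5)
        assert (cm.tp, cm.tn) == (1, 1)

    def test_degenerate_f1_is_zero_with_warning(self):
        cohort = make_cohort([0.1, 0.2], [0, 0])
        with pytest.warns(UserWarning):
            cm = confusion_metrics(cohort, 0.5)
        assert cm.f1 == 0.0


class TestRocAuc:
    def test_perfect_separation_auc_one(self):
        assert roc_auc(make_cohort([0.9, 0.8, 0.2], [1, 1, 0])).auc == 1.0

    def test_all_ties_auc_half(self):
        assert roc_auc(make_cohort([0.5] * 6, [1, 1, 1, 0, 0, 0])).auc == 0.5

    def test_eight_item_cohort_with_tie_matches_pair_count(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9, 0.5, 0.2]
        labels = [0, 0, 1, 1, 0, 1, 1, 0]
        cohort = make_cohort(scores, labels)
        assert roc_auc(cohort).auc == pytest.approx(
            mann_whitney_auc(scores, labels), abs=1e-12
        )

    def test_matches_mann_whitney_on_random_cohorts(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 31))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            cohort = make_cohort(scores, labels)
            assert roc_auc(cohort).auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(make_cohort([0.1, 0.9], [1, 1]))


class TestAucCI:
    def test_perfect_separation_interval_collapses(self, rng):
        scores = np.r_[rng.uniform(0.6, 1.0, 200), rng.uniform(0.0, 0.4, 200)]
        labels = np.r_[np.ones(200, int), np.zeros(200, int)]
        lo, hi = auc_ci(make_cohort(scores, labels))
        assert hi == 1.0
        assert lo == pytest.approx(1.0, abs=1e-9)

    def test_label_reversal_reflects_interval(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        cohort = make_cohort(scores, labels)
        flipped = make_cohort(scores, 1 - labels)
        lo, hi = auc_ci(cohort)
        lo2, hi2 = auc_ci(flipped)
        assert lo2 == pytest.approx(1 - hi, abs=1e-12)
        assert hi2 == pytest.approx(1 - lo, abs=1e-12)

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(10):
            scores = rng.random(40)
            labels = rng.integers(0, 2, 40)
            labels[:2] = [0, 1]
            cohort = make_cohort(scores, labels)
            lo, hi = auc_ci(cohort)
            assert lo <= roc_auc(cohort).auc <= hi

    def test_bootstrap_method_agrees_roughly_with_delong(self, rng):
        scores = expit(np.r_[rng.normal(1.0, 1.0, 80), rng.normal(0.0, 1.0, 80)])
        labels = np.r_[np.ones(80, int), np.zeros(80, int)]
        cohort = make_cohort(scores, labels)
        lo_d, hi_d = auc_ci(cohort, method="delong")
        lo_b, hi_b = auc_ci(cohort, method="bootstrap", n_boot=500, seed=0)
        assert abs(lo_d - lo_b) < 0.05 and abs(hi_d - hi_b) < 0.05

    def test_delong_coverage_of_binormal_auc(self):
        """95% DeLong intervals cover the closed-form binormal AUC >= 93% of
        the time (500 simulations, n = 200 per class, separation d = 1)."""
        d = 1.0
        true_auc = norm.cdf(d / np.sqrt(2))
        rng = np.random.default_rng(2024)
        covered = 0
        n_sim = 500
        for _ in range(n_sim):
            pos = expit(rng.normal(d, 1.0, 200))
            neg = expit(rng.normal(0.0, 1.0, 200))
            cohort = make_cohort(
                np.r_[pos, neg], np.r_[np.ones(200, int), np.zeros(200, int)]
            )
            lo, hi = auc_ci(cohort, level=0.95)
            covered += lo <= true_auc <= hi
        assert covered / n_sim >= 0.93

    def test_degenerate_cohort_rejected(self):
        with pytest.raises(ValueError):
            auc_ci(make_cohort([0.2, 0.9], [0, 1]))


class TestOptimalCutoffs:
    def test_perfect_classifier_youden_is_one(self):
        cohort = make_cohort([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        roc = roc_auc(cohort)
        cut_y, cut_d = optimal_cutoffs(roc)
        cm = confusion_metrics(cohort, cut_y)
        assert cm.sensitivity + cm.specificity - 1 == 1.0
        cm_d = confusion_metrics(cohort, cut_d)
        assert cm_d.accuracy == 1.0

    def test_six_point_roc_matches_exhaustive_search(self):
        scores = [0.95, 0.8, 0.7, 0.55, 0.3, 0.1]
        labels = [1, 1, 0, 1, 0, 0]
        cohort = make_cohort(scores, labels)
        cut_y, cut_d = optimal_cutoffs(roc_auc(cohort))
        # exhaustive search over all distinct-score thresholds
        best = {}
        for cut in sorted(set(scores)):
            cm = confusion_metrics(cohort, cut)
            j = cm.sensitivity + cm.specificity - 1
            d = np.hypot(1 - cm.sensitivity, 1 - cm.specificity)
            best[cut] = (j, d)
        j_best = max(v[0] for v in best.values())
        d_best = min(v[1] for v in best.values())
        assert best[cut_y][0] == pytest.approx(j_best)
        assert best[cut_d][1] == pytest.approx(d_best)

    def test_random_cohorts_match_exhaustive_search(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 25))
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            scores = np.round(rng.random(n), 2)
            cohort = make_cohort(scores, labels)
            cut_y, cut_d = optimal_cutoffs(roc_auc(cohort))
            results = {}
            for cut in sorted(set(scores)):
                cm = confusion_metrics(cohort, cut)
                results[cut] = (
                    cm.sensitivity + cm.specificity - 1,
                    np.hypot(1 - cm.sensitivity, 1 - cm.specificity),
                )
            j_best = max(v[0] for v in results.values())
            d_best = min(v[1] for v in results.values())
            assert results[cut_y][0] == pytest.approx(j_best, abs=1e-12)
            assert results[cut_d][1] == pytest.approx(d_best, abs=1e-12)

    def test_monotone_transform_preserves_partition(self, rng):
        scores = np.round(rng.random(14), 2)
        labels = rng.integers(0, 2, 14)
        labels[:2] = [0, 1]
        cohort = make_cohort(scores, labels)
        cubed = make_cohort(scores**3, labels)
        cut_y, _ = optimal_cutoffs(roc_auc(cohort))
        cut_y3, _ = optimal_cutoffs(roc_auc(cubed))
        np.testing.assert_array_equal(scores >= cut_y, scores**3 >= cut_y3)


class TestDecisionCurve:
    def test_perfect_classifier_net_benefit_equals_prevalence(self):
        cohort = make_cohort([1.0, 1.0, 0.0, 0.0, 0.0], [1, 1, 0, 0, 0])
        dca = decision_curve(cohort)
        np.testing.assert_allclose(dca.nb_model, 2 / 5, atol=1e-12)

    def test_treat_all_closed_form_and_zero_crossing(self):
        labels = [1] * 3 + [0] * 7  # prevalence 0.3
        cohort = make_cohort([0.5] * 10, labels)
        thresholds = np.array([0.001, 0.1, 0.3, 0.6])
        dca = decision_curve(cohort, thresholds)
        pi = 0.3
        expected = pi - (1 - pi) * thresholds / (1 - thresholds)
        np.testing.assert_allclose(dca.nb_treat_all, expected, atol=1e-12)
        assert dca.nb_treat_all[0] == pytest.approx(pi, abs=1e-2)
        assert dca.nb_treat_all[2] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_array_equal(dca.nb_treat_none, 0.0)

    def test_matches_per_threshold_recount_oracle(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        cohort = make_cohort(scores, labels)
        thresholds = np.arange(0.01, 1.0, 0.01)
        dca = decision_curve(cohort, thresholds)
        for t, nb in zip(thresholds, dca.nb_model):
            tp = np.sum((scores >= t) & (labels == 1))
            fp = np.sum((scores >= t) & (labels == 0))
            expected = tp / 50 - (fp / 50) * t / (1 - t)
            assert nb == pytest.approx(expected, abs=1e-10)

    def test_model_net_benefit_bounded_by_prevalence(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        dca = decision_curve(make_cohort(scores, labels))
        assert np.all(dca.nb_model <= labels.mean() + 1e-12)

    def test_all_positive_cutoff_equals_treat_all(self):
        cohort = make_cohort([0.9] * 8, [1, 1, 1, 0, 0, 0, 0, 0])
        dca = decision_curve(cohort, np.array([0.2, 0.5]))
        np.testing.assert_allclose(dca.nb_model, dca.nb_treat_all, atol=1e-12)

    def test_thresholds_outside_unit_interval_rejected(self, rng):
        cohort = make_cohort(rng.random(5), [1, 0, 1, 0, 1])
        with pytest.raises(ValueError):
            decision_curve(cohort, np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            decision_curve(cohort, np.array([0.5, 1.0]))


class TestEvaluateCohort:
    def test_full_report_consistency(self, rng):
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        cohort = make_cohort(scores, labels)
        report = evaluate_cohort(cohort, cutoff="youden")
        assert report.tp + report.fp + report.tn + report.fn == 80
        assert report.auc_ci[0] <= report.auc <= report.auc_ci[1]
        assert report.cutoff == report.cutoff_youden
        report2 = evaluate_cohort(cohort, cutoff="min_distance")
        assert report2.cutoff == report2.cutoff_min_distance

    def test_flipped_convention_reverses_auc(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        cohort = make_cohort(scores, labels)
        a = evaluate_cohort(cohort).auc
        b = evaluate_cohort(cohort, positive_label=0).auc
        assert a == pytest.approx(b)  # flipping labels AND scores preserves AUC

    def test_pure_function_same_report_twice(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        cohort = make_cohort(scores, labels)
        assert evaluate_cohort(cohort) == evaluate_cohort(cohort)
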