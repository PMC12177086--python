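"""Diagnostic-statistics module against analytic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonomil import metrics
from sonomil.metrics import (ClinicalRecord, auc_variance, chi_square,
                             confusion_at, dca, delong_test,
                             fit_clinical_model, miou, pr_curve, roc_auc,
                             simulate_clinical_records)


def brute_force_auc(scores, labels):
    """Exhaustive pairwise positive-negative comparison (ties count 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_hand_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_and_inverted(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        assert roc_auc(scores, [0, 0, 1, 1]) == 1.0
        assert roc_auc(scores, [1, 1, 0, 0]) == pytest.approx(
            1.0 - roc_auc(scores, [0, 0, 1, 1]))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 1)),
                    min_size=4, max_size=30))
    def test_matches_pairwise_oracle(self, pairs):
        scores = np.array([s for s, _ in pairs], float) / 10.0
        labels = np.array([y for _, y in pairs])
        if labels.min() == labels.max():
            return
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels))

    def test_matches_sklearn(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=200)
        labels = rng.integers(0, 2, 200)
        from sklearn.metrics import roc_auc_score
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores))


class TestConfusion:
    def test_hand_counted_table(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.4, 0.55, 0.3, 0.2, 0.45, 0.1]
        labels = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        c = confusion_at(scores, labels, 0.5)
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 2, 4, 1)
        assert c.accuracy == pytest.approx(0.7)
        assert c.sensitivity == pytest.approx(3 / 4)
        assert c.specificity == pytest.approx(4 / 6)
        assert c.ppv == pytest.approx(3 / 5)
        assert c.npv == pytest.approx(4 / 5)
        assert c.mistake_rate == pytest.approx(1 - c.specificity)
        assert c.omission_rate == pytest.approx(1 - c.sensitivity)

    def test_perfect_classifier(self):
        c = confusion_at([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert c.sensitivity == 1.0 and c.specificity == 1.0

    def test_f1_identity_on_random_sets(self, rng):
        for _ in range(20):
            scores = rng.uniform(size=40)
            labels = rng.integers(0, 2, 40)
            c = confusion_at(scores, labels, 0.5)
            if np.isnan(c.ppv) or (c.ppv + c.sensitivity) == 0:
                continue
            expect = 2 * c.ppv * c.sensitivity / (c.ppv + c.sensitivity)
            assert c.f1 == pytest.approx(expect)


class TestDelong:
    def test_identical_models(self, rng):
        scores = rng.uniform(size=60)
        labels = rng.integers(0, 2, 60)
        auc_a, auc_b, _, z, p = delong_test(scores, scores, labels)
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        a, b = rng.uniform(size=(2, 80))
        labels = rng.integers(0, 2, 80)
        _, _, _, z1, p1 = delong_test(a, b, labels)
        _, _, _, z2, p2 = delong_test(b, a, labels)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_variance_nonnegative(self, rng):
        for _ in range(25):
            scores = rng.uniform(size=30)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            assert auc_variance(scores, labels) >= 0.0

    def test_variance_matches_bootstrap(self):
        """DeLong variance vs a 10,000-rep case bootstrap on 50 cases."""
        rng = np.random.default_rng(99)
        labels = np.array([1] * 20 + [0] * 30)
        scores = np.where(labels == 1, rng.normal(0.8, 0.6, 50),
                          rng.normal(0.0, 0.6, 50))
        var_delong = auc_variance(scores, labels)
        reps = []
        for _ in range(10_000):
            idx = rng.integers(0, 50, 50)
            if labels[idx].min() == labels[idx].max():
                continue
            reps.append(roc_auc(scores[idx], labels[idx]))
        var_boot = np.var(reps, ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.35)

    def test_unpaired_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.1, 0.2, 0.3], [0, 1, 1])


class TestPrCurve:
    def test_perfect_ranking(self):
        _, _, _, ap = pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert ap == 1.0

    def test_constant_scores_give_prevalence(self):
        precision, recall, _, ap = pr_curve([0.5] * 10, [1, 1, 1, 0] + [0] * 6)
        assert ap == pytest.approx(0.3)
        assert precision[np.argmin(np.abs(recall - 1.0))] == pytest.approx(0.3)

    def test_hand_example_matches_threshold_sweep(self):
        scores = np.array([0.9, 0.7, 0.6, 0.5, 0.3, 0.1])
        labels = np.array([1, 0, 1, 1, 0, 0])
        precision, recall, thresholds, _ = pr_curve(scores, labels)
        for t, prec, rec in zip(thresholds, precision[:-1], recall[:-1]):
            pred = scores >= t
            assert prec == pytest.approx(labels[pred].mean())
            assert rec == pytest.approx(labels[pred].sum() / labels.sum())


class TestDca:
    def test_treat_all_crosses_zero_at_prevalence(self, rng):
        labels = np.array([1] * 3 + [0] * 9)   # prevalence 0.25
        scores = rng.uniform(size=12)
        curve = dca(scores, labels, thresholds=[0.1, 0.25, 0.6])
        assert curve.nb_treat_all[1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(curve.nb_treat_none == 0.0)

    def test_perfect_classifier_net_benefit_is_prevalence(self):
        labels = np.array([1, 1, 0, 0, 0])
        scores = np.array([0.99, 0.98, 0.01, 0.02, 0.03])
        curve = dca(scores, labels, thresholds=np.linspace(0.05, 0.95, 10))
        np.testing.assert_allclose(curve.nb_model, 0.4, atol=1e-12)

    def test_hand_counted_case(self):
        scores = [0.9, 0.6, 0.4, 0.35, 0.3, 0.2, 0.15, 0.05]
        labels = [1, 1, 0, 1, 0, 0, 0, 0]
        curve = dca(scores, labels, thresholds=[0.25])
        # score >= 0.25 -> 5 predicted positive: TP=3, FP=2, n=8
        assert curve.nb_model[0] == pytest.approx(3 / 8 - (2 / 8) * (0.25 / 0.75))

    def test_threshold_one_rejected(self, rng):
        with pytest.raises(ValueError):
            dca(rng.uniform(size=4), [0, 1, 0, 1], thresholds=[1.0])


class TestMiou:
    def test_identical_disjoint_partial(self):
        a = np.zeros((4, 4), bool)
        a[1:3, 1:3] = True
        assert miou([a], [a]) == 1.0
        b = np.zeros((4, 4), bool)
        b[0, 0] = True
        c = np.zeros((4, 4), bool)
        c[3, 3] = True
        assert miou([b], [c]) == 0.0
        r1 = np.zeros((1, 4), bool)
        r1[0, :2] = True     # width-2 strip
        r2 = np.zeros((1, 4), bool)
        r2[0, 1:3] = True    # overlaps in one column
        assert miou([r1], [r2]) == pytest.approx(1 / 3)

    def test_empty_union_counts_as_one(self):
        empty = np.zeros((3, 3), bool)
        assert miou([empty], [empty]) == 1.0

    def test_probability_thresholding(self):
        gt = np.zeros((2, 2), bool)
        gt[0, 0] = True
        pred = np.array([[0.9, 0.2], [0.1, 0.4]])
        assert miou([pred], [gt]) == 1.0


class TestChiSquare:
    def test_identical_rows_are_independent(self):
        stat, df, p = chi_square([[10, 20, 30], [10, 20, 30]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 5], [0, 7]])

    def test_matches_permutation_null(self):
        """Pearson p vs a fixed-margin permutation null on a 2x3 table.

        Counts are kept moderate (expected cells ~25-40) so the
        asymptotic chi-square tail is valid at Monte-Carlo resolution.
        """
        table = np.array([[30, 45, 25], [22, 33, 40]])
        stat, _, p = chi_square(table)
        rng = np.random.default_rng(5)
        row0 = table.sum(axis=1)[0]
        cols = table.sum(axis=0)
        reps = 40_000
        exceed = 0
        for _ in range(reps):
            top = rng.multivariate_hypergeometric(cols, row0)
            t = np.stack([top, cols - top])
            s, _, _ = chi_square(t)
            exceed += s >= stat - 1e-9
        p_perm = exceed / reps
        se = np.sqrt(p_perm * (1 - p_perm) / reps)
        assert abs(p - p_perm) < 4 * se + 0.005


class TestClinicalModel:
    TRUE_COEF = np.array([-1.5, 0.4, 0.9, 1.4, 0.3, 0.8, 1.2])

    def test_recovers_simulated_coefficients(self):
        rng = np.random.default_rng(11)
        records = simulate_clinical_records(2000, self.TRUE_COEF, rng)
        model = fit_clinical_model(records)
        assert model.converged
        for est, se, truth in zip(model.coef, model.coef_se, self.TRUE_COEF):
            assert abs(est - truth) < 3 * se

    def test_null_effects_recovered_as_zero(self):
        rng = np.random.default_rng(12)
        coef = np.zeros(7)
        records = simulate_clinical_records(2000, coef, rng)
        model = fit_clinical_model(records)
        for est, se in zip(model.coef[1:], model.coef_se[1:]):
            assert abs(est) < 3 * se

    def test_monotone_risk_gives_monotone_probabilities(self):
        rng = np.random.default_rng(13)
        coef = np.array([-2.0, 0.5, 1.0, 1.5, 0.0, 0.0, 0.0])
        records = simulate_clinical_records(3000, coef, rng)
        model = fit_clinical_model(records)
        probe = [ClinicalRecord(b, "T1", 0) for b in metrics.BIRADS_LEVELS]
        probs = model.predict(probe)
        assert np.all(np.diff(probs) > 0)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            fit_clinical_model([ClinicalRecord("3", "T1", 0),
                                ClinicalRecord("4A", "T2", 1)])
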