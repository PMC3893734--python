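"""Per-subtype PLS + logistic classifier: fitting, prediction, LOOCV,
metrics.  Cross-checked against statsmodels' Logit as the independent
logistic-regression implementation."""

import numpy as np
import pytest

from plssubtype import (ExpressionMatrix, classifier_metrics, fit_classifier,
                        fit_pls, loocv_probabilities, predict_probability)
from plssubtype.classifier import LogisticModel, fit_logistic_irls


def two_cluster_matrix(n_per=10, shift=3.0, n_genes=10, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    labels = np.array([1.0] * n_per + [0.0] * n_per)
    values = rng.normal(0, noise, (n_genes, 2 * n_per))
    values[:, :n_per] += shift
    m = ExpressionMatrix(genes, [f"S{j}" for j in range(2 * n_per)], values)
    return m, labels, genes


class TestLogisticIRLS:
    def test_closed_form_probabilities(self):
        lr = LogisticModel(beta0=0.0, betas=np.array([1.0]))
        assert lr.probability(np.array([[0.0]]))[0] == pytest.approx(0.5)
        assert lr.probability(np.array([[np.log(3)]]))[0] == pytest.approx(0.75)
        assert lr.probability(np.array([[-20.0]]))[0] < 1e-8

    def test_matches_statsmodels_on_separable_free_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        eta = 0.5 + 1.2 * x
        y = (rng.random(80) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = fit_logistic_irls(x[:, None], y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose([ours.beta0, ours.betas[0]],
                                   ref.params, atol=1e-6)

    def test_perfect_separation_triggers_ridge_fallback(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = np.array([0.0, 0, 0, 1, 1, 1])
        model = fit_logistic_irls(x[:, None], y)
        assert model.ridged
        p = model.probability(x[:, None]).ravel()
        assert np.all((p[y == 1] > 0.5) & (p[y == 0] < 0.5))


class TestFitClassifier:
    def test_separable_clusters_perfect_training_accuracy(self):
        m, labels, genes = two_cluster_matrix(shift=3.0)
        clf = fit_classifier(m, labels, genes, k=1, subtype_name="test")
        probs = predict_probability(clf, m)
        assert np.all((probs > 0.5) == (labels == 1))

    def test_k1_matches_direct_pls_plus_statsmodels_oracle(self):
        import statsmodels.api as sm

        # overlapping clusters: separable data has no finite ML solution and
        # the comparison would be between two divergence behaviours
        m, labels, genes = two_cluster_matrix(n_per=20, shift=0.4, seed=3)
        clf = fit_classifier(m, labels, genes, k=1)
        assert not clf.lr.ridged
        # oracle: standardize, one PLS component, standard IRLS logistic
        X = m.values.T
        X0 = (X - X.mean(0)) / X.std(0, ddof=1)
        model = fit_pls(X0, labels - labels.mean(), 1)
        ref = sm.Logit(labels, sm.add_constant(model.T)).fit(disp=0)
        probs = predict_probability(clf, m)
        np.testing.assert_allclose(probs, ref.predict(), atol=1e-6)

    def test_permuted_labels_give_null_cross_validated_auc(self):
        # oracle: with labels independent of expression the expected
        # held-out AUC is 1/2; simulate permutation replicates (the
        # resubstitution AUC is overfit-biased upward and is not null-0.5)
        rng = np.random.default_rng(4)
        m, labels, genes = two_cluster_matrix(n_per=15, shift=0.0, seed=4)
        aucs = []
        for _ in range(20):
            perm = rng.permutation(labels)
            probs = loocv_probabilities(m, perm, genes, k=1)
            aucs.append(classifier_metrics(probs, perm).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.15)

    def test_too_few_per_class_rejected(self):
        m, labels, genes = two_cluster_matrix(n_per=5)
        labels = np.zeros_like(labels)
        labels[:2] = 1
        with pytest.raises(ValueError, match="3 samples"):
            fit_classifier(m, labels, genes, k=1)

    def test_missing_panel_gene_rejected(self):
        m, labels, genes = two_cluster_matrix()
        with pytest.raises(KeyError, match="ABSENT"):
            fit_classifier(m, labels, genes + ["ABSENT"], k=1)


class TestPredictProbability:
    def test_probabilities_open_interval_and_monotone_in_predictor(self):
        m, labels, genes = two_cluster_matrix(shift=2.0, seed=5)
        clf = fit_classifier(m, labels, genes, k=1)
        probs = predict_probability(clf, m)
        assert np.all((probs > 0) & (probs < 1))
        eta = clf.lr.linear_predictor(clf._scores(m)).ravel()
        order = np.argsort(eta)
        assert np.all(np.diff(probs[order]) >= 0)


class TestLOOCV:
    def test_separable_clusters_all_held_out_correct(self):
        m, labels, genes = two_cluster_matrix(n_per=3, shift=4.0, seed=6,
                                              noise=0.5)
        probs = loocv_probabilities(m, labels, genes, k=1)
        assert np.all((probs > 0.5) == (labels == 1))

    def test_matches_hand_rolled_refit_loop(self):
        m, labels, genes = two_cluster_matrix(n_per=4, shift=1.5, seed=7)
        probs = loocv_probabilities(m, labels, genes, k=1)
        # oracle: an independent loop deleting one sample and refitting the
        # full classifier, then predicting the held-out sample with it
        for i in range(m.n_samples):
            keep = np.ones(m.n_samples, bool)
            keep[i] = False
            sub = m.subset_samples(keep)
            clf = fit_classifier(sub, labels[keep], genes, k=1)
            held = m.subset_samples(np.array([i]))
            expected = predict_probability(clf, held)[0]
            assert probs[i] == pytest.approx(expected, abs=1e-8)

    def test_no_leakage_duplicate_with_flipped_label_changes_probability(self):
        m, labels, genes = two_cluster_matrix(n_per=5, shift=1.0, seed=8)
        base = loocv_probabilities(m, labels, genes, k=1)
        dup_values = np.column_stack([m.values, m.values[:, 0]])
        dup = ExpressionMatrix(genes, m.sample_ids + ["DUP"], dup_values)
        dup_labels = np.append(labels, 1.0 - labels[0])
        flipped = loocv_probabilities(dup, dup_labels, genes, k=1)
        assert flipped[0] != pytest.approx(base[0], abs=1e-12)

    def test_loocv_auc_below_resubstitution_on_average(self):
        deltas = []
        for seed in range(20):
            m, labels, genes = two_cluster_matrix(n_per=6, shift=0.8,
                                                  seed=100 + seed)
            clf = fit_classifier(m, labels, genes, k=1)
            resub = classifier_metrics(
                predict_probability(clf, m), labels).auc
            loo = classifier_metrics(
                loocv_probabilities(m, labels, genes, k=1), labels).auc
            deltas.append(resub - loo)
        assert np.mean(deltas) > 0


class TestClassifierMetrics:
    def test_perfect_ranking(self):
        m = classifier_metrics(np.array([0.9, 0.8, 0.2, 0.1]),
                               np.array([1.0, 1, 0, 0]))
        assert m.accuracy == 1.0 and m.auc == 1.0
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_all_tied_probabilities_give_half_auc(self):
        m = classifier_metrics(np.full(6, 0.5), np.array([1.0, 0, 1, 0, 1, 0]),
                               threshold=0.4)
        assert m.auc == pytest.approx(0.5)

    def test_midrank_auc_matches_pairwise_oracle(self):
        probs = np.array([0.6, 0.4, 0.7, 0.2])
        labels = np.array([1.0, 0, 0, 1])
        # oracle: brute force over all positive-negative pairs, ties 1/2
        wins = 0.0
        for i in np.flatnonzero(labels == 1):
            for j in np.flatnonzero(labels == 0):
                wins += (probs[i] > probs[j]) + 0.5 * (probs[i] == probs[j])
        expected = wins / 4
        assert expected == 0.25
        assert classifier_metrics(probs, labels).auc == pytest.approx(expected)

    def test_accuracy_identity(self):
        rng = np.random.default_rng(9)
        probs = rng.uniform(0.01, 0.99, 40)
        labels = (rng.random(40) < 0.4).astype(float)
        m = classifier_metrics(probs, labels)
        P, N = m.n_positive, m.n_negative
        assert m.accuracy == pytest.approx(
            (m.sensitivity * P + m.specificity * N) / (P + N))

    def test_single_class_auc_missing(self):
        m = classifier_metrics(np.array([0.2, 0.6]), np.array([1.0, 1.0]))
        assert np.isnan(m.auc)

    def test_nagelkerke_r2_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        x = rng.normal(size=60)
        y = (rng.random(60) < 1 / (1 + np.exp(-x))).astype(float)
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        probs = np.clip(fit.predict(), 1e-12, 1 - 1e-12)
        n = len(y)
        cox_snell = 1 - np.exp(-fit.llr / n * 2 / 2)  # llr = 2(ll - ll0)
        expected = cox_snell / (1 - np.exp(2 * fit.llnull / n))
        m = classifier_metrics(probs, y)
        assert m.adjusted_r2 == pytest.approx(expected, abs=1e-8)
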