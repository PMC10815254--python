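"""SMOTE balancing, classifier training, and metric computation."""

import numpy as np
import pytest

import dlrpmds as d
from dlrpmds.datatypes import ValidationError


def latent_set(X, y):
    return d.LabeledLatentSet(
        latents=np.asarray(X, float),
        labels=np.asarray(y, int),
        variant_ids=np.array([f"v{i}" for i in range(len(y))]),
    )


def blobs(n_per_class=60, q=6, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_per_class, q))
    b = rng.normal(size=(n_per_class, q))
    b[:, 0] += sep
    X = np.vstack([a, b])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return latent_set(X, y)


class TestSmoteBalance:
    def test_balanced_input_returned_unchanged(self, rng):
        data = latent_set(rng.normal(size=(10, 3)), [0] * 5 + [1] * 5)
        assert d.smote_balance(data, seed=1) is data

    def test_counts_equalized_and_originals_preserved(self, rng):
        X = rng.normal(size=(30, 4))
        y = [0] * 24 + [1] * 6
        out = d.smote_balance(latent_set(X, y), seed=2)
        counts = np.bincount(out.labels)
        assert counts[0] == counts[1] == 24
        assert np.array_equal(out.latents[:30], X)
        assert np.array_equal(out.labels[:30], y)

    def test_identical_minority_points_give_identical_synthetics(self):
        X = np.vstack([np.zeros((2, 3)) + 7.0, np.ones((8, 3))])
        y = [1, 1] + [0] * 8
        out = d.smote_balance(latent_set(X, y), seed=0)
        synth = out.latents[10:]
        assert np.allclose(synth, 7.0)

    def test_synthetics_lie_on_knn_segments(self, rng):
        # brute-force oracle: each synthetic point must be a convex
        # combination of some minority point and one of its k nearest
        # minority neighbours
        k = 3
        X_min = rng.normal(size=(10, 2))
        X_maj = rng.normal(size=(40, 2)) + 20
        data = latent_set(np.vstack([X_min, X_maj]), [1] * 10 + [0] * 40)
        out = d.smote_balance(data, k_neighbors=k, seed=5)
        synth = out.latents[50:]
        assert len(synth) == 30

        dists = np.linalg.norm(X_min[:, None] - X_min[None, :], axis=2)
        np.fill_diagonal(dists, np.inf)
        knn = np.argsort(dists, axis=1)[:, :k]

        for s in synth:
            ok = False
            for i in range(10):
                for j in knn[i]:
                    lo = np.minimum(X_min[i], X_min[j])
                    hi = np.maximum(X_min[i], X_min[j])
                    if np.all(s >= lo - 1e-9) and np.all(s <= hi + 1e-9):
                        # also collinear with the segment
                        v, w = X_min[j] - X_min[i], s - X_min[i]
                        cross = abs(v[0] * w[1] - v[1] * w[0])
                        if cross < 1e-9 * max(1.0, np.linalg.norm(v)):
                            ok = True
                            break
                if ok:
                    break
            assert ok, f"synthetic point {s} not on any k-NN segment"

    def test_single_sample_minority_raises_with_guidance(self, rng):
        data = latent_set(rng.normal(size=(5, 2)), [1, 0, 0, 0, 0])
        with pytest.raises(ValidationError, match="wildtype"):
            d.smote_balance(data)

    def test_deterministic_under_seed(self, rng):
        data = latent_set(rng.normal(size=(30, 4)), [0] * 24 + [1] * 6)
        a = d.smote_balance(data, seed=9)
        b = d.smote_balance(data, seed=9)
        assert np.array_equal(a.latents, b.latents)


class TestTrainClassifier:
    def test_separable_blobs_reach_perfect_training_accuracy(self):
        data = blobs(sep=10.0)
        cfg = d.ClassifierConfig(width=32, epochs=30, seed=0)
        model = d.train_classifier(data, cfg)
        pred = (model.predict_deleterious(data.latents) >= 0.5).astype(int)
        assert np.mean(pred == data.labels) == 1.0
        # linear-SVM oracle agrees the problem is separable
        from sklearn.svm import LinearSVC

        svm = LinearSVC().fit(data.latents, data.labels)
        assert svm.score(data.latents, data.labels) == 1.0

    def test_probabilities_sum_to_one(self):
        data = blobs(n_per_class=20, sep=3.0)
        model = d.train_classifier(data, d.ClassifierConfig(width=16, epochs=5, seed=0))
        proba = model.predict_proba(data.latents)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert proba.min() >= 0

    def test_paper_architecture_accepted(self):
        cfg = d.ClassifierConfig(hidden_layers=3, width=512, dropout=0.0)
        assert cfg.hidden_layers == 3 and cfg.width == 512

    def test_one_class_input_rejected(self, rng):
        data = latent_set(rng.normal(size=(10, 3)), [0] * 10)
        with pytest.raises(ValidationError):
            d.train_classifier(data, d.ClassifierConfig(width=8, epochs=1))

    def test_fixed_seed_identical_predictions(self):
        data = blobs(n_per_class=15, sep=2.0)
        cfg = d.ClassifierConfig(width=16, epochs=5, seed=3)
        p1 = d.train_classifier(data, cfg).predict_proba(data.latents)
        p2 = d.train_classifier(data, cfg).predict_proba(data.latents)
        assert np.array_equal(p1, p2)


class TestComputeMetrics:
    def test_confusion_matrix_arithmetic(self):
        # TP=8, FN=2, TN=6, FP=4
        labels = np.array([1] * 10 + [0] * 10)
        scores = np.array([0.9] * 8 + [0.1] * 2 + [0.2] * 6 + [0.8] * 4)
        m = d.compute_metrics(scores, labels)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.6)
        assert m.balanced_accuracy == pytest.approx(0.7)

    def test_balanced_accuracy_identity_on_enumerated_confusions(self):
        for tp, fn, tn, fp in [(1, 1, 1, 1), (5, 0, 3, 2), (2, 3, 4, 1)]:
            labels = np.array([1] * (tp + fn) + [0] * (tn + fp))
            scores = np.concatenate(
                [np.full(tp, 0.9), np.full(fn, 0.1), np.full(tn, 0.1), np.full(fp, 0.9)]
            )
            m = d.compute_metrics(scores, labels)
            assert m.balanced_accuracy == pytest.approx(
                (m.sensitivity + m.specificity) / 2
            )

    def test_limiting_aucs(self):
        labels = np.array([0, 0, 1, 1])
        assert d.compute_metrics(np.array([0.1, 0.2, 0.8, 0.9]), labels).auc == 1.0
        assert d.compute_metrics(np.full(4, 0.5), labels).auc == 0.5

    def test_auc_matches_mann_whitney_pairwise_count(self, rng):
        # brute-force oracle: AUC = P(score_pos > score_neg) + 0.5 P(tie)
        labels = rng.integers(0, 2, size=150)
        labels[:2] = [0, 1]
        scores = np.round(rng.uniform(size=150), 2)  # ties likely
        pos, neg = scores[labels == 1], scores[labels == 0]
        gt = np.sum(pos[:, None] > neg[None, :])
        ties = np.sum(pos[:, None] == neg[None, :])
        oracle = (gt + 0.5 * ties) / (len(pos) * len(neg))
        m = d.compute_metrics(scores, labels)
        assert m.auc == pytest.approx(oracle, abs=1e-12)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValidationError):
            d.compute_metrics(np.array([0.1, 0.9]), np.array([1, 1]))
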