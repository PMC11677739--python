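import numpy as np
import pytest

from massdesc.classify import (
    MLPConfig,
    accuracy_from_confusion,
    balanced_accuracy,
    confusion,
    cross_validate,
    roc_auc,
    train_mlp,
)


def blobs(n_per_class=30, n_classes=4, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        center = np.array([c * sep, (c % 2) * sep])
        X.append(rng.normal(center, 1.0, (n_per_class, 2)))
        y.append(np.full(n_per_class, c + 2))
    return np.vstack(X), np.concatenate(y)


class TestTrainMLP:
    def test_separable_blobs_high_training_accuracy(self):
        X, y = blobs()
        model = train_mlp(X, y, MLPConfig(seed=1))
        assert (model.predict(X) == y).mean() >= 0.95

    def test_deterministic_given_seed(self):
        X, y = blobs(seed=2)
        p1 = train_mlp(X, y, MLPConfig(seed=7)).predict(X)
        p2 = train_mlp(X, y, MLPConfig(seed=7)).predict(X)
        assert np.array_equal(p1, p2)

    def test_constant_features_no_signal(self):
        rng = np.random.default_rng(0)
        X = np.ones((80, 3))
        y = np.array([0] * 60 + [1] * 20)
        model = train_mlp(X, y, MLPConfig(seed=0, epochs=100))
        acc = (model.predict(X) == y).mean()
        assert acc == pytest.approx(0.75, abs=0.05)  # majority-class rate

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_mlp(np.ones((10, 2)), np.zeros(10), MLPConfig())


class TestCrossValidate:
    def test_perfect_feature_is_perfect(self):
        rng = np.random.default_rng(0)
        y = np.repeat([2, 3, 4, 5], 30)
        X = np.column_stack([y.astype(float), rng.normal(0, 0.01, y.size)])
        rep = cross_validate(X, y, MLPConfig(seed=1), k=5, seed=1)
        assert rep.accuracy == 1.0 and rep.accuracy_sd == 0.0
        assert rep.balanced_accuracy == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (120, 3))
        accs = []
        for rep_seed in range(5):
            y = rng.permutation(np.repeat([0, 1, 2, 3], 30))
            rep = cross_validate(X, y, MLPConfig(seed=rep_seed, epochs=120), k=3, seed=rep_seed)
            accs.append(rep.accuracy)
        assert 0.10 <= np.mean(accs) <= 0.45  # chance level is 0.25

    def test_report_schema_complete(self):
        X, y = blobs(n_per_class=12)
        rep = cross_validate(X, y, MLPConfig(seed=0, epochs=120), k=3, seed=0)
        assert rep.fold_accuracy.size == 3
        assert rep.confusion.shape == (4, 4)
        row_sums = rep.confusion_normalized.sum(axis=1)
        assert np.allclose(row_sums[rep.confusion.sum(axis=1) > 0], 1.0)
        assert 0 <= rep.auc <= 1

    def test_folds_degrade_gracefully(self, caplog):
        X, y = blobs(n_per_class=4)
        with caplog.at_level("WARNING"):
            rep = cross_validate(X, y, MLPConfig(seed=0, epochs=50), k=10, seed=0)
        assert rep.fold_accuracy.size == 4
        assert "reducing folds" in caplog.text

    def test_k_below_two_rejected(self):
        X, y = blobs(n_per_class=5)
        with pytest.raises(ValueError):
            cross_validate(X, y, MLPConfig(), k=1)


class TestMetrics:
    def test_balanced_accuracy_arithmetic(self):
        assert balanced_accuracy(np.array([[8, 2], [4, 6]])) == pytest.approx(0.7)

    def test_perfect_predictions_give_one(self):
        y = np.repeat([0, 1, 2, 3], 10)
        assert balanced_accuracy(confusion(y, y)) == 1.0

    def test_random_binary_predictions_near_half(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(20):
            y = rng.integers(0, 2, 200)
            pred = rng.integers(0, 2, 200)
            vals.append(balanced_accuracy(confusion(y, pred)))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.07)

    def test_class_duplication_invariance(self):
        conf = np.array([[8, 2], [4, 6]])
        doubled = conf.copy()
        doubled[0] *= 3  # duplicate every sample of class 0
        assert balanced_accuracy(conf) == pytest.approx(balanced_accuracy(doubled))

    def test_accuracy_is_trace_over_total(self):
        conf = np.array([[5, 1, 0], [2, 7, 1], [0, 0, 4]])
        assert accuracy_from_confusion(conf) == np.trace(conf) / conf.sum()

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.zeros((2, 2)))


class TestRocAuc:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0

    def test_sign_reversal_symmetry(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        s = rng.random(100)
        assert roc_auc(s, y) + roc_auc(1 - s, y) == pytest.approx(1.0)

    def test_scores_independent_of_labels_near_half(self):
        rng = np.random.default_rng(1)
        vals = [roc_auc(rng.random(300), rng.integers(0, 2, 300)) for _ in range(20)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.2, 0.4]), np.array([1, 1]))
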