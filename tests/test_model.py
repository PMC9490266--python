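"""Architecture conformance, training behavior, metrics, cross-validation."""

import warnings

import numpy as np
import pytest

import spikealpha as sa
from spikealpha.model import ModelConfig
from spikealpha.training import TrainConfig, _fit_eval


def _toy_data(n_per_class=10, seed=0, strength=40.0):
    """Linearly separable 3-class epochs: each class drives a distinct
    channel group with a strong 11 Hz rhythm."""
    rng = np.random.default_rng(seed)
    t = np.arange(128) / 128.0
    X, y = [], []
    groups = [(0, 1, 2, 3), (4, 5, 6, 7), (8, 9, 10, 11)]
    for cls, chans in enumerate(groups):
        for _ in range(n_per_class):
            e = rng.normal(scale=2.0, size=(14, 128))
            e[list(chans)] += strength * np.sin(
                2 * np.pi * 11 * t + rng.uniform(0, 2 * np.pi)
            )
            X.append(e)
            y.append(cls)
    return np.asarray(X), np.asarray(y)


class TestArchitecture:
    def test_shape_trace_default(self):
        trace = sa.build_model(seed=0).shape_trace()
        assert trace["block2"] == (8, 14, 128)
        assert trace["block3"] == (16, 1, 128)
        assert trace["block3_pool"] == (16, 1, 32)
        assert trace["block4"] == (16, 1, 32)
        assert trace["block4_pool"] == (16, 1, 4)
        assert trace["flatten"] == (64,)
        assert trace["dense"] == (3,)

    def test_probabilities_normalized(self, rng):
        model = sa.build_model(seed=0)
        probs = model.forward(rng.normal(size=(5, 14, 128)))
        assert probs.shape == (5, 3)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_ann_variant_same_trace(self):
        spike = sa.build_model(variant="spike", seed=0).shape_trace()
        ann = sa.build_model(variant="ann", seed=0).shape_trace()
        assert spike == ann

    def test_invalid_pooling_config_rejected(self):
        with pytest.raises(ValueError):
            sa.SpikeEEGNet(ModelConfig(input_shape=(14, 100)), rng=0)

    def test_invalid_depth_multiplier_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            ModelConfig(block3_filters=12)

    def test_eval_determinism(self, rng):
        model = sa.build_model(seed=0)
        x = rng.normal(size=(3, 14, 128))
        a = model.forward(x, rng=np.random.default_rng(7))
        b = model.forward(x, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = sa.build_model(seed=3)
        x = rng.normal(size=(4, 14, 128))
        path = tmp_path / "model.npz"
        model.save(path)
        clone = sa.SpikeEEGNet.load(path)
        np.testing.assert_array_equal(
            model.forward(x, rng=np.random.default_rng(1)),
            clone.forward(x, rng=np.random.default_rng(1)),
        )


class TestTraining:
    def test_separable_data_reaches_full_training_accuracy(self):
        X, y = _toy_data()
        model = sa.build_model(seed=1)
        tc = TrainConfig(epochs=50, seed=1)
        sa.train(model, X, y, tc)
        preds = model.predict(X, rng=np.random.default_rng(2))
        assert (preds == y).mean() == 1.0

    def test_zero_learning_rate_freezes_weights(self):
        X, y = _toy_data(n_per_class=4)
        model = sa.build_model(seed=1)
        before = [p.copy() for p in model.parameters]
        sa.train(model, X, y, TrainConfig(learning_rate=0.0, epochs=3, seed=0))
        for b, p in zip(before, model.parameters):
            np.testing.assert_array_equal(b, p)

    def test_same_seed_identical_history(self):
        X, y = _toy_data(n_per_class=4)
        histories = []
        for _ in range(2):
            model = sa.build_model(seed=2)
            histories.append(sa.train(model, X, y, TrainConfig(epochs=3, seed=9)))
        assert histories[0] == histories[1]

    def test_single_class_rejected(self):
        X, y = _toy_data(n_per_class=4)
        with pytest.raises(ValueError, match="class"):
            sa.train(sa.build_model(seed=0), X[y == 0], y[y == 0], TrainConfig(epochs=1))


class TestEvaluate:
    def test_perfect_predictions(self):
        truth = np.array([0, 1, 2] * 10)
        rep = sa.evaluate(truth, truth)
        assert rep.summary() == {
            "accuracy": 1.0, "precision": 1.0, "recall": 1.0, "f1": 1.0
        }

    def test_confusion_matrix_example(self):
        # confusion [[8,2,0],[1,7,2],[0,1,9]]: accuracy = trace 24 / total 30
        cm = np.array([[8, 2, 0], [1, 7, 2], [0, 1, 9]])
        truth, preds = [], []
        for i in range(3):
            for j in range(3):
                truth += [i] * cm[i, j]
                preds += [j] * cm[i, j]
        rep = sa.evaluate(np.array(preds), np.array(truth))
        assert rep.accuracy == pytest.approx(0.8)
        np.testing.assert_array_equal(rep.confusion, cm)
        assert rep.confusion.sum(axis=1).tolist() == [10, 10, 10]

    def test_never_predicted_class_contributes_zero(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        preds = np.array([0, 0, 1, 1, 1, 0])  # class 2 never predicted
        with pytest.warns(UserWarning, match="never predicted"):
            rep = sa.evaluate(preds, truth)
        per_class_precision = [1.0 * 2 / 3, 2 / 3, 0.0]
        assert rep.precision == pytest.approx(np.mean(per_class_precision))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            sa.evaluate(np.array([0, 1]), np.array([0, 1, 2]))


class TestCrossValidation:
    @pytest.mark.parametrize(
        "n,expected",
        [(504, [101, 101, 101, 101, 100]), (432, [87, 87, 86, 86, 86])],
    )
    def test_fold_test_sizes(self, n, expected, monkeypatch):
        sizes = []

        def stub(cfg, X, y, tr_idx, te_idx, tc, fold_seed):
            sizes.append(len(te_idx))
            return sa.evaluate(y[te_idx], y[te_idx])

        monkeypatch.setattr("spikealpha.training._fit_eval", stub)
        y = np.arange(n) % 3
        X = np.zeros((n, 1))
        rep = sa.crossvalidate(X, y, TrainConfig(seed=0))
        assert sorted(sizes, reverse=True) == expected
        assert rep.accuracy == 1.0  # perfect stub -> mean accuracy 1.0

    def test_report_schema_and_confusion_totals(self, monkeypatch):
        def stub(cfg, X, y, tr_idx, te_idx, tc, fold_seed):
            rng = np.random.default_rng(fold_seed)
            return sa.evaluate(rng.integers(0, 3, len(te_idx)), y[te_idx])

        monkeypatch.setattr("spikealpha.training._fit_eval", stub)
        y = np.arange(90) % 3
        rep = sa.crossvalidate(np.zeros((90, 1)), y, TrainConfig(seed=0))
        assert len(rep.per_fold) == 5
        assert set(rep.per_fold[0]) == {"accuracy", "precision", "recall", "f1"}
        assert rep.confusion.sum() == 90

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            sa.crossvalidate(np.zeros((3, 1)), np.array([0, 1, 2]), TrainConfig())

    def test_holdout_mode_single_split(self, monkeypatch):
        monkeypatch.setattr(
            "spikealpha.training._fit_eval",
            lambda cfg, X, y, tr, te, tc, fold_seed: sa.evaluate(y[te], y[te]),
        )
        y = np.arange(60) % 3
        rep = sa.crossvalidate(np.zeros((60, 1)), y, TrainConfig(seed=0), holdout=True)
        assert len(rep.per_fold) == 1
        assert rep.confusion.sum() == 12  # 20% of 60

    def test_spike_and_ann_report_identical_schema(self):
        """Both variants consume the same dataset and emit the same report
        structure (small real run)."""
        X, y = _toy_data(n_per_class=5, strength=40.0)
        tc = TrainConfig(epochs=2, folds=2, seed=0)
        reports = {
            v: sa.crossvalidate(X, y, tc, ModelConfig(variant=v)) for v in ("spike", "ann")
        }
        assert set(reports["spike"].summary()) == set(reports["ann"].summary())
        assert reports["spike"].confusion.shape == reports["ann"].confusion.shape
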