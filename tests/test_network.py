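"""Random splits and the scaled-conjugate-gradient classifier."""

import numpy as np
import pytest

from periprog.classifier import SplitSpec, random_split
from periprog.network import (
    NetworkModel,
    TrainConfig,
    predict_proba,
    train_network,
)


class TestRandomSplit:
    def test_default_spec_realizes_70_15_15(self):
        tr, va, te = random_split(100)
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_partition_is_disjoint_and_exhaustive(self):
        tr, va, te = random_split(103, SplitSpec(seed=7))
        allidx = np.concatenate([tr, va, te])
        assert len(allidx) == 103
        assert len(np.unique(allidx)) == 103

    def test_deterministic_given_seed(self):
        a = random_split(50, SplitSpec(seed=3))
        b = random_split(50, SplitSpec(seed=3))
        for x, y in zip(a, b):
            assert np.array_equal(x, y)
        c = random_split(50, SplitSpec(seed=4))
        assert not all(np.array_equal(x, y) for x, y in zip(a, c))

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            SplitSpec(0.5, 0.2, 0.2)
        with pytest.raises(ValueError):
            SplitSpec(-0.1, 0.6, 0.5)
        with pytest.raises(ValueError):
            random_split(2)


def _zero_model(n_in=3, hidden=(2,)):
    sizes = (n_in, *hidden, 1)
    weights = [
        (np.zeros((a, b)), np.zeros(b)) for a, b in zip(sizes[:-1], sizes[1:])
    ]
    return NetworkModel(sizes, weights, np.zeros(n_in), np.ones(n_in))


class TestPredict:
    def test_zero_weight_network_outputs_half(self):
        model = _zero_model()
        p = predict_proba(model, np.random.default_rng(0).random((10, 3)))
        np.testing.assert_allclose(p, 0.5)

    def test_monotone_in_positive_weight_logistic_unit(self):
        model = NetworkModel(
            (1, 1), [(np.array([[2.0]]), np.array([0.0]))], np.zeros(1), np.ones(1)
        )
        xs = np.linspace(-3, 3, 11)[:, None]
        p = predict_proba(model, xs)
        assert np.all(np.diff(p) > 0)

    def test_batch_and_single_row_agree(self):
        rng = np.random.default_rng(1)
        model = _zero_model(4, (3,))
        model.weights = [
            (rng.standard_normal(w.shape), rng.standard_normal(b.shape))
            for w, b in model.weights
        ]
        X = rng.random((5, 4))
        batch = predict_proba(model, X)
        singles = np.array([predict_proba(model, x) for x in X])
        np.testing.assert_allclose(batch, singles)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predict_proba(_zero_model(3), np.zeros((2, 5)))


class TestTraining:
    def test_linearly_separable_toy_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        X0 = rng.normal((-2, -2), 0.5, size=(60, 2))
        X1 = rng.normal((2, 2), 0.5, size=(60, 2))
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(60), np.ones(60)]
        model = train_network(X, y, config=TrainConfig(max_iter=200, seed=0))
        acc = ((predict_proba(model, X) >= 0.5) == y).mean()
        assert acc == 1.0

    def test_xor_clusters_solved_with_ten_hidden_units(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        X = np.vstack([rng.normal(c, 0.08, size=(50, 2)) for c in centers])
        y = np.r_[np.zeros(100), np.ones(100)]
        solved = 0
        for seed in (0, 1, 2):
            model = train_network(
                X, y, config=TrainConfig(hidden_sizes=(10,), max_iter=400, seed=seed)
            )
            acc = ((predict_proba(model, X) >= 0.5) == y).mean()
            solved += acc > 0.95
        assert solved >= 2

    def test_cross_entropy_never_increases(self):
        rng = np.random.default_rng(2)
        X = rng.random((80, 5))
        y = (X[:, 0] > 0.5).astype(float)
        model = train_network(X, y, config=TrainConfig(max_iter=60, seed=0))
        losses = model.trace["train_loss"]
        assert losses[-1] <= losses[0]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_training_is_bit_reproducible(self):
        rng = np.random.default_rng(3)
        X = rng.random((60, 4))
        y = (X.sum(axis=1) > 2).astype(float)
        cfg = TrainConfig(max_iter=50, seed=9)
        m1 = train_network(X, y, config=cfg)
        m2 = train_network(X, y, config=cfg)
        for (w1, b1), (w2, b2) in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2) and np.array_equal(b1, b2)

    def test_single_class_and_nonfinite_rejected(self):
        X = np.random.default_rng(4).random((10, 3))
        with pytest.raises(ValueError):
            train_network(X, np.zeros(10))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_network(X, np.r_[np.zeros(5), np.ones(5)])

    def test_validation_early_stopping_returns_best_weights(self):
        rng = np.random.default_rng(5)
        X = rng.random((200, 6))
        y = (X[:, 0] + 0.3 * rng.standard_normal(200) > 0.5).astype(float)
        model = train_network(
            X[:150], y[:150], X[150:], y[150:],
            TrainConfig(max_iter=500, patience=5, seed=0),
        )
        assert model.trace["stop_reason"] in ("early_stop", "max_iter", "gradient")
        assert len(model.trace["val_loss"]) >= 1


def test_model_json_round_trip(tmp_path):
    from periprog.network import load_model_json, save_model_json

    rng = np.random.default_rng(6)
    X = rng.random((40, 3))
    y = (X[:, 0] > 0.5).astype(float)
    model = train_network(X, y, config=TrainConfig(max_iter=30, seed=0))
    path = tmp_path / "model.json"
    save_model_json(model, path)
    loaded = load_model_json(path)
    np.testing.assert_allclose(
        predict_proba(loaded, X), predict_proba(model, X), rtol=1e-12
    )
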