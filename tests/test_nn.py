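"""Attention-CNN classifier: shapes, gradients, attention contract, training."""

import numpy as np
import pytest

from pacnn.nn import (
    ModelConfig,
    PacnnClassifier,
    PacnnModel,
    attention_forward,
    build_model,
    init_params,
    loss_and_grads,
    predict_proba,
    train,
)

TINY = dict(
    input_length=24, conv_layers=2, filters=6, kernel_size=3, pool_size=2,
    attention_units=5, dense_units=8, batch_size=8, max_epochs=12,
)


def tiny_cfg(**kw) -> ModelConfig:
    return ModelConfig(**{**TINY, **kw})


class TestConfig:
    def test_stage_lengths(self):
        cfg = ModelConfig(input_length=144)
        assert cfg.stage_lengths() == [72, 36, 18]
        assert cfg.n_positions == 18

    def test_pool_larger_than_positions_names_stage(self):
        with pytest.raises(ValueError, match="stage 2"):
            ModelConfig(input_length=6, conv_layers=3, pool_size=4)

    def test_negative_sizes_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_length=0)
        with pytest.raises(ValueError):
            ModelConfig(input_length=10, learning_rate=0)

    def test_seeded_init_is_reproducible(self):
        a = init_params(tiny_cfg(seed=5))
        b = init_params(tiny_cfg(seed=5))
        assert a.keys() == b.keys()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
        c = init_params(tiny_cfg(seed=6))
        assert any(not np.array_equal(a[k], c[k]) for k in a)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        cfg = tiny_cfg(dtype="float64", seed=3)
        params = init_params(cfg)
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (5, cfg.input_length))
        y = rng.integers(0, 2, 5)
        _, grads, _ = loss_and_grads(params, cfg, X, y)
        eps = 1e-6
        for k in params:
            flat, gflat = params[k].ravel(), grads[k].ravel()
            for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _, _ = loss_and_grads(params, cfg, X, y)
                flat[i] = orig - eps
                lm, _, _ = loss_and_grads(params, cfg, X, y)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert gflat[i] == pytest.approx(num, rel=1e-4, abs=1e-8), k


class TestAttention:
    def test_single_position_passes_through(self):
        model = build_model(tiny_cfg(seed=0))
        h = np.random.default_rng(1).normal(size=(1, TINY["filters"]))
        trace = attention_forward(model, h)
        np.testing.assert_allclose(trace.alpha, [1.0])
        np.testing.assert_allclose(trace.s, h[0])

    def test_identical_inputs_get_uniform_weights(self):
        model = build_model(tiny_cfg(seed=0))
        row = np.random.default_rng(2).normal(size=TINY["filters"])
        h = np.tile(row, (4, 1))
        trace = attention_forward(model, h)
        np.testing.assert_allclose(trace.alpha, np.full(4, 0.25), atol=1e-12)
        np.testing.assert_allclose(trace.s, row, atol=1e-12)

    def test_weights_positive_normalized_and_summary_convex(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            model = build_model(tiny_cfg(seed=seed))
            h = rng.normal(size=(7, TINY["filters"]))
            trace = attention_forward(model, h)
            assert (trace.alpha > 0).all()
            assert trace.alpha.sum() == pytest.approx(1.0, abs=1e-6)
            # s lies coordinate-wise within [min, max] over positions
            assert (trace.s >= h.min(axis=0) - 1e-12).all()
            assert (trace.s <= h.max(axis=0) + 1e-12).all()
            np.testing.assert_allclose(trace.s, trace.alpha @ h, atol=1e-12)


def _separable_data(n=24, length=24, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 0.05, (n, length))
    y = np.arange(n) % 2
    X[y == 1, :] += 0.9  # large offset: trivially separable
    return X, y


class TestTraining:
    def test_learns_separable_data(self):
        X, y = _separable_data()
        clf = PacnnClassifier(**tiny_cfg(seed=1).__dict__)
        clf.fit(X, y)
        assert (clf.predict(X) == y).all()
        assert clf.model.history[-1]["accuracy"] == 1.0

    def test_same_seed_same_loss(self):
        X, y = _separable_data()
        cfg = tiny_cfg(seed=4)
        m1 = train(build_model(cfg), X, y)
        m2 = train(build_model(cfg), X, y)
        assert m1.history[-1]["loss"] == m2.history[-1]["loss"]
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_single_class_rejected(self):
        X, _ = _separable_data()
        with pytest.raises(ValueError, match="both classes"):
            train(build_model(tiny_cfg()), X, np.zeros(len(X), dtype=int))

    def test_loss_decreases_in_aggregate(self):
        X, y = _separable_data(seed=5)
        model = train(build_model(tiny_cfg(seed=2)), X, y)
        losses = [h["loss"] for h in model.history]
        assert losses[-1] < losses[0]


class TestPrediction:
    @pytest.fixture()
    def fitted(self):
        X, y = _separable_data()
        return PacnnClassifier(**tiny_cfg(seed=1).__dict__).fit(X, y), X

    def test_rows_are_probabilities(self, fitted):
        clf, X = fitted
        probs = clf.predict_proba(X)
        assert probs.shape == (len(X), 2)
        assert ((probs > 0) & (probs < 1)).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_rows_identical(self, fitted):
        clf, X = fitted
        dup = np.vstack([X[0], X[0]])
        probs = clf.predict_proba(dup)
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_zero_vector_is_finite(self, fitted):
        clf, X = fitted
        probs = clf.predict_proba(np.zeros((1, X.shape[1])))
        assert np.isfinite(probs).all()
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_length_mismatch_rejected(self, fitted):
        clf, X = fitted
        with pytest.raises(ValueError, match="width"):
            clf.predict_proba(np.zeros((2, X.shape[1] + 1)))

    def test_checkpoint_round_trip(self, fitted, tmp_path):
        clf, X = fitted
        path = tmp_path / "model.npz"
        clf.model.save(path)
        reloaded = PacnnModel.load(path)
        np.testing.assert_array_equal(
            predict_proba(reloaded, X), clf.predict_proba(X)
        )
        assert reloaded.config == clf.model.config
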