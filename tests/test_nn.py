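"""Deep-classifier contracts: gradients, length invariance, persistence."""

import numpy as np
import pytest

from tippingews import (
    EWSNetConfig,
    LSTMFCNClassifier,
    TrainingConfig,
    load_model,
    save_model,
)
from tippingews.nn import CheckpointError
from tippingews.nn.model import _pad_stack, evaluate, train_ewsnet


@pytest.fixture
def tiny_model(tiny_net_config):
    return LSTMFCNClassifier(tiny_net_config, seed=0, dtype=np.float64)


class TestConfig:
    def test_three_blocks_enforced(self):
        with pytest.raises(ValueError):
            EWSNetConfig(conv_filters=(8, 8), conv_kernels=(3, 3))

    def test_final_width_is_three(self):
        with pytest.raises(ValueError):
            EWSNetConfig(fc_sizes=(16, 4))

    def test_gap_dimension_is_last_filter_count(self):
        m = LSTMFCNClassifier(EWSNetConfig(conv_filters=(8, 16, 12), lstm_units=4), seed=0)
        x = np.random.default_rng(0).standard_normal((2, 50))
        m.forward(x, train=False)
        assert m.gap.forward(np.zeros((2, 12, 50)), train=False).shape == (2, 12)


class TestForward:
    def test_probability_simplex(self, tiny_model, rng):
        probs = tiny_model.forward(rng.standard_normal((5, 60)), train=False)
        assert probs.shape == (5, 3)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_length_invariance(self, tiny_model, rng):
        """The same weights accept 200- and 400-point series."""
        for t in (200, 400):
            probs = tiny_model.forward(rng.standard_normal((3, t)), train=False)
            assert probs.shape == (3, 3)

    def test_parameter_count_independent_of_length(self, tiny_net_config):
        m = LSTMFCNClassifier(tiny_net_config, seed=0)
        n0 = m.n_parameters()
        m.forward(np.zeros((1, 333)), train=False)
        assert m.n_parameters() == n0

    def test_too_short_input_errors(self, tiny_model):
        with pytest.raises(ValueError, match="minimum"):
            tiny_model.forward(np.zeros((1, 4)), train=False)

    def test_zeroed_head_gives_uniform(self, tiny_model, rng):
        tiny_model.fc2.W.value[...] = 0.0
        tiny_model.fc2.b.value[...] = 0.0
        probs = tiny_model.forward(rng.standard_normal((2, 40)), train=False)
        np.testing.assert_allclose(probs, 1 / 3, atol=1e-12)

    def test_padded_batch_equals_individual(self, tiny_model, rng):
        """Masked ragged batching is exactly equivalent to per-series passes."""
        series = [rng.standard_normal(n) for n in (30, 45, 25)]
        xb, lens = _pad_stack(series)
        batched = tiny_model.forward(xb, train=False, lengths=lens)
        single = np.stack([tiny_model.forward(s[None, :], train=False)[0] for s in series])
        np.testing.assert_allclose(batched, single, atol=1e-12)


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_model, rng):
        """Analytic gradients of the full masked network agree with central
        finite differences."""
        m = tiny_model
        series = [rng.standard_normal(n) for n in (24, 30, 30, 18)]
        xb, lens = _pad_stack(series)
        onehot = np.eye(3)[[0, 1, 2, 1]]

        def loss_at():
            probs = m.forward(xb, train=True, lengths=lens)
            return float(-np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1)))

        for p in m.params:
            p.grad[...] = 0.0
        m.forward(xb, train=True, lengths=lens)
        m.backward_cross_entropy(onehot)
        eps = 1e-6
        for p in m.params:
            flat, grad = p.value.ravel(), p.grad.ravel()
            for j in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[j]
                flat[j] = old + eps
                lp = loss_at()
                flat[j] = old - eps
                lm = loss_at()
                flat[j] = old
                num = (lp - lm) / (2 * eps)
                if abs(num) + abs(grad[j]) > 1e-7:
                    rel = abs(num - grad[j]) / (abs(num) + abs(grad[j]))
                    assert rel < 1e-4


class TestTraining:
    def test_learns_separable_means(self, tiny_net_config, rng):
        """Classes separable by level are learned to perfect validation
        accuracy within 10 epochs."""
        series, labels = [], []
        for lbl, mu in zip(["C.T.", "S.T.", "N.T."], [0.0, 1.5, 3.0]):
            for _ in range(20):
                series.append(mu + 0.1 * rng.standard_normal(40))
                labels.append(lbl)
        m = LSTMFCNClassifier(tiny_net_config, seed=1)
        tc = TrainingConfig(epochs=10, batch_size=8, learning_rate=3e-3, seed=1)
        hist = train_ewsnet(m, series, labels, tc)
        assert len(hist["val_accuracy"]) == 10
        assert max(hist["val_accuracy"]) == 1.0

    def test_history_length_matches_epochs(self, tiny_net_config, rng):
        series = [rng.standard_normal(30) for _ in range(12)]
        labels = (["C.T.", "S.T.", "N.T."] * 4)[:12]
        hist = train_ewsnet(
            LSTMFCNClassifier(tiny_net_config, seed=0),
            series,
            labels,
            TrainingConfig(epochs=3, batch_size=4, seed=0),
        )
        assert len(hist["loss"]) == 3

    def test_same_seed_identical_weights(self, tiny_net_config, rng):
        series = [rng.standard_normal(30) for _ in range(12)]
        labels = (["C.T.", "S.T.", "N.T."] * 4)[:12]
        weights = []
        for _ in range(2):
            m = LSTMFCNClassifier(tiny_net_config, seed=5)
            train_ewsnet(m, series, labels, TrainingConfig(epochs=2, batch_size=4, seed=5))
            weights.append(np.concatenate([p.value.ravel() for p in m.params]))
        np.testing.assert_array_equal(weights[0], weights[1])

    def test_invalid_training_config(self):
        with pytest.raises(ValueError):
            TrainingConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainingConfig(n_trials=0)


class TestPersistence:
    def test_roundtrip_identical_predictions(self, tiny_model, rng, tmp_path):
        probe = rng.standard_normal((4, 50))
        before = tiny_model.forward(probe, train=False)
        save_model(tiny_model, tmp_path / "ckpt")
        loaded = load_model(tmp_path / "ckpt")
        after = loaded.forward(probe, train=False)
        np.testing.assert_allclose(after, before, atol=1e-6)

    def test_corrupt_checkpoint_errors(self, tiny_model, tmp_path):
        save_model(tiny_model, tmp_path / "ckpt")
        (tmp_path / "ckpt" / "weights.npz").write_bytes(b"not a zipfile")
        with pytest.raises(CheckpointError):
            load_model(tmp_path / "ckpt")

    def test_config_mismatch_errors(self, tiny_model, tmp_path):
        save_model(tiny_model, tmp_path / "ckpt")
        with pytest.raises(CheckpointError, match="checkpoint"):
            load_model(tmp_path / "ckpt", config=EWSNetConfig())

    def test_missing_checkpoint_errors(self, tmp_path):
        with pytest.raises(CheckpointError):
            load_model(tmp_path / "nothing")
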