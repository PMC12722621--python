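"""Network architecture, parameter counts, training protocol, evaluation."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import shortcut_audit as sa
from shortcut_audit.cnn import Conv3D, Dense, rank_auc


def _enumerate_parameters(network: sa.Network) -> int:
    """Independent oracle: sum array sizes over the built layers."""
    return sum(
        layer.weight.size + layer.bias.size for layer in network.parameters()
    )


class TestArchitecture:
    def test_paper_input_tensor_shapes_halve_to_10_15_16(self):
        spec = sa.NetworkSpec(input_shape=(160, 240, 256))
        assert tuple(n // 16 for n in spec.input_shape) == (10, 15, 16)
        assert spec.flat_features == 10 * 15 * 16 * 8

    def test_small_input_preflatten_64_features(self):
        spec = sa.NetworkSpec(input_shape=(32, 32, 32))
        assert spec.flat_features == 2 * 2 * 2 * 8

    def test_indivisible_input_raises(self):
        with pytest.raises(ValueError, match="not divisible"):
            sa.NetworkSpec(input_shape=(30, 30, 30))

    def test_forward_halves_each_block(self, tiny_network):
        x = np.random.default_rng(0).uniform(0, 1, (2, 16, 16, 16)).astype(np.float32)
        logits = tiny_network.forward(x)
        assert logits.shape == (2, 2)

    def test_softmax_probabilities_sum_to_one(self, tiny_network):
        x = np.random.default_rng(1).uniform(0, 1, (3, 16, 16, 16)).astype(np.float32)
        proba = tiny_network.predict_proba(x)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert (proba >= 0).all()


class TestParameterCount:
    def test_paper_network_has_0_3_million_parameters(self):
        n = sa.count_parameters(sa.NetworkSpec(input_shape=(160, 240, 256)))
        assert n == 319_626
        assert round(n / 1e6, 1) == 0.3

    def test_small_input_count(self):
        assert sa.count_parameters(sa.NetworkSpec(input_shape=(32, 32, 32))) == 13_450

    def test_single_dense_layer_hand_count(self):
        layer = Dense(2, 2, np.random.default_rng(0))
        assert layer.n_params == 6

    @pytest.mark.parametrize("shape,blocks,channels", [
        ((32, 32, 32), 4, 8),
        ((16, 16, 16), 4, 8),
        ((32, 64, 32), 4, 8),
        ((16, 16, 16), 2, 4),
        ((32, 32, 32), 3, 6),
    ])
    def test_closed_form_matches_built_network(self, shape, blocks, channels):
        spec = sa.NetworkSpec(input_shape=shape, n_blocks=blocks, channels=channels)
        net = sa.build_network(spec, np.random.default_rng(0))
        assert sa.count_parameters(spec) == _enumerate_parameters(net)


class TestGradients:
    def test_conv_backward_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        layer = Conv3D(1, 2, 2, rng)
        x = rng.uniform(0, 1, (1, 1, 4, 4, 4)).astype(np.float64)
        out = layer.forward(x, cache=True)
        dout = rng.normal(size=out.shape)
        dx = layer.backward(dout)
        eps = 1e-5
        for idx in [(0, 0, 1, 2, 3), (0, 0, 0, 0, 0), (0, 0, 3, 3, 3)]:
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            num = (np.sum(layer.forward(xp) * dout) - np.sum(layer.forward(xm) * dout)) / (2 * eps)
            assert num == pytest.approx(dx[idx], rel=1e-3, abs=1e-5)


class TestTraining:
    def test_separable_toy_reaches_perfect_validation(self, separable_data):
        x, y = separable_data
        net = sa.build_network(sa.NetworkSpec((16, 16, 16)), np.random.default_rng(2))
        res = sa.train_session(
            net, x[:30], y[:30], x[30:], y[30:],
            sa.TrainingSpec(epochs=30, init_seed=0),
        )
        assert res.validation_accuracy == 1.0
        assert res.converged

    def test_biases_nonpositive_after_training(self, separable_data):
        x, y = separable_data
        net = sa.build_network(sa.NetworkSpec((16, 16, 16)), np.random.default_rng(3))
        sa.train_session(net, x[:30], y[:30], x[30:], y[30:],
                         sa.TrainingSpec(epochs=3, init_seed=1))
        assert net.max_bias() <= 0.0

    def test_shuffled_labels_stay_at_chance(self, separable_data):
        """Label-shuffled (null) training hovers near 50% validation
        accuracy across seeds."""
        x, y = separable_data
        rng = np.random.default_rng(99)
        in_band = 0
        n_seeds = 10
        for seed in range(n_seeds):
            y_train = rng.permutation(y[:30])
            # balanced validation labels so chance level is exactly 1/2
            y_val = rng.permutation(np.array([0] * 5 + [1] * 5))
            net = sa.build_network(sa.NetworkSpec((16, 16, 16)),
                                   np.random.default_rng(seed))
            res = sa.train_session(
                net, x[:30], y_train, x[30:], y_val,
                sa.TrainingSpec(epochs=3, init_seed=seed),
            )
            in_band += 0.35 <= res.validation_accuracy <= 0.65
        assert in_band >= 0.9 * n_seeds


class TestConvergenceScreen:
    def _result(self, val_acc, loss=0.5):
        return sa.RunResult(
            "A2", 0, 0, 0, 0, False, val_acc, loss, [], np.array([]),
            np.array([]), np.array([]),
        )

    def test_below_threshold_excluded(self):
        assert not sa.is_converged(self._result(0.50))

    def test_above_threshold_included(self):
        assert sa.is_converged(self._result(0.80))

    def test_nan_loss_always_excluded(self):
        assert not sa.is_converged(self._result(0.95, loss=float("nan")))


class TestEvaluate:
    def _run(self, true, pred, scores):
        return sa.RunResult(
            "A2", 0, 0, 0, 0, True, 1.0, 0.1,
            [f"i{k}" for k in range(len(true))],
            np.asarray(true), np.asarray(pred), np.asarray(scores),
        )

    def test_perfect_classifier(self):
        r = self._run([1, 1, 0, 0], [1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        perf = sa.evaluate([r])
        for metric in ("accuracy", "sensitivity", "specificity", "auc"):
            assert getattr(perf, metric).mean == 1.0
        assert perf.accuracy.sd == 0.0  # single session: degenerate interval

    def test_auc_pair_count_oracle(self):
        true = np.array([1, 1, 0, 0])
        assert rank_auc(np.array([0.9, 0.8, 0.7, 0.1]), true) == 1.0
        assert rank_auc(np.array([0.9, 0.8, 0.85, 0.1]), true) == 0.75

    def test_auc_matches_sklearn_on_random_scores(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.integers(0, 2, size=50)
            if len(np.unique(y)) < 2:
                continue
            s = rng.uniform(size=50)
            assert rank_auc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_no_converged_sessions_raise(self):
        r = self._run([1], [1], [0.9])
        r.converged = False
        with pytest.raises(ValueError, match="no converged"):
            sa.evaluate([r])
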