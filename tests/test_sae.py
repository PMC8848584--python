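import numpy as np
import pytest

from spikerhythm.sae import (SAEConfig, SAELayer, decode, encode, encode_stack,
                             init_layer, sae_cost_and_grad, sigmoid,
                             stack_pretrain, train_sae)
from spikerhythm.sae import _pack, _unpack


def numerical_gradient(fun, theta, eps=1e-6):
    """Central finite differences, the independent gradient oracle."""
    g = np.zeros_like(theta)
    for i in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        g[i] = (fun(tp)[0] - fun(tm)[0]) / (2 * eps)
    return g


class TestEncodeDecode:
    def test_zero_weights_give_half_activation(self):
        layer = SAELayer(W1=np.zeros((3, 4)), b1=np.zeros(3),
                         W2=np.zeros((4, 3)), b2=np.zeros(4))
        h = encode(np.ones((2, 4)), layer)
        assert np.all(h == 0.5)

    def test_two_by_two_hand_oracle(self):
        W1 = np.array([[1.0, 2.0], [-1.0, 0.5]])
        b1 = np.array([0.1, -0.2])
        layer = SAELayer(W1=W1, b1=b1, W2=np.zeros((2, 2)), b2=np.zeros(2))
        x = np.array([1.0, -1.0])
        # hand matrix multiply: z = W1 @ x + b1
        z = np.array([1.0 * 1 + 2.0 * (-1) + 0.1, -1.0 * 1 + 0.5 * (-1) - 0.2])
        expected = 1 / (1 + np.exp(-z))
        assert np.allclose(encode(x, layer)[0], expected, rtol=1e-12)

    def test_autoencoding_shape_contract(self, rng):
        layer = init_layer(6, 4, rng)
        x = rng.uniform(size=(5, 6))
        assert decode(encode(x, layer), layer).shape == x.shape

    def test_shape_mismatch_rejected(self, rng):
        layer = init_layer(6, 4, rng)
        with pytest.raises(ValueError, match="width"):
            encode(np.ones((2, 5)), layer)


class TestCostAndGrad:
    def test_penalties_off_reduces_to_mse(self, rng):
        d, h, m = 5, 3, 4
        layer = init_layer(d, h, rng)
        X = rng.uniform(size=(m, d))
        cost, _ = sae_cost_and_grad(_pack(layer), X, d, h, 0.0, 0.0, 0.05)
        Xhat = decode(encode(X, layer), layer)
        assert cost == pytest.approx(0.5 * np.sum((X - Xhat) ** 2) / m, rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        d, h, m = 4, 3, 5
        layer = init_layer(d, h, rng)
        X = rng.uniform(size=(m, d))
        theta = _pack(layer)

        def fun(t):
            return sae_cost_and_grad(t, X, d, h, 0.01, 0.1, 0.05)

        _, g = fun(theta)
        g_num = numerical_gradient(fun, theta)
        assert np.linalg.norm(g - g_num) / np.linalg.norm(g_num) < 1e-6

    def test_sparsity_term_zero_at_target_activation(self):
        d, h, m = 3, 2, 4
        rho = 0.2
        # zero weights with bias = logit(rho) pin every activation at rho
        b1 = np.full(h, np.log(rho / (1 - rho)))
        layer = SAELayer(W1=np.zeros((h, d)), b1=b1,
                         W2=np.zeros((d, h)), b2=np.zeros(d))
        X = np.random.default_rng(0).uniform(size=(m, d))
        c_beta, _ = sae_cost_and_grad(_pack(layer), X, d, h, 0.0, 5.0, rho)
        c_nobeta, _ = sae_cost_and_grad(_pack(layer), X, d, h, 0.0, 0.0, rho)
        assert c_beta == pytest.approx(c_nobeta, abs=1e-12)

    def test_empty_batch_rejected(self, rng):
        layer = init_layer(3, 2, rng)
        with pytest.raises(ValueError, match="empty"):
            sae_cost_and_grad(_pack(layer), np.empty((0, 3)), 3, 2, 0, 0, 0.05)


class TestTraining:
    def test_memorizes_single_repeated_vector(self, rng):
        x = rng.uniform(0.2, 0.8, size=8)
        X = np.tile(x, (4, 1))
        cfg = SAEConfig(layer_sizes=(8, 6, 4), l2_weight=0.0, sparsity_weight=0.0,
                        unsup_epochs=600, seed=0)
        layer = train_sae(X, 6, cfg)
        Xhat = decode(encode(X, layer), layer)
        assert np.mean((X - Xhat) ** 2) < 1e-3

    def test_cost_history_non_increasing(self, rng):
        X = rng.uniform(size=(10, 8))
        cfg = SAEConfig(layer_sizes=(8, 5, 3), unsup_epochs=100, seed=1)
        layer = train_sae(X, 5, cfg)
        h = np.asarray(layer.cost_history)
        assert h[-1] <= h[0]
        assert np.all(np.diff(h) <= 1e-12)

    def test_sparsity_penalty_pulls_activations_toward_target(self, rng):
        X = rng.uniform(size=(20, 10))
        rho = 0.05
        kw = dict(layer_sizes=(10, 8, 4), l2_weight=0.0, unsup_epochs=300, seed=2)
        lay_b = train_sae(X, 8, SAEConfig(sparsity_weight=0.5, sparsity_target=rho, **kw))
        lay_0 = train_sae(X, 8, SAEConfig(sparsity_weight=0.0, sparsity_target=rho, **kw))
        act_b = encode(X, lay_b).mean()
        act_0 = encode(X, lay_0).mean()
        assert abs(act_b - rho) < abs(act_0 - rho)

    def test_penalty_trades_reconstruction_for_sparsity(self, rng):
        X = rng.uniform(size=(15, 10))
        kw = dict(layer_sizes=(10, 6, 3), l2_weight=0.0, unsup_epochs=300, seed=3)
        lay_plain = train_sae(X, 6, SAEConfig(sparsity_weight=0.0, **kw))
        lay_sparse = train_sae(X, 6, SAEConfig(sparsity_weight=0.1, **kw))
        err = lambda lay: np.mean((X - decode(encode(X, lay), lay)) ** 2)
        assert err(lay_plain) <= err(lay_sparse)

    def test_seeded_determinism_bitwise(self, rng):
        X = rng.uniform(size=(10, 8))
        cfg = SAEConfig(layer_sizes=(8, 5, 3), unsup_epochs=50, seed=11)
        a = train_sae(X, 5, cfg)
        b = train_sae(X, 5, cfg)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.b2, b.b2)

    def test_out_of_range_inputs_rejected(self, rng):
        cfg = SAEConfig(layer_sizes=(4, 3, 2))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            train_sae(rng.normal(size=(5, 4)) * 10, 3, cfg)


class TestStack:
    def test_greedy_wiring_and_code_dimension(self, rng):
        X = rng.uniform(size=(12, 10))
        cfg = SAEConfig(layer_sizes=(10, 7, 4), unsup_epochs=60, seed=5)
        l1, l2 = stack_pretrain(X, cfg)
        code = encode_stack(X, l1, l2)
        assert code.shape == (12, 4)
        assert np.all(np.isfinite(code))
        # layer2 consumes layer1's code: widths must chain
        assert l2.n_visible == l1.n_hidden

    def test_default_code_width_is_824(self):
        assert SAEConfig().layer_sizes == (1024, 1224, 824)

    def test_width_mismatch_rejected(self, rng):
        cfg = SAEConfig(layer_sizes=(10, 7, 4))
        with pytest.raises(ValueError, match="width"):
            stack_pretrain(rng.uniform(size=(5, 8)), cfg)


def test_pack_unpack_roundtrip(rng):
    layer = init_layer(6, 4, rng)
    back = _unpack(_pack(layer), 6, 4)
    assert np.array_equal(back.W1, layer.W1)
    assert np.array_equal(back.b2, layer.b2)
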