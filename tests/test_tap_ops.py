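"""Verification of the temporal-attentive-pooling arithmetic against
independent per-frame loop oracles, plus gradient correctness."""

import numpy as np
import pytest

from tapcrnn.models import (
    ModelConfig,
    TapParams,
    attentive_context,
    build_net,
    classify,
    global_attention,
    local_attention,
)
from tapcrnn.nn.layers import Dense, softmax


def random_params(cnn_dim: int, rnn_dim: int, rng) -> TapParams:
    return TapParams(
        W_c=rng.standard_normal((cnn_dim, cnn_dim)),
        W_r=rng.standard_normal((rnn_dim, rnn_dim)),
        u=rng.standard_normal(cnn_dim + rnn_dim),
        b_global=rng.standard_normal(cnn_dim + rnn_dim),
        W_l=rng.standard_normal((cnn_dim, cnn_dim)),
        b_l=rng.standard_normal(cnn_dim),
        v=rng.standard_normal(cnn_dim),
        W_g=rng.standard_normal((rnn_dim, rnn_dim)),
    )


def loop_attention_oracle(Y, hN, p: TapParams):
    """Brute-force scalar-loop computation of the whole TAP block."""
    n = Y.shape[0]
    e = np.zeros(n)
    for i in range(n):
        c = np.concatenate([p.W_c @ Y[i], p.W_r @ hN]) + p.b_global
        e[i] = sum(p.u[j] * np.tanh(c[j]) for j in range(len(c)))
    alpha = np.exp(e - e.max())
    alpha /= alpha.sum()
    g = np.zeros(n)
    for i in range(n):
        z = alpha[i] * Y[i]
        t = p.W_l @ z + p.b_l
        g[i] = sum(p.v[j] * np.tanh(t[j]) for j in range(len(t)))
    beta = np.exp(g - g.max())
    beta /= beta.sum()
    f_hat = np.zeros(Y.shape[1])
    for i in range(n):
        f_hat += alpha[i] * beta[i] * Y[i]
    return alpha, beta, f_hat / n


class TestShapes:
    def test_tap_params_shape_assertions(self, rng):
        with pytest.raises(ValueError, match="W_l"):
            TapParams(
                W_c=np.eye(3),
                W_r=np.eye(2),
                u=np.zeros(5),
                b_global=np.zeros(5),
                W_l=np.eye(4),
                b_l=np.zeros(3),
                v=np.zeros(3),
                W_g=np.eye(2),
            )

    def test_dim_mismatch_names_offender(self, rng):
        p = random_params(3, 2, rng)
        with pytest.raises(ValueError, match="W_c"):
            global_attention(rng.standard_normal((4, 5)), np.zeros(2), p)
        with pytest.raises(ValueError, match="W_r"):
            global_attention(rng.standard_normal((4, 3)), np.zeros(7), p)


class TestGlobalAttention:
    def test_singleton_gives_one(self, rng):
        p = random_params(3, 2, rng)
        alpha = global_attention(rng.standard_normal((1, 3)), rng.standard_normal(2), p)
        np.testing.assert_allclose(alpha, [1.0])

    def test_sums_to_one(self, rng):
        p = random_params(4, 3, rng)
        alpha = global_attention(rng.standard_normal((9, 4)), rng.standard_normal(3), p)
        assert abs(alpha.sum() - 1.0) < 1e-12
        assert (alpha >= 0).all()

    def test_hand_set_two_frame_case(self):
        """Identity matrices, u = ones: matches a two-line computation."""
        p = TapParams(
            W_c=np.eye(2),
            W_r=np.eye(2),
            u=np.ones(4),
            b_global=np.zeros(4),
            W_l=np.eye(2),
            b_l=np.zeros(2),
            v=np.ones(2),
            W_g=np.eye(2),
        )
        Y = np.array([[0.5, -0.2], [1.0, 0.3]])
        hN = np.array([0.1, 0.4])
        e = [np.tanh(np.r_[y, hN]).sum() for y in Y]
        expected = np.exp(e) / np.exp(e).sum()
        np.testing.assert_allclose(global_attention(Y, hN, p), expected, atol=1e-12)


class TestLocalAttention:
    def test_singleton_gives_one(self, rng):
        p = random_params(3, 2, rng)
        beta = local_attention(rng.standard_normal((1, 3)), np.array([1.0]), p)
        np.testing.assert_allclose(beta, [1.0])

    def test_uniform_for_identical_frames(self, rng):
        p = random_params(3, 2, rng)
        Y = np.tile(rng.standard_normal(3), (5, 1))
        beta = local_attention(Y, np.full(5, 0.2), p)
        np.testing.assert_allclose(beta, np.full(5, 0.2), atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        p = random_params(2, 2, rng)
        Y = rng.standard_normal((3, 2))
        alpha = softmax(rng.standard_normal(3))
        expected_scores = [
            p.v @ np.tanh(p.W_l @ (alpha[i] * Y[i]) + p.b_l) for i in range(3)
        ]
        np.testing.assert_allclose(
            local_attention(Y, alpha, p), softmax(np.array(expected_scores)), atol=1e-12
        )


class TestAttentiveContext:
    def test_equal_weights_identical_frames(self):
        y0 = np.array([1.0, -2.0, 3.0])
        Y = np.vstack([y0, y0])
        f = attentive_context(Y, np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        np.testing.assert_allclose(f, 0.25 * y0)

    def test_one_hot_weights(self):
        Y = np.array([[1.0, 2.0], [3.0, 4.0]])
        f = attentive_context(Y, np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        np.testing.assert_allclose(f, Y[0] / 2)

    def test_matches_elementwise_loop(self, rng):
        Y = rng.standard_normal((5, 4))
        a, b = softmax(rng.standard_normal(5)), softmax(rng.standard_normal(5))
        expected = sum(a[i] * b[i] * Y[i] for i in range(5)) / 5
        np.testing.assert_allclose(attentive_context(Y, a, b), expected, atol=1e-12)


class TestClassify:
    def test_posterior_is_distribution(self, rng):
        p = random_params(3, 2, rng)
        layers = [Dense(5, 4, rng), Dense(4, 2, rng, activation="linear")]
        o = classify(rng.standard_normal(3), rng.standard_normal(2), p, layers)
        assert o.shape == (2,)
        assert abs(o.sum() - 1.0) < 1e-12
        assert (o >= 0).all()

    def test_zero_weights_give_uniform(self, rng):
        p = random_params(3, 2, rng)
        layers = [Dense(5, 4, rng), Dense(4, 2, rng, activation="linear")]
        for layer in layers:
            layer.params["W"][:] = 0
            layer.params["b"][:] = 0
        o = classify(np.ones(3), np.ones(2), p, layers)
        np.testing.assert_allclose(o, [0.5, 0.5])

    def test_tiny_network_matches_matrix_oracle(self, rng):
        p = random_params(2, 2, rng)
        layers = [Dense(4, 2, rng), Dense(2, 2, rng, activation="linear")]
        f_hat, hN = rng.standard_normal(2), rng.standard_normal(2)
        s = np.concatenate([f_hat, p.W_g @ hN])
        a1 = np.tanh(layers[0].params["W"].T @ s + layers[0].params["b"])
        logits = layers[1].params["W"].T @ a1 + layers[1].params["b"]
        np.testing.assert_allclose(
            classify(f_hat, hN, p, layers), softmax(logits), atol=1e-12
        )


class TestOracleEquivalence:
    def test_50_random_small_instances(self, rng):
        """Vectorized TAP block equals the scalar loop oracle to 1e-9 on
        50 random small instances (N <= 8, dims <= 4)."""
        cfg = ModelConfig(
            architecture="tap_crnn", conv_spec=[(1, 1, 2)], rnn_spec=[2], dense_spec=[3]
        )
        for trial in range(50):
            n = int(rng.integers(1, 9))
            cnn_dim = int(rng.integers(1, 5))
            rnn_dim = int(rng.integers(1, 5))
            p = random_params(cnn_dim, rnn_dim, rng)
            Y = rng.standard_normal((n, cnn_dim))
            hN = rng.standard_normal(rnn_dim)
            alpha = global_attention(Y, hN, p)
            beta = local_attention(Y, alpha, p)
            f_hat = attentive_context(Y, alpha, beta)
            oa, ob, of = loop_attention_oracle(Y, hN, p)
            np.testing.assert_allclose(alpha, oa, atol=1e-9)
            np.testing.assert_allclose(beta, ob, atol=1e-9)
            np.testing.assert_allclose(f_hat, of, atol=1e-9)
            assert abs(alpha.sum() - 1) < 1e-9 and abs(beta.sum() - 1) < 1e-9

    def test_net_forward_matches_functional_path(self, rng):
        """The trained net's internal attention equals the functional ops."""
        cfg = ModelConfig(
            architecture="tap_crnn", conv_spec=[(2, 1, 3)], rnn_spec=[3], dense_spec=[4]
        )
        net = build_net(5, cfg, rng)
        for key in ("u", "v"):  # leave the uniform start; perturb to generic point
            net.tap.params[key][:] = rng.standard_normal(net.tap.params[key].shape)
        x = rng.standard_normal((6, 5))
        probs, trace = net.forward(x)
        Y = net.conv_encode(x)
        _, hN = net.recurrent_encode(Y)
        p = net.tap_params()
        alpha = global_attention(Y, hN, p)
        beta = local_attention(Y, alpha, p)
        np.testing.assert_allclose(alpha, trace.alpha_global, atol=1e-12)
        np.testing.assert_allclose(beta, trace.beta_local, atol=1e-12)
        o = classify(attentive_context(Y, alpha, beta), hN, p, net.denses)
        np.testing.assert_allclose(o, probs, atol=1e-12)


class TestGradients:
    @pytest.mark.parametrize("arch,spec", [
        ("tap_crnn", dict(conv_spec=[(2, 1, 3), (2, 1, 3)], rnn_spec=[3], dense_spec=[4])),
        ("crnn", dict(conv_spec=[(2, 1, 3)], rnn_spec=[3, 3], dense_spec=[4])),
        ("cnn", dict(conv_spec=[(2, 1, 3), (2, 2, 2)], rnn_spec=[], dense_spec=[4])),
    ])
    def test_finite_difference_agreement(self, arch, spec, rng):
        """Central finite differences agree with backprop (rel err < 1e-4)
        for every parameter tensor, including all TAP tensors."""
        cfg = ModelConfig(architecture=arch, **spec)
        net = build_net(5, cfg, rng)
        # move off the symmetric uniform-attention start to a generic point
        for k, p in net.parameters().items():
            p += 0.05 * rng.standard_normal(p.shape)
        x = rng.standard_normal((6, 5))
        net.zero_grads()
        net.loss_grad(x, 1)
        grads = {k: v.copy() for k, v in net.gradients().items()}
        eps = 1e-6
        for name, p in net.parameters().items():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = -np.log(net.forward(x)[0][1])
                p[idx] = orig - eps
                lm = -np.log(net.forward(x)[0][1])
                p[idx] = orig
                fd = (lp - lm) / (2 * eps)
                an = grads[name][idx]
                denom = max(abs(fd) + abs(an), 1e-4)
                assert abs(fd - an) / denom < 1e-4, f"{name}{idx}: fd={fd} an={an}"


class TestForwardInvariants:
    def test_singleton_epl_is_one(self, rng):
        cfg = ModelConfig(
            architecture="tap_crnn", conv_spec=[(2, 1, 3)], rnn_spec=[3], dense_spec=[4]
        )
        net = build_net(5, cfg, rng)
        _, trace = net.forward(rng.standard_normal((1, 5)))
        np.testing.assert_allclose(trace.epl, [1.0])

    def test_normalizations_within_1e9(self, rng):
        cfg = ModelConfig(
            architecture="tap_crnn", conv_spec=[(2, 1, 3)], rnn_spec=[3], dense_spec=[4]
        )
        net = build_net(6, cfg, rng)
        for _ in range(5):
            _, trace = net.forward(rng.standard_normal((int(rng.integers(2, 30)), 6)))
            assert abs(trace.alpha_global.sum() - 1) < 1e-9
            assert abs(trace.beta_local.sum() - 1) < 1e-9
            assert (trace.epl >= 0).all() and (trace.epl <= 1).all()

    def test_permuting_frames_changes_hN(self, rng):
        cfg = ModelConfig(
            architecture="crnn", conv_spec=[(2, 1, 3)], rnn_spec=[3], dense_spec=[4]
        )
        net = build_net(5, cfg, rng)
        x = rng.standard_normal((8, 5))
        Y1 = net.conv_encode(x)
        _, h1 = net.recurrent_encode(Y1)
        perm = rng.permutation(8)
        Y2 = net.conv_encode(x[perm])
        _, h2 = net.recurrent_encode(Y2)
        assert not np.allclose(h1, h2)

    def test_recurrent_default_width_is_256(self, rng):
        cfg = ModelConfig.crnn_default()
        assert cfg.rnn_spec == [256, 256]
        assert cfg.dense_spec == [256, 256]
        assert cfg.conv_spec == [(16, 1, 4), (16, 1, 4)]

    def test_conv_preserves_length_and_flattens(self, rng):
        cfg = ModelConfig(
            architecture="crnn", conv_spec=[(4, 1, 4), (4, 1, 4)], rnn_spec=[3], dense_spec=[2]
        )
        net = build_net(17, cfg, rng)
        for n in (1, 2, 9):
            Y = net.conv_encode(rng.standard_normal((n, 17)))
            assert Y.shape == (n, 17 * 4)

    def test_zero_input_zero_bias_gives_zero_conv_output(self, rng):
        cfg = ModelConfig(
            architecture="cnn", conv_spec=[(3, 1, 4)], rnn_spec=[], dense_spec=[2]
        )
        net = build_net(8, cfg, rng)
        Y = net.conv_encode(np.zeros((4, 8)))
        np.testing.assert_allclose(Y, 0.0)
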