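import numpy as np
import pytest

from conftest import numeric_gradcheck
from edapain.encoder import (
    AttentionConfig,
    EncoderBlock,
    MultiHeadAttention,
    TCNConfig,
    attention_output,
    attention_scores,
    attention_weights,
    causal_conv,
)
from edapain.nn import Conv1d


class TestCausalConv:
    def test_layer_matches_reference_function(self, rng):
        conv = Conv1d(3, 2, 4, 1, "causal", rng=rng, dtype=np.float64)
        x = rng.standard_normal((2, 10, 3))
        W = np.transpose(conv.W.value, (2, 1, 0))  # (K, C1, C2)
        np.testing.assert_allclose(
            conv(x), causal_conv(x, W, conv.b.value), atol=1e-10
        )

    def test_future_perturbations_never_leak_backward(self, rng):
        """Output at t is bit-identical under any perturbation strictly after t."""
        conv = Conv1d(2, 2, 5, 1, "causal", rng=rng)
        x = rng.standard_normal((1, 20, 2)).astype(np.float32)
        base = conv(x)
        for t0 in (0, 7, 18):
            xp = x.copy()
            xp[0, t0 + 1 :, :] += rng.standard_normal((19 - t0, 2)).astype(np.float32)
            assert np.array_equal(conv(xp)[0, : t0 + 1], base[0, : t0 + 1])

    def test_kernel_one_is_pointwise(self, rng):
        conv = Conv1d(3, 3, 1, 1, "causal", rng=rng, dtype=np.float64)
        x = rng.standard_normal((2, 6, 3))
        np.testing.assert_allclose(conv(x), x @ conv.W.value[:, :, 0].T + conv.b.value)

    def test_length_preserved(self, rng):
        conv = Conv1d(2, 4, 7, 1, "causal", rng=rng)
        assert conv(np.zeros((1, 30, 2), dtype=np.float32)).shape == (1, 30, 4)


class TestAttentionMath:
    def test_orthogonal_rows_zero_off_diagonal(self):
        q = np.eye(4)
        e = attention_scores(q, q, scale=1.0)
        np.testing.assert_allclose(e - np.diag(np.diag(e)), 0.0)

    def test_hand_two_by_two_example(self):
        q = np.array([[1.0, 2.0], [0.0, 1.0]])
        k = np.array([[3.0, 0.0], [1.0, 1.0]])
        e = attention_scores(q, k, scale=0.5)
        np.testing.assert_allclose(e, 0.5 * np.array([[3.0, 3.0], [0.0, 1.0]]))

    def test_bilinear_scaling(self, rng):
        q = rng.standard_normal((3, 4))
        k = rng.standard_normal((3, 4))
        c = 1.7
        np.testing.assert_allclose(
            attention_scores(c * q, c * k, 0.25),
            c**2 * attention_scores(q, k, 0.25),
            atol=1e-12,
        )

    def test_weights_row_stochastic_and_oracle(self, rng):
        e = rng.standard_normal((6, 6)) * 3
        a = attention_weights(e)
        np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(a >= 0)
        manual = np.empty_like(e)
        for i in range(6):
            ex = np.exp(e[i])
            manual[i] = ex / ex.sum()
        np.testing.assert_allclose(a, manual, atol=1e-7)

    def test_identical_keys_give_uniform_weights(self):
        e = np.zeros((4, 5))
        np.testing.assert_allclose(attention_weights(e), 1.0 / 5)

    def test_dominant_score_saturates(self):
        e = np.array([[0.0, 100.0, 0.0]])
        a = attention_weights(e)
        assert a[0, 1] == pytest.approx(1.0, abs=1e-20)

    def test_output_uniform_weights_give_mean(self, rng):
        v = rng.standard_normal((4, 3))
        alpha = np.full((4, 4), 0.25)
        np.testing.assert_allclose(attention_output(alpha, v),
                                   np.tile(v.mean(axis=0), (4, 1)), atol=1e-12)

    def test_output_one_hot_selects_row(self, rng):
        v = rng.standard_normal((3, 2))
        alpha = np.eye(3)[[2, 0, 1]]
        np.testing.assert_allclose(attention_output(alpha, v), v[[2, 0, 1]])

    def test_output_stays_in_convex_hull(self, rng):
        v = rng.standard_normal((5, 4))
        e = rng.standard_normal((5, 5))
        z = attention_output(attention_weights(e), v)
        assert np.all(z <= v.max(axis=0) + 1e-12)
        assert np.all(z >= v.min(axis=0) - 1e-12)


class TestMultiHeadAttention:
    def test_output_width_restored(self, rng):
        cfg = AttentionConfig(n_heads=5, feature_size=75)
        mha = MultiHeadAttention(cfg, TCNConfig(7), rng)
        mha.eval()
        out = mha(rng.standard_normal((2, 10, 75)).astype(np.float32))
        assert out.shape == (2, 10, 75)
        assert mha.proj.W.value.shape == (5 * 75, 75)

    def test_single_head_with_identity_maps_is_plain_attention(self, rng):
        cfg = AttentionConfig(n_heads=1, feature_size=6)
        mha = MultiHeadAttention(cfg, TCNConfig(3), rng)
        eye = np.eye(6, dtype=np.float32)
        for lin in (mha.w_q[0], mha.w_k[0], mha.w_v[0], mha.proj):
            lin.W.value[...] = eye
        x = rng.standard_normal((1, 5, 6)).astype(np.float32)
        out = mha(x)
        xq, xk, xv = mha.conv_q(x), mha.conv_k(x), mha.conv_v(x)
        expected = attention_output(
            attention_weights(attention_scores(xq[0], xk[0], mha.scale)), xv[0]
        )
        np.testing.assert_allclose(out[0], expected, atol=1e-5)

    def test_split_head_mode_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            AttentionConfig(n_heads=4, feature_size=75, split_heads=True)
        cfg = AttentionConfig(n_heads=5, feature_size=75, split_heads=True)
        assert cfg.feature_size % cfg.n_heads == 0

    def test_score_scale_policies(self):
        assert AttentionConfig(feature_size=64).scale_value() == pytest.approx(1 / 8)
        assert AttentionConfig(feature_size=64, score_scale="linear").scale_value() \
            == pytest.approx(1 / 64)

    @pytest.mark.parametrize("split", [False, True])
    def test_gradients(self, rng, split):
        cfg = AttentionConfig(n_heads=2, feature_size=6, split_heads=split)
        mha = MultiHeadAttention(cfg, TCNConfig(3), rng)
        numeric_gradcheck(mha, rng.standard_normal((2, 5, 6)), rng)


class TestEncoderBlock:
    def test_shape_conservation(self, rng):
        cfg = AttentionConfig(n_heads=5, feature_size=75)
        block = EncoderBlock(cfg, TCNConfig(7), ffn_hidden=16, dropout=0.0, rng=rng)
        block.eval()
        x = rng.standard_normal((2, 12, 75)).astype(np.float32)
        assert block(x).shape == x.shape

    @pytest.mark.parametrize("residual", ["tcn", "input"])
    def test_gradients(self, rng, residual):
        cfg = AttentionConfig(n_heads=2, feature_size=6, residual_source=residual)
        block = EncoderBlock(cfg, TCNConfig(3), ffn_hidden=5, dropout=0.0, rng=rng)
        numeric_gradcheck(block, rng.standard_normal((2, 4, 6)), rng)
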