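import numpy as np
import pytest
from scipy.integrate import quad

from conftest import numeric_gradcheck
from edapain.nn import (
    BatchNorm1d,
    Conv1d,
    Dropout,
    GELU,
    LayerNorm,
    Linear,
    MaxPool1d,
    SizeError,
    conv_output_length,
    gelu,
    softmax,
    softmax_cross_entropy,
)
from edapain.nn.layers import ReLU


def brute_force_maxpool(x, pool, stride):
    n, l, c = x.shape
    lout = (l - pool) // stride + 1
    out = np.empty((n, lout, c))
    for i in range(n):
        for j in range(lout):
            for k in range(c):
                out[i, j, k] = x[i, j * stride : j * stride + pool, k].max()
    return out


def brute_force_conv(x, W, b, stride):
    """Direct triple-loop valid convolution; W is (out, in, k)."""
    n, l, cin = x.shape
    cout, _, k = W.shape
    lout = (l - k) // stride + 1
    out = np.zeros((n, lout, cout))
    for i in range(n):
        for j in range(lout):
            for o in range(cout):
                out[i, j, o] = (
                    x[i, j * stride : j * stride + k, :] * W[o].T
                ).sum() + b[o]
    return out


class TestMaxPool:
    def test_hand_example(self):
        x = np.array([1.0, 3.0, 2.0, 5.0]).reshape(1, 4, 1)
        out = MaxPool1d(2, 2)(x)
        np.testing.assert_array_equal(out[0, :, 0], [3.0, 5.0])

    def test_constant_channel_stays_constant(self):
        x = np.full((2, 10, 3), 4.2)
        assert np.all(MaxPool1d(3, 2)(x) == 4.2)

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(20):
            pool, stride = rng.integers(1, 5), rng.integers(1, 4)
            x = rng.standard_normal((2, int(rng.integers(int(pool), 20)), 3))
            np.testing.assert_allclose(
                MaxPool1d(int(pool), int(stride))(x),
                brute_force_maxpool(x, int(pool), int(stride)),
                atol=1e-6,
            )

    def test_pool_longer_than_input_rejected(self):
        with pytest.raises(SizeError):
            MaxPool1d(5, 1)(np.zeros((1, 3, 1)))


class TestBatchNorm:
    def test_standardizes_with_identity_affine(self, rng):
        bn = BatchNorm1d(4)
        x = rng.standard_normal((8, 20, 4)) * 3.0 + 1.5
        y = bn(x)
        np.testing.assert_allclose(y.mean(axis=(0, 1)), 0.0, atol=1e-5)
        np.testing.assert_allclose(y.var(axis=(0, 1)), 1.0, atol=1e-3)

    def test_zero_gamma_collapses_to_beta(self, rng):
        bn = BatchNorm1d(3)
        bn.gamma.value[...] = 0.0
        bn.beta.value[...] = 0.7
        y = bn(rng.standard_normal((4, 5, 3)))
        np.testing.assert_allclose(y, 0.7, atol=1e-7)

    def test_hand_computed_example(self):
        """2x2x1 example checked against the per-channel formula."""
        x = np.array([[[1.0], [2.0]], [[3.0], [6.0]]])
        mu = 3.0
        var = np.mean((x - mu) ** 2)
        bn = BatchNorm1d(1, eps=1e-5)
        expected = (x - mu) / np.sqrt(var + 1e-5)
        np.testing.assert_allclose(bn(x), expected, rtol=1e-6)

    def test_zero_variance_channel_is_finite(self):
        bn = BatchNorm1d(1)
        y = bn(np.full((3, 4, 1), 2.0))
        assert np.all(np.isfinite(y))

    def test_eval_uses_running_statistics(self, rng):
        bn = BatchNorm1d(2)
        for _ in range(200):
            bn(rng.standard_normal((16, 10, 2)) * 2.0 + 5.0)
        bn.eval()
        y = bn(np.full((1, 10, 2), 5.0))
        np.testing.assert_allclose(y, 0.0, atol=0.1)


class TestGelu:
    def test_zero_fixed_point_and_limits(self):
        assert gelu(0.0) == 0.0
        assert gelu(30.0) == pytest.approx(30.0, rel=1e-12)
        assert gelu(-30.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_quadrature_of_normal_cdf(self):
        """g(x) = x * Phi(x) with Phi computed by numerical integration."""
        pdf = lambda t: np.exp(-t * t / 2.0) / np.sqrt(2.0 * np.pi)
        for x in (-2.3, -0.7, 0.31, 1.0, 2.9):
            phi, _ = quad(pdf, -np.inf, x)
            assert gelu(x) == pytest.approx(x * phi, abs=1e-8)


class TestConv:
    def test_matches_brute_force(self, rng):
        for _ in range(10):
            k, s = int(rng.integers(1, 6)), int(rng.integers(1, 3))
            conv = Conv1d(2, 3, k, s, rng=rng, dtype=np.float64)
            x = rng.standard_normal((2, int(rng.integers(k, 15)), 2))
            expected = brute_force_conv(x, conv.W.value, conv.b.value, s)
            np.testing.assert_allclose(conv(x), expected, atol=1e-10)

    def test_output_length_formula(self, rng):
        for _ in range(20):
            l = int(rng.integers(5, 50))
            k = int(rng.integers(1, l + 1))
            s = int(rng.integers(1, 5))
            conv = Conv1d(1, 1, k, s)
            out = conv(np.zeros((1, l, 1), dtype=np.float32))
            assert out.shape[1] == conv_output_length(l, k, s) == (l - k) // s + 1

    def test_same_padding_preserves_length(self, rng):
        conv = Conv1d(2, 2, 8, 1, "same", rng=rng)
        assert conv(np.zeros((1, 40, 2), dtype=np.float32)).shape[1] == 40

    def test_kernel_longer_than_input_rejected(self):
        with pytest.raises(SizeError):
            Conv1d(1, 1, 10)(np.zeros((1, 5, 1), dtype=np.float32))

    def test_conv_block_identity_composition(self, rng):
        """Size-1 identity conv + frozen unit batch-norm reduces to gelu(x)."""
        conv = Conv1d(1, 1, 1, 1, rng=rng)
        conv.W.value[...] = 1.0
        conv.b.value[...] = 0.0
        bn = BatchNorm1d(1, eps=1e-12)
        bn.eval()  # frozen stats: mean 0, var 1
        act = GELU()
        x = rng.standard_normal((2, 9, 1))
        np.testing.assert_allclose(act(bn(conv(x))), gelu(x), rtol=1e-5, atol=1e-7)


class TestDropoutAndSoftmax:
    def test_dropout_identity_in_eval(self, rng):
        drop = Dropout(0.5)
        drop.eval()
        x = rng.standard_normal((3, 4))
        np.testing.assert_array_equal(drop(x), x)

    def test_dropout_preserves_expectation(self, rng):
        drop = Dropout(0.3)
        x = np.ones((200, 200))
        y = drop(x)
        uniques = np.unique(y)
        assert len(uniques) == 2
        np.testing.assert_allclose(uniques, [0.0, 1 / 0.7], atol=1e-9)
        assert y.mean() == pytest.approx(1.0, abs=0.02)

    def test_cross_entropy_gradient_is_probs_minus_onehot(self, rng):
        logits = rng.standard_normal((5, 3))
        y = np.array([0, 2, 1, 1, 0])
        loss, dl, probs = softmax_cross_entropy(logits, y)
        onehot = np.eye(3)[y]
        np.testing.assert_allclose(dl, (probs - onehot) / 5, atol=1e-12)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert loss > 0


class TestLayerNorm:
    def test_moments_before_affine(self, rng):
        ln = LayerNorm(16)
        x = rng.standard_normal((3, 5, 16)) * 4 + 2
        y = ln(x)
        np.testing.assert_allclose(y.mean(axis=-1), 0.0, atol=1e-6)
        np.testing.assert_allclose(y.var(axis=-1), 1.0, atol=1e-3)


class TestGradients:
    """Analytic backward passes agree with central finite differences."""

    @pytest.mark.parametrize(
        "make_layer,shape",
        [
            (lambda rng: Conv1d(2, 3, 4, 2, rng=rng), (2, 11, 2)),
            (lambda rng: Conv1d(2, 2, 3, 1, "same", rng=rng), (2, 8, 2)),
            (lambda rng: Conv1d(2, 2, 3, 1, "causal", rng=rng), (2, 8, 2)),
            (lambda rng: MaxPool1d(3, 2), (2, 11, 2)),
            (lambda rng: BatchNorm1d(3), (3, 6, 3)),
            (lambda rng: LayerNorm(7), (2, 4, 7)),
            (lambda rng: Linear(6, 4, rng=rng), (3, 6)),
            (lambda rng: GELU(), (2, 5, 3)),
            (lambda rng: ReLU(), (2, 5, 3)),
        ],
        ids=["conv_strided", "conv_same", "conv_causal", "maxpool",
             "batchnorm", "layernorm", "linear", "gelu", "relu"],
    )
    def test_layer_gradients(self, make_layer, shape, rng):
        layer = make_layer(rng)
        x = rng.standard_normal(shape)
        numeric_gradcheck(layer, x, rng)
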