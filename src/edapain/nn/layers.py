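"""Standard layers on (batch, length, channels) feature maps."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

from .core import Module, Param

# python-float constants: keep float32 inputs from being promoted to float64
_SQRT2 = float(np.sqrt(2.0))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


class SizeError(ValueError):
    """Input geometry incompatible with the layer configuration."""


def conv_output_length(length: int, kernel: int, stride: int) -> int:
    """Valid-convolution output length: floor((L - k) / stride) + 1."""
    if kernel > length:
        raise SizeError(f"kernel {kernel} exceeds input length {length}")
    return (length - kernel) // stride + 1


class Conv1d(Module):
    """1-D convolution over the length axis of an (N, L, C) map.

    ``padding`` is one of ``'valid'`` (no padding), ``'same'`` (stride-1
    length-preserving zero padding), or ``'causal'`` (K-1 zeros on the left,
    so output t depends only on inputs at positions <= t).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: str = "valid",
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
        needs_input_grad: bool = True,
    ):
        super().__init__()
        if padding not in ("valid", "same", "causal"):
            raise ValueError(f"unknown padding mode {padding!r}")
        if padding in ("same", "causal") and stride != 1:
            raise ValueError(f"padding={padding!r} requires stride 1")
        rng = rng or np.random.default_rng(0)
        self.needs_input_grad = needs_input_grad
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = kernel_size * in_channels
        self.W = Param(
            (rng.standard_normal((out_channels, in_channels, kernel_size))
             * np.sqrt(2.0 / fan_in)).astype(dtype)
        )
        self.b = Param(np.zeros(out_channels, dtype=dtype)) if bias else None

    def _pad_amounts(self) -> tuple[int, int]:
        k = self.kernel_size
        if self.padding == "same":
            return (k - 1) // 2, k // 2
        if self.padding == "causal":
            return k - 1, 0
        return 0, 0

    def output_length(self, length: int) -> int:
        left, right = self._pad_amounts()
        return conv_output_length(length + left + right, self.kernel_size, self.stride)

    def forward(self, x: np.ndarray) -> np.ndarray:
        left, right = self._pad_amounts()
        if left or right:
            x = np.pad(x, ((0, 0), (left, right), (0, 0)))
        n, lp, c = x.shape
        if c != self.in_channels:
            raise SizeError(f"expected {self.in_channels} channels, got {c}")
        lout = conv_output_length(lp, self.kernel_size, self.stride)
        windows = sliding_window_view(x, self.kernel_size, axis=1)[:, :: self.stride]
        win_flat = np.ascontiguousarray(windows).reshape(n * lout, c * self.kernel_size)
        w_flat = self.W.value.reshape(self.out_channels, -1)
        y = win_flat @ w_flat.T
        if self.b is not None:
            y += self.b.value
        self._cache = (win_flat, (n, lp, c), lout)
        return y.reshape(n, lout, self.out_channels)

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        win_flat, (n, lp, c), lout = self._cache
        k, s = self.kernel_size, self.stride
        g_flat = grad.reshape(n * lout, self.out_channels)
        self.W.grad += (g_flat.T @ win_flat).reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += g_flat.sum(axis=0)
        if not self.needs_input_grad:
            return None
        # col2im: one BLAS call for all window gradients, then strided adds.
        dcols = (g_flat @ self.W.value.reshape(self.out_channels, -1)).reshape(
            n, lout, c, k
        )
        dx_pad = np.zeros((n, lp, c), dtype=grad.dtype)
        for j in range(k):
            # output position l reads padded input position l*s + j
            dx_pad[:, j : j + s * lout : s, :] += dcols[:, :, :, j]
        left, right = self._pad_amounts()
        if left or right:
            dx_pad = dx_pad[:, left : lp - right, :]
        return dx_pad


class MaxPool1d(Module):
    """Per-channel windowed maximum over the length axis."""

    def __init__(self, pool: int, stride: int | None = None):
        super().__init__()
        self.pool = pool
        self.stride = stride if stride is not None else pool

    def output_length(self, length: int) -> int:
        return conv_output_length(length, self.pool, self.stride)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, l, c = x.shape
        if self.pool > l:
            raise SizeError(f"pool {self.pool} exceeds input length {l}")
        windows = sliding_window_view(x, self.pool, axis=1)[:, :: self.stride]
        idx = windows.argmax(axis=-1)
        y = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        n, lout, c = grad.shape
        dx = np.zeros(shape, dtype=grad.dtype)
        pos = idx + self.stride * np.arange(lout)[None, :, None]
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, None, :]
        np.add.at(dx, (ni, pos, ci), grad)
        return dx


class BatchNorm1d(Module):
    """Per-channel batch normalization over batch and length positions."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            n, l, _ = x.shape
            if n * l < 2:
                raise SizeError("batch statistics need more than one position")
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        n, l, _ = shape
        m = n * l
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1))
        self.beta.grad += grad.sum(axis=(0, 1))
        dxhat = grad * self.gamma.value
        if not self.training:
            return dxhat * inv_std
        sum_d = dxhat.sum(axis=(0, 1))
        sum_dx = (dxhat * xhat).sum(axis=(0, 1))
        return (inv_std / m) * (m * dxhat - sum_d - xhat * sum_dx)


class LayerNorm(Module):
    """Normalization over the trailing feature axis, with affine."""

    def __init__(self, features: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gamma = Param(np.ones(features, dtype=dtype))
        self.beta = Param(np.zeros(features, dtype=dtype))

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        f = xhat.shape[-1]
        red = tuple(range(xhat.ndim - 1))
        self.gamma.grad += (grad * xhat).sum(axis=red)
        self.beta.grad += grad.sum(axis=red)
        dxhat = grad * self.gamma.value
        sum_d = dxhat.sum(axis=-1, keepdims=True)
        sum_dx = (dxhat * xhat).sum(axis=-1, keepdims=True)
        return (inv_std / f) * (f * dxhat - sum_d - xhat * sum_dx)


def gelu(x: np.ndarray) -> np.ndarray:
    """Gaussian error linear unit, exact form: x * Phi(x) via erf."""
    x = np.asarray(x)
    return x * 0.5 * (1.0 + erf(x / _SQRT2))


class GELU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return gelu(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        phi = 0.5 * (1.0 + erf(x / _SQRT2))
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return grad * (phi + x * pdf)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        mask = x > 0
        self._cache = mask
        return np.where(mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._cache


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._dropout_rng = np.random.default_rng(0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0.0:
            self._cache = None
            return x
        keep = 1.0 - self.rate
        mask = (self._dropout_rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._cache = mask
        return x * mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._cache is None else grad * self._cache


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 gain: float = 2.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.W = Param(
            (rng.standard_normal((in_features, out_features))
             * np.sqrt(gain / in_features)).astype(dtype)
        )
        self.b = Param(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        x2 = x.reshape(-1, x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.W.grad += x2.T @ g2
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        return grad @ self.W.value.T


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._cache)


class Transpose(Module):
    """Swap the length and channel axes: (N, L, C) <-> (N, C, L)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(np.swapaxes(x, 1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(np.swapaxes(grad, 1, 2))
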