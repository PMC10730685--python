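"""Squeeze-and-excitation residual recalibration of multiscale features.

The block convolves the concatenated feature map with two 1x1 convolutions
(ReLU activations) to give V, squeezes V to per-channel statistics z by
global average pooling, produces sigmoid channel gates
``alpha = sigmoid(W2 relu(W1 z))`` through a bottleneck of width C/r, scales
V channel-wise by the gates, and adds the block input back as a residual:
``X_tilde = X + alpha (x) V``.

The squeeze is taken per example over the length axis (so inference does not
depend on batch composition); a ``batch_squeeze`` flag reproduces the
batch-coupled 1/(N*L) average for equation-level checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv1d, Linear, Module, ReLU


@dataclass(frozen=True)
class SEConfig:
    reduction_ratio: int = 16
    n_blocks: int = 1
    batch_squeeze: bool = False
    residual_source: str = "x"  # 'x': add block input; 'v': add conv output

    def __post_init__(self) -> None:
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        if self.residual_source not in ("x", "v"):
            raise ValueError("residual_source must be 'x' or 'v'")


@dataclass
class SEState:
    """Captured internals of one forward pass, for visualization."""

    z: np.ndarray  # squeeze statistics, (N, C) or (C,)
    alpha: np.ndarray  # channel gates in (0, 1), same shape as z
    pre_mean: np.ndarray  # mean over batch of the block input, (L, C)
    v_mean: np.ndarray  # mean over batch of V, (L, C)
    post_mean: np.ndarray  # mean over batch of X_tilde, (L, C)


def squeeze(v: np.ndarray, batch_mode: bool = False) -> np.ndarray:
    """Global average over length (and batch, if ``batch_mode``) per channel."""
    return v.mean(axis=(0, 1)) if batch_mode else v.mean(axis=1)


def excite(z: np.ndarray, W1: np.ndarray, W2: np.ndarray) -> np.ndarray:
    """Bottleneck gating: sigmoid(W2 relu(W1 z)).

    ``W1`` has shape (C/r, C) and ``W2`` shape (C, C/r); ``z`` is (..., C).
    """
    h = np.maximum(z @ W1.T, 0.0)
    pre = h @ W2.T
    return 1.0 / (1.0 + np.exp(-pre))


def recalibrate(x: np.ndarray, v: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Channel-wise gate of v then residual addition with x."""
    gates = alpha if alpha.ndim == 1 else alpha[:, None, :]
    return x + gates * v


class SEBlock(Module):
    def __init__(self, channels: int, cfg: SEConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.channels = channels
        hidden = max(1, channels // cfg.reduction_ratio)
        self.conv1 = Conv1d(channels, channels, 1, 1, "valid", rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(channels, channels, 1, 1, "valid", rng=rng)
        self.relu2 = ReLU()
        self.fc1 = Linear(channels, hidden, bias=False, rng=rng)
        self.fc2 = Linear(hidden, channels, bias=False, rng=rng, gain=1.0)
        self.last_state: SEState | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        v = self.relu2(self.conv2(self.relu1(self.conv1(x))))
        z = squeeze(v, batch_mode=self.cfg.batch_squeeze)
        h = np.maximum(z @ self.fc1.W.value, 0.0)
        pre = h @ self.fc2.W.value
        alpha = 1.0 / (1.0 + np.exp(-pre))
        gates = alpha if alpha.ndim == 1 else alpha[:, None, :]
        m = gates * v
        base = x if self.cfg.residual_source == "x" else v
        out = base + m
        self._cache = (x, v, z, h, alpha)
        self.last_state = SEState(
            z=z,
            alpha=alpha,
            pre_mean=x.mean(axis=0),
            v_mean=v.mean(axis=0),
            post_mean=out.mean(axis=0),
        )
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, v, z, h, alpha = self._cache
        n, l, c = v.shape
        gates = alpha if alpha.ndim == 1 else alpha[:, None, :]

        dv = gates * grad  # through the channel-wise product
        if self.cfg.batch_squeeze:
            dalpha = (grad * v).sum(axis=(0, 1))
        else:
            dalpha = (grad * v).sum(axis=1)
        # sigmoid -> fc2 -> relu -> fc1
        dpre = dalpha * alpha * (1.0 - alpha)
        self.fc2.W.grad += h.reshape(-1, h.shape[-1]).T @ dpre.reshape(-1, c)
        dh = (dpre @ self.fc2.W.value.T) * (h > 0)
        self.fc1.W.grad += z.reshape(-1, c).T @ dh.reshape(-1, dh.shape[-1])
        dz = dh @ self.fc1.W.value.T
        # squeeze backward: mean over length (and batch)
        if self.cfg.batch_squeeze:
            dv += dz / (n * l)
        else:
            dv += dz[:, None, :] / l
        if self.cfg.residual_source == "v":
            dv = dv + grad
        dv = self.relu2.backward(dv)
        dv = self.conv2.backward(dv)
        dv = self.relu1.backward(dv)
        dx = self.conv1.backward(dv)
        if self.cfg.residual_source == "x":
            dx = dx + grad
        return dx


class SEResNet(Module):
    """A stack of ``cfg.n_blocks`` squeeze-and-excitation residual blocks."""

    def __init__(self, channels: int, cfg: SEConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.blocks = [SEBlock(channels, cfg, rng) for _ in range(cfg.n_blocks)]

    @property
    def last_state(self) -> SEState | None:
        return self.blocks[-1].last_state

    def forward(self, x: np.ndarray) -> np.ndarray:
        for b in self.blocks:
            x = b(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for b in reversed(self.blocks):
            grad = b.backward(grad)
        return grad
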