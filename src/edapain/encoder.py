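"""Causal-attention encoder and classification head.

After squeeze-and-excitation recalibration the feature map is transposed so
that channels index attention positions and the temporal axis (length 75 by
default) is the per-position feature vector.  Query, key and value are
produced by three causal (left-padded) temporal convolutions of the input —
position t never sees positions after t — followed by per-head full-width
linear projections.  H parallel scaled dot-product attention layers are
concatenated to width H*L and projected back to width L; the encoder tail is
the standard residual + layer-norm sandwich around a feed-forward block, and
the head is two fully connected layers feeding a softmax.

The printed attention scale in the source architecture is 1/L; the canonical
scaled dot-product uses 1/sqrt(L).  Both are available via
``AttentionConfig.score_scale`` ('rsqrt' default, 'linear' for the literal
1/L form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Conv1d,
    Dropout,
    Flatten,
    LayerNorm,
    Linear,
    Module,
    ReLU,
    Sequential,
    softmax,
)


@dataclass(frozen=True)
class TCNConfig:
    """Causal temporal convolution geometry (left padding = K - 1)."""

    kernel_size: int = 7

    @property
    def left_padding(self) -> int:
        return self.kernel_size - 1


@dataclass(frozen=True)
class AttentionConfig:
    n_heads: int = 5
    feature_size: int = 75
    score_scale: str = "rsqrt"  # 'rsqrt': 1/sqrt(L); 'linear': 1/L
    split_heads: bool = False  # per-head width L/H instead of full width
    residual_source: str = "tcn"  # 'tcn': add query-path TCN output; 'input'

    def __post_init__(self) -> None:
        if self.score_scale not in ("rsqrt", "linear"):
            raise ValueError("score_scale must be 'rsqrt' or 'linear'")
        if self.residual_source not in ("tcn", "input"):
            raise ValueError("residual_source must be 'tcn' or 'input'")
        if self.split_heads and self.feature_size % self.n_heads != 0:
            raise ValueError(
                f"feature_size {self.feature_size} not divisible by "
                f"n_heads {self.n_heads} in split-head mode"
            )

    def scale_value(self) -> float:
        d = self.feature_size
        return float(1.0 / np.sqrt(d)) if self.score_scale == "rsqrt" else 1.0 / d


def causal_conv(x: np.ndarray, weights: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Reference causal convolution: output t sums inputs at t-K+1..t.

    ``x`` is (N, L, C1) and ``weights`` is (K, C1, C2).  Provided as a plain
    function for oracle-style use; the trainable layer is `Conv1d` with
    causal padding.
    """
    k = weights.shape[0]
    xp = np.pad(x, ((0, 0), (k - 1, 0), (0, 0)))
    n, lp, _ = xp.shape
    l = x.shape[1]
    out = np.zeros((n, l, weights.shape[2]), dtype=x.dtype)
    for j in range(k):
        out += xp[:, j : j + l, :] @ weights[j]
    if bias is not None:
        out += bias
    return out


def attention_scores(q: np.ndarray, k: np.ndarray, scale: float) -> np.ndarray:
    """Pairwise scaled dot products e_ij = scale * q_i . k_j."""
    if q.shape[-1] != k.shape[-1]:
        raise ValueError("query and key feature widths differ")
    return scale * (q @ np.swapaxes(k, -1, -2))


def attention_weights(e: np.ndarray) -> np.ndarray:
    """Row-stochastic softmax of the score matrix (max-stabilized)."""
    return softmax(e, axis=-1)


def attention_output(alpha: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Convex combinations of value rows: z_i = sum_j alpha_ij v_j."""
    return alpha @ v


class MultiHeadAttention(Module):
    """Causal-conv Q/K/V paths with H parallel attention heads."""

    def __init__(self, cfg: AttentionConfig, tcn: TCNConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        f = cfg.feature_size
        self.cfg = cfg
        self.scale = cfg.scale_value()
        self.head_dim = f // cfg.n_heads if cfg.split_heads else f
        self.conv_q = Conv1d(f, f, tcn.kernel_size, 1, "causal", rng=rng)
        self.conv_k = Conv1d(f, f, tcn.kernel_size, 1, "causal", rng=rng)
        self.conv_v = Conv1d(f, f, tcn.kernel_size, 1, "causal", rng=rng)
        mk = lambda: Linear(f, self.head_dim, bias=False, rng=rng, gain=1.0)
        self.w_q = [mk() for _ in range(cfg.n_heads)]
        self.w_k = [mk() for _ in range(cfg.n_heads)]
        self.w_v = [mk() for _ in range(cfg.n_heads)]
        self.proj = Linear(cfg.n_heads * self.head_dim, f, bias=False, rng=rng, gain=1.0)
        self.last_query_path: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        xq = self.conv_q(x)
        xk = self.conv_k(x)
        xv = self.conv_v(x)
        self.last_query_path = xq
        heads = []
        cache = []
        for h in range(self.cfg.n_heads):
            q = self.w_q[h](xq)
            k = self.w_k[h](xk)
            v = self.w_v[h](xv)
            e = attention_scores(q, k, self.scale)
            a = attention_weights(e)
            z = attention_output(a, v)
            heads.append(z)
            cache.append((q, k, v, a))
        concat = np.concatenate(heads, axis=-1)
        out = self.proj(concat)
        self._cache = cache
        return out

    def backward(self, grad: np.ndarray,
                 grad_query_path: np.ndarray | None = None) -> np.ndarray:
        dconcat = self.proj.backward(grad)
        hd = self.head_dim
        dxq = np.zeros_like(self.last_query_path)
        dxk = np.zeros_like(dxq)
        dxv = np.zeros_like(dxq)
        for h, (q, k, v, a) in enumerate(self._cache):
            dz = dconcat[..., h * hd : (h + 1) * hd]
            da = dz @ np.swapaxes(v, -1, -2)
            dv = np.swapaxes(a, -1, -2) @ dz
            de = a * (da - (da * a).sum(axis=-1, keepdims=True))
            dq = self.scale * (de @ k)
            dk = self.scale * (np.swapaxes(de, -1, -2) @ q)
            dxq += self.w_q[h].backward(dq)
            dxk += self.w_k[h].backward(dk)
            dxv += self.w_v[h].backward(dv)
        if grad_query_path is not None:
            dxq = dxq + grad_query_path
        dx = self.conv_q.backward(dxq)
        dx += self.conv_k.backward(dxk)
        dx += self.conv_v.backward(dxv)
        return dx


class EncoderBlock(Module):
    """MHA with residual layer-norms and a feed-forward sublayer."""

    def __init__(self, cfg: AttentionConfig, tcn: TCNConfig,
                 ffn_hidden: int = 120, dropout: float = 0.1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        f = cfg.feature_size
        self.cfg = cfg
        self.mha = MultiHeadAttention(cfg, tcn, rng)
        self.ln1 = LayerNorm(f)
        self.ffn = Sequential(
            Linear(f, ffn_hidden, rng=rng),
            ReLU(),
            Dropout(dropout),
            Linear(ffn_hidden, f, rng=rng),
        )
        self.ln2 = LayerNorm(f)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mha_out = self.mha(x)
        res = self.mha.last_query_path if self.cfg.residual_source == "tcn" else x
        y1 = self.ln1(res + mha_out)
        y2 = self.ln2(y1 + self.ffn(y1))
        return y2

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g2 = self.ln2.backward(grad)
        g1 = g2 + self.ffn.backward(g2)
        gr = self.ln1.backward(g1)
        if self.cfg.residual_source == "tcn":
            return self.mha.backward(gr, grad_query_path=gr)
        return self.mha.backward(gr) + gr


class ClassifierHead(Module):
    """Two fully connected layers over the flattened encoder output."""

    def __init__(self, in_features: int, hidden: int, n_classes: int,
                 dropout: float = 0.1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.net = Sequential(
            Flatten(),
            Linear(in_features, hidden, rng=rng),
            ReLU(),
            Dropout(dropout),
            Linear(hidden, n_classes, rng=rng, gain=1.0),
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)
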