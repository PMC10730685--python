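"""Multiscale convolutional front-end.

Three parallel branches convolve the raw conductance segment with kernels
spanning long (2 s), medium (1 s), and short (0.1 s) windows — 1,024, 512 and
50 samples at 512 Hz — so the network sees both the slow tonic trend and the
fast phasic transients.  Each branch applies three convolutions (each
followed by batch normalization and GELU) and two max-pooling stages, with
dropout after the first pooling; branch outputs are cropped to a common
temporal length and concatenated channel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nn import BatchNorm1d, Conv1d, Dropout, GELU, MaxPool1d, Module, Sequential


class ConfigurationError(ValueError):
    """Branch geometries cannot be harmonized."""


@dataclass(frozen=True)
class BranchConfig:
    """Geometry of one multiscale branch."""

    window_seconds: float
    kernel_size: int
    stride: int
    conv_channels: tuple[int, int, int]
    pool_sizes: tuple[int, int]
    pool_strides: tuple[int, int]
    mid_kernel_size: int = 8
    dropout_rate: float = 0.5

    def output_length(self, length: int) -> int:
        """Closed-form temporal length after the full branch."""
        l = (length - self.kernel_size) // self.stride + 1  # first conv, valid
        l = (l - self.pool_sizes[0]) // self.pool_strides[0] + 1
        # interior convs are 'same'-padded: length preserved
        l = (l - self.pool_sizes[1]) // self.pool_strides[1] + 1
        return l


def default_branch_configs(
    sampling_rate: float = 512.0,
    conv_channels: tuple[int, int, int] = (32, 32, 30),
    dropout_rate: float = 0.5,
) -> tuple[BranchConfig, BranchConfig, BranchConfig]:
    """Kernels for the 2 s / 1 s / 0.1 s windows at the given rate.

    The long and medium kernels are ``round(window * rate)`` (1,024 and 512
    at 512 Hz); the short branch uses the fixed 50-sample kernel.  Strides and
    pool geometries are chosen so all three branches emit at least 75 time
    steps on a 5.5 s segment.
    """
    long = BranchConfig(
        window_seconds=2.0,
        kernel_size=round(2.0 * sampling_rate),
        stride=5,
        conv_channels=conv_channels,
        pool_sizes=(2, 2),
        pool_strides=(2, 2),
        dropout_rate=dropout_rate,
    )
    medium = BranchConfig(
        window_seconds=1.0,
        kernel_size=round(1.0 * sampling_rate),
        stride=6,
        conv_channels=conv_channels,
        pool_sizes=(2, 2),
        pool_strides=(2, 2),
        dropout_rate=dropout_rate,
    )
    short = BranchConfig(
        window_seconds=0.1,
        kernel_size=50,
        stride=6,
        conv_channels=conv_channels,
        pool_sizes=(2, 3),
        pool_strides=(2, 3),
        dropout_rate=dropout_rate,
    )
    return (short, medium, long)


def vary_branch_window(cfg: BranchConfig, window_seconds: float,
                       sampling_rate: float = 512.0) -> BranchConfig:
    """A branch config with its window changed; kernel = round(window * rate)."""
    return replace(cfg, window_seconds=window_seconds,
                   kernel_size=round(window_seconds * sampling_rate))


class Branch(Module):
    """conv -> pool -> dropout -> conv -> conv -> pool, with BN+GELU per conv."""

    def __init__(self, cfg: BranchConfig, in_channels: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c0, c1, c2 = cfg.conv_channels
        self.cfg = cfg
        self.net = Sequential(
            # first conv consumes the raw signal: no input gradient needed
            Conv1d(in_channels, c0, cfg.kernel_size, cfg.stride, "valid", rng=rng,
                   needs_input_grad=False),
            BatchNorm1d(c0),
            GELU(),
            MaxPool1d(cfg.pool_sizes[0], cfg.pool_strides[0]),
            Dropout(cfg.dropout_rate),
            Conv1d(c0, c1, cfg.mid_kernel_size, 1, "same", rng=rng),
            BatchNorm1d(c1),
            GELU(),
            Conv1d(c1, c2, cfg.mid_kernel_size, 1, "same", rng=rng),
            BatchNorm1d(c2),
            GELU(),
            MaxPool1d(cfg.pool_sizes[1], cfg.pool_strides[1]),
        )

    @property
    def out_channels(self) -> int:
        return self.cfg.conv_channels[-1]

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)


class MSCN(Module):
    """The three-branch front-end with channel-wise concatenation.

    Branch outputs are left-cropped to a common temporal length before
    concatenation (``crop_to`` if given, otherwise the minimum branch
    length); a branch shorter than ``crop_to`` is a configuration error.
    """

    def __init__(
        self,
        configs: tuple[BranchConfig, ...],
        in_channels: int = 1,
        crop_to: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.branches = [Branch(cfg, in_channels, rng) for cfg in configs]
        self.crop_to = crop_to

    @property
    def out_channels(self) -> int:
        return sum(b.out_channels for b in self.branches)

    def output_length(self, length: int) -> int:
        lmin = min(b.cfg.output_length(length) for b in self.branches)
        if self.crop_to is not None:
            if lmin < self.crop_to:
                raise ConfigurationError(
                    f"branch lengths (min {lmin}) are shorter than the "
                    f"required feature length {self.crop_to}"
                )
            return self.crop_to
        return lmin

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [b(x) for b in self.branches]
        lengths = [o.shape[1] for o in outs]
        target = self.output_length(x.shape[1])
        self._cache = (lengths, [o.shape[2] for o in outs])
        return np.concatenate([o[:, :target, :] for o in outs], axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        lengths, channels = self._cache
        n, target, _ = grad.shape
        dx = None
        offset = 0
        for branch, l, c in zip(self.branches, lengths, channels):
            g = np.zeros((n, l, c), dtype=grad.dtype)
            g[:, :target, :] = grad[:, :, offset : offset + c]
            offset += c
            gx = branch.backward(g)
            if gx is not None:
                dx = gx if dx is None else dx + gx
        return dx
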