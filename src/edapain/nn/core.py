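"""Minimal layer framework: parameters, modules, and the training loss.

Every layer implements ``forward`` (caching what backward needs) and
``backward`` (returning the input gradient and accumulating parameter
gradients).  Gradients are exact; the test suite checks them against central
finite differences.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class; discovers Params and sub-Modules from instance attributes."""

    def __init__(self) -> None:
        self.training = True

    # -- graph traversal -----------------------------------------------------
    def _children(self):
        for key, val in vars(self).items():
            if isinstance(val, Module):
                yield key, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{key}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for key, val in vars(self).items():
            if isinstance(val, Param):
                yield prefix + key, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Param):
                        yield f"{prefix}{key}.{i}", item
        for key, child in self._children():
            yield from child.named_parameters(f"{prefix}{key}.")

    def parameters(self) -> list[Param]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    # -- state ---------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    # -- computation ---------------------------------------------------------
    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def reseed_dropout(module: Module, seed) -> None:
    """Give every dropout layer in ``module`` a fresh spawned generator."""
    drops = [m for m in module.modules() if hasattr(m, "_dropout_rng")]
    if not drops:
        return
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    children = seed.spawn(len(drops))
    for layer, child in zip(drops, children):
        layer._dropout_rng = np.random.default_rng(child)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stabilized softmax (max subtraction; value unchanged)."""
    shifted = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over the batch.

    Returns (loss, dloss/dlogits, class probabilities).
    """
    n = logits.shape[0]
    probs = softmax(logits, axis=-1)
    eps = np.finfo(probs.dtype).tiny
    loss = float(-np.log(probs[np.arange(n), targets] + eps).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    dlogits /= n
    return loss, dlogits, probs
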