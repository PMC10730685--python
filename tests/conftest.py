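import numpy as np
import pytest

from edapain.nn import Module
from edapain.protocol import ProtocolConfig
from edapain.simulate import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_protocol():
    """A down-scaled protocol: 3 usable subjects, 3 reps per class."""
    return ProtocolConfig(n_recruited=5, n_excluded=2, reps_per_class=3)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_protocol):
    return generate_cohort(tiny_protocol, separation=2.0, seed=7)


def cast_float64(module: Module) -> Module:
    """Promote every parameter and running statistic to float64 in place."""
    for p in module.parameters():
        p.value = p.value.astype(np.float64)
        p.grad = np.zeros_like(p.value)
    for m in module.modules():
        if hasattr(m, "running_mean"):
            m.running_mean = m.running_mean.astype(np.float64)
            m.running_var = m.running_var.astype(np.float64)
    return module


def numeric_gradcheck(
    module: Module,
    x: np.ndarray,
    rng: np.random.Generator,
    n_entries: int = 6,
    h: float = 1e-6,
    rtol: float = 1e-4,
    atol: float = 1e-7,
    check_input_grad: bool = True,
) -> None:
    """Compare analytic gradients with central finite differences.

    The scalar objective is a fixed random linear functional of the output,
    so its exact gradient is the backward pass applied to that functional.
    """
    cast_float64(module)
    # jitter parameters off exact zeros so no ReLU/max sits on its kink
    for p in module.parameters():
        p.value += 0.05 * rng.standard_normal(p.value.shape)
    x = x.astype(np.float64)
    weight = rng.standard_normal(module.forward(x).shape)

    def objective(inp):
        return float((module.forward(inp) * weight).sum())

    module.zero_grad()
    module.forward(x)
    dx = module.backward(weight)

    if check_input_grad and dx is not None:
        flat = x.reshape(-1)
        idxs = rng.choice(flat.size, size=min(n_entries, flat.size), replace=False)
        for i in idxs:
            orig = flat[i]
            step = h * max(1.0, abs(orig))
            flat[i] = orig + step
            up = objective(x)
            flat[i] = orig - step
            down = objective(x)
            flat[i] = orig
            num = (up - down) / (2 * step)
            ana = dx.reshape(-1)[i]
            assert np.isclose(ana, num, rtol=rtol, atol=max(atol, rtol * abs(num))), (
                f"input grad mismatch at {i}: analytic {ana}, numeric {num}"
            )

    for name, p in module.named_parameters():
        flat = p.value.reshape(-1)
        gflat = p.grad.reshape(-1)
        idxs = rng.choice(flat.size, size=min(n_entries, flat.size), replace=False)
        for i in idxs:
            orig = flat[i]
            step = h * max(1.0, abs(orig))
            flat[i] = orig + step
            up = objective(x)
            flat[i] = orig - step
            down = objective(x)
            flat[i] = orig
            num = (up - down) / (2 * step)
            ana = gflat[i]
            assert np.isclose(ana, num, rtol=rtol, atol=max(atol, rtol * abs(num))), (
                f"param {name}[{i}]: analytic {ana}, numeric {num}"
            )
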