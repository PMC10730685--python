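"""Full classifier assembly: MSCN -> SEResNet -> causal-attention encoder -> head.

`ModelConfig` collects every architectural hyperparameter; `build_model`
instantiates the network for a given raw segment length, and `dry_run` traces
every intermediate shape symbolically-by-execution so geometry errors fail
fast and name the module boundary at fault.  Ablation variants are expressed
through the ``use_se`` / ``use_encoder`` flags.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoder import AttentionConfig, ClassifierHead, EncoderBlock, TCNConfig
from .mscn import MSCN, BranchConfig, ConfigurationError, default_branch_configs
from .nn import Module, Transpose
from .seresnet import SEConfig, SEResNet, SEState


@dataclass(frozen=True)
class ModelConfig:
    branches: tuple[BranchConfig, ...] = field(default_factory=default_branch_configs)
    se: SEConfig = field(default_factory=SEConfig)
    tcn: TCNConfig = field(default_factory=TCNConfig)
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    ffn_hidden: int = 120
    head_hidden: int = 64
    head_dropout: float = 0.1
    encoder_dropout: float = 0.1
    n_classes: int = 2
    use_se: bool = True
    use_encoder: bool = True


def small_model_config(n_classes: int = 2) -> ModelConfig:
    """A desk-scale preset: same architecture, narrower channels.

    Used for simulation studies on small synthetic cohorts where the full
    channel widths would be wasteful.
    """
    return ModelConfig(
        branches=default_branch_configs(conv_channels=(8, 8, 8), dropout_rate=0.2),
        se=SEConfig(reduction_ratio=4),
        ffn_hidden=64,
        head_hidden=32,
        n_classes=n_classes,
    )


class PainIntensityClassifier(Module):
    """The end-to-end network mapping raw segments to class logits."""

    def __init__(self, cfg: ModelConfig, input_length: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.input_length = input_length
        feat = cfg.attention.feature_size
        self.mscn = MSCN(cfg.branches, in_channels=1, crop_to=feat, rng=rng)
        # raises ConfigurationError early if branches cannot reach `feat`
        self.mscn.output_length(input_length)
        channels = self.mscn.out_channels
        self.se = SEResNet(channels, cfg.se, rng) if cfg.use_se else None
        if cfg.use_encoder:
            self.transpose = Transpose()
            self.encoder = EncoderBlock(
                cfg.attention, cfg.tcn, cfg.ffn_hidden, cfg.encoder_dropout, rng
            )
        else:
            self.transpose = None
            self.encoder = None
        self.head = ClassifierHead(
            feat * channels, cfg.head_hidden, cfg.n_classes, cfg.head_dropout, rng
        )

    @property
    def se_state(self) -> SEState | None:
        return self.se.last_state if self.se is not None else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, :, None]
        h = self.mscn(x)
        if self.se is not None:
            h = self.se(h)
        if self.encoder is not None:
            h = self.transpose(h)
            h = self.encoder(h)
        return self.head(h)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.head.backward(grad)
        if self.encoder is not None:
            g = self.encoder.backward(g)
            g = self.transpose.backward(g)
        if self.se is not None:
            g = self.se.backward(g)
        g = self.mscn.backward(g)
        return g[..., 0] if g is not None else None


def build_model(cfg: ModelConfig, input_length: int, seed: int = 0) -> PainIntensityClassifier:
    return PainIntensityClassifier(cfg, input_length, seed)


def dry_run(cfg: ModelConfig, input_length: int) -> list[tuple[str, tuple[int, ...]]]:
    """Trace every intermediate shape from raw input to softmax logits.

    Executes the model in eval mode on a 2-example zero batch; any geometry
    mismatch raises a ConfigurationError naming the failing boundary.
    """
    try:
        model = build_model(cfg, input_length)
    except Exception as exc:
        raise ConfigurationError(f"model construction failed: {exc}") from exc
    model.eval()
    x = np.zeros((2, input_length, 1), dtype=np.float32)
    trace: list[tuple[str, tuple[int, ...]]] = [("input", x.shape)]

    def run(name: str, fn, val):
        try:
            out = fn(val)
        except Exception as exc:
            raise ConfigurationError(f"shape error at {name}: {exc}") from exc
        trace.append((name, out.shape))
        return out

    for branch, label in zip(model.mscn.branches, ("short", "medium", "long")):
        run(f"mscn.{label}_branch", branch, x)
    h = run("mscn.concat", model.mscn, x)
    if model.se is not None:
        h = run("seresnet", model.se, h)
    if model.encoder is not None:
        h = run("transpose", model.transpose, h)
        h = run("encoder", model.encoder, h)
    logits = run("head.logits", model.head, h)
    trace.append(("softmax", logits.shape))
    return trace


# -- (de)serialization -------------------------------------------------------

def model_config_to_dict(cfg: ModelConfig) -> dict:
    return dataclasses.asdict(cfg)


def model_config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    d["branches"] = tuple(
        BranchConfig(**{**b, "conv_channels": tuple(b["conv_channels"]),
                        "pool_sizes": tuple(b["pool_sizes"]),
                        "pool_strides": tuple(b["pool_strides"])})
        for b in d["branches"]
    )
    d["se"] = SEConfig(**d["se"])
    d["tcn"] = TCNConfig(**d["tcn"])
    d["attention"] = AttentionConfig(**d["attention"])
    return ModelConfig(**d)


def _named_modules(module: Module, prefix: str = ""):
    yield prefix.rstrip("."), module
    for key, child in module._children():
        yield from _named_modules(child, f"{prefix}{key}.")


def save_checkpoint(model: PainIntensityClassifier, path: str | Path) -> None:
    """Serialize parameters, running statistics, and the exact ModelConfig."""
    arrays: dict[str, np.ndarray] = {}
    for name, p in model.named_parameters():
        arrays[f"param:{name}"] = p.value
    for name, mod in _named_modules(model):
        if hasattr(mod, "running_mean"):
            arrays[f"buffer:{name}.running_mean"] = mod.running_mean
            arrays[f"buffer:{name}.running_var"] = mod.running_var
    meta = {
        "config": model_config_to_dict(model.cfg),
        "input_length": model.input_length,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> PainIntensityClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]))
        cfg = model_config_from_dict(meta["config"])
        model = build_model(cfg, meta["input_length"])
        params = dict(model.named_parameters())
        for key in data.files:
            if key.startswith("param:"):
                params[key[len("param:"):]].value = data[key].copy()
            elif key.startswith("buffer:"):
                name, attr = key[len("buffer:"):].rsplit(".", 1)
                mod = dict(_named_modules(model))[name]
                setattr(mod, attr, data[key].copy())
    model.eval()
    return model
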