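"""Configuration files, overrides, validation, and run manifests.

A run is configured by a single nested YAML file with three sections —
``protocol`` (stimulation protocol), ``model`` (architecture) and ``train``
(optimization recipe).  Precedence is defaults < file < command-line
overrides.  Unknown keys are a hard error so typos never pass silently, and
validation reports every violated invariant it can find, not just the first.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import TrainConfig
from .model import ModelConfig, model_config_from_dict, model_config_to_dict
from .protocol import ProtocolConfig
from . import __version__


class ConfigError(ValueError):
    """One or more configuration violations; the message lists them all."""


@dataclass
class Configs:
    protocol: ProtocolConfig
    model: ModelConfig
    train: TrainConfig
    raw: dict = field(default_factory=dict)


def default_config_dict() -> dict:
    return {
        "protocol": dataclasses.asdict(ProtocolConfig()),
        "model": model_config_to_dict(ModelConfig()),
        "train": dataclasses.asdict(TrainConfig()),
    }


def _merge(base: dict, update: dict, path: str, errors: list[str]) -> None:
    for key, val in update.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            errors.append(f"unknown configuration key: {here}")
            continue
        if isinstance(base[key], dict) and isinstance(val, dict):
            _merge(base[key], val, here, errors)
        elif isinstance(base[key], list) and isinstance(val, list) \
                and base[key] and isinstance(base[key][0], dict):
            if len(val) != len(base[key]):
                errors.append(
                    f"{here}: expected {len(base[key])} entries, got {len(val)}"
                )
                continue
            for i, item in enumerate(val):
                if isinstance(item, dict):
                    _merge(base[key][i], item, f"{here}[{i}]", errors)
                else:
                    errors.append(f"{here}[{i}]: expected a mapping")
        else:
            base[key] = val


def _apply_override(cfg: dict, spec: str, errors: list[str]) -> None:
    if "=" not in spec:
        errors.append(f"override {spec!r} is not of the form key.path=value")
        return
    keypath, raw_val = spec.split("=", 1)
    val = yaml.safe_load(raw_val)
    node = cfg
    keys = keypath.strip().split(".")
    for key in keys[:-1]:
        if not isinstance(node, dict) or key not in node:
            errors.append(f"unknown configuration key: {keypath}")
            return
        node = node[key]
    if not isinstance(node, dict) or keys[-1] not in node:
        errors.append(f"unknown configuration key: {keypath}")
        return
    node[keys[-1]] = val


def load_config(
    path: str | Path | None = None, overrides: list[str] | None = None
) -> Configs:
    """Merge defaults, an optional YAML file, and ``key.path=value`` overrides.

    An empty (or missing) file yields pure defaults.  Raises ConfigError with
    every violation found.
    """
    cfg = default_config_dict()
    errors: list[str] = []
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        _merge(cfg, loaded, "", errors)
    for spec in overrides or []:
        _apply_override(cfg, spec, errors)
    if errors:
        raise ConfigError("; ".join(errors))

    sections: dict[str, object] = {}
    for name, builder in (
        ("protocol", lambda d: ProtocolConfig(**{**d, "interval_range": tuple(d["interval_range"])})),
        ("model", model_config_from_dict),
        ("train", lambda d: TrainConfig(**{**d, "betas": tuple(d["betas"])})),
    ):
        try:
            sections[name] = builder(cfg[name])
        except (TypeError, ValueError) as exc:
            errors.append(f"{name}: {exc}")
    if errors:
        raise ConfigError("; ".join(errors))
    return Configs(
        protocol=sections["protocol"],
        model=sections["model"],
        train=sections["train"],
        raw=cfg,
    )


@dataclass
class RunManifest:
    """Traceability record written next to every artifact a command produces."""

    command: str
    config: dict
    seed: int
    outputs: list[str]
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
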