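"""Run configuration: validated, YAML-backed, with the reference defaults.

The default architecture mirrors the published parameterization: encoder GRU
layers of 36/25 -> 20 -> 16 units, a 10-unit coupling layer, a mirrored
decoder, ReLU activations with a Sigmoid output layer, batch normalization
after layers 2, 3, 5 and 6, Adam with learning rate 0.001 and batch size 32.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .model import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class ArchitectureBlock:
    dim_e: int = 36
    dim_o: int = 25
    hidden_units: tuple[int, int] = (20, 16)
    code_dim: int = 10
    hidden_activation: str = "relu"
    output_activation: str = "sigmoid"
    batch_norm_layers: tuple[int, ...] = (2, 3, 5, 6)

    def validate(self):
        if min(self.dim_e, self.dim_o, self.code_dim) < 1:
            raise ConfigError("dimensions must be positive")
        if any(u < 1 for u in self.hidden_units):
            raise ConfigError("hidden units must be positive")


@dataclass(frozen=True)
class OptimizerBlock:
    name: str = "adam"
    lr: float = 0.001
    batch_size: int = 32
    fine_tune_epochs: int = 100
    pretrain_steps: int = 60

    def validate(self):
        if self.name != "adam":
            raise ConfigError(f"unsupported optimizer {self.name!r}")
        if self.lr <= 0 or self.batch_size < 1:
            raise ConfigError("lr must be > 0 and batch_size >= 1")
        if self.fine_tune_epochs < 0 or self.pretrain_steps < 0:
            raise ConfigError("epoch/step counts must be >= 0")


@dataclass(frozen=True)
class CouplingBlock:
    alpha: float = 0.4
    metric_mode: str = "euclidean"
    metric_file: str | None = None
    coupling_form: str = "mahalanobis"

    def validate(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.metric_mode not in ("euclidean", "learned"):
            raise ConfigError("metric_mode must be 'euclidean' or 'learned'")
        if self.coupling_form not in ("mahalanobis", "bilinear"):
            raise ConfigError("coupling_form must be 'mahalanobis' or 'bilinear'")


@dataclass(frozen=True)
class DataBlock:
    path: str | None = None
    steps_per_epoch: int = 8

    def validate(self):
        if self.steps_per_epoch < 1:
            raise ConfigError("steps_per_epoch must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    architecture: ArchitectureBlock = field(default_factory=ArchitectureBlock)
    optimizer: OptimizerBlock = field(default_factory=OptimizerBlock)
    coupling: CouplingBlock = field(default_factory=CouplingBlock)
    data: DataBlock = field(default_factory=DataBlock)
    seed: int = 0
    out_dir: str = "."

    def validate(self) -> "RunConfig":
        for block in (self.architecture, self.optimizer, self.coupling, self.data):
            block.validate()
        return self

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            alpha=self.coupling.alpha,
            code_dim=self.architecture.code_dim,
            lr=self.optimizer.lr,
            batch_size=self.optimizer.batch_size,
            fine_tune_epochs=self.optimizer.fine_tune_epochs,
            pretrain_steps=self.optimizer.pretrain_steps,
            coupling_form=self.coupling.coupling_form,
            seed=self.seed,
        )


_BLOCKS = {
    "architecture": ArchitectureBlock,
    "optimizer": OptimizerBlock,
    "coupling": CouplingBlock,
    "data": DataBlock,
}


def _build_block(cls, raw: dict, context: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file -> defaults)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    top_known = set(_BLOCKS) | {"seed", "out_dir"}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        if name in raw:
            block_raw = raw[name]
            if not isinstance(block_raw, dict):
                raise ConfigError(f"{name} must be a mapping")
            kwargs[name] = _build_block(cls, block_raw, name)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "out_dir" in raw:
        kwargs["out_dir"] = str(raw["out_dir"])
    return RunConfig(**kwargs).validate()


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(path: str | Path, config: RunConfig) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_to_plain(asdict(config)), sort_keys=False))
    return path
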