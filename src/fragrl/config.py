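"""Run configuration: YAML/JSON loading with strict schema validation.

Unknown keys are rejected by name; all defaults are materialized so the fully
resolved configuration can be echoed into the run directory.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .a2c import TimeSchedule, TrainConfig
from .rewards import DEFAULT_TOXICOPHORES, PropertyRanges, RewardWeights

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    heads: int = 4
    blocks: int = 2
    d_f: int = 64
    d_p: int = 16
    head_layers: tuple[int, ...] = (128, 64)
    max_positions: int = 32


@dataclass
class RewardConfig:
    ranges: dict = field(
        default_factory=lambda: {
            "E": [1, 1],
            "MW": [200.0, 500.0],
            "logP": [1.5, 5.5],
            "PSA": [40.0, 120.0],
            "T": [0, 2],
        }
    )
    weights: dict = field(
        default_factory=lambda: {
            "validity": 0.1, "per_property": 0.15, "gate": 0.2, "activity": 0.3,
        }
    )
    toxicophores: str | None = None  # path to a SMARTS list, default screen if None

    def property_ranges(self) -> PropertyRanges:
        return PropertyRanges(
            ranges={k: tuple(v) for k, v in self.ranges.items()}
        )

    def reward_weights(self) -> RewardWeights:
        return RewardWeights(**self.weights)

    def screen(self) -> tuple[str, ...]:
        if self.toxicophores is None:
            return DEFAULT_TOXICOPHORES
        lines = Path(self.toxicophores).read_text().splitlines()
        return tuple(s.strip() for s in lines if s.strip() and not s.startswith("#"))


@dataclass
class TrainSection:
    gamma: float = 0.99
    lr_actor: float = 3e-4
    lr_critic: float = 3e-4
    entropy_coef: float = 0.01
    time: int = 1
    epochs: int = 100
    batch_size: int = 32
    use_property_optimization: bool = True
    time_schedule: dict = field(
        default_factory=lambda: {"mode": "fixed", "max_time": 6,
                                 "window": 50, "tolerance": 0.01}
    )


@dataclass
class DockingConfig:
    aggregator: str = "best"
    workers: int = 4
    retry_limit: int = 2
    engine: str = "mock"


@dataclass
class RunConfig:
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    reward: RewardConfig = field(default_factory=RewardConfig)
    train: TrainSection = field(default_factory=TrainSection)
    docking: DockingConfig = field(default_factory=DockingConfig)

    def train_config(self, seed: int | None = None) -> TrainConfig:
        t = self.train
        return TrainConfig(
            gamma=t.gamma,
            lr_actor=t.lr_actor,
            lr_critic=t.lr_critic,
            entropy_coef=t.entropy_coef,
            time=t.time,
            epochs=t.epochs,
            batch_size=t.batch_size,
            seed=self.seed if seed is None else seed,
            use_property_optimization=t.use_property_optimization,
            ranges=self.reward.property_ranges(),
            weights=self.reward.reward_weights(),
            time_schedule=TimeSchedule(**t.time_schedule),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def echo(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_SECTIONS = {
    "model": ModelConfig,
    "reward": RewardConfig,
    "train": TrainSection,
    "docking": DockingConfig,
}


def _build_section(cls, obj: dict, context: str):
    if not isinstance(obj, dict):
        raise ConfigError(f"section {context!r} must be a mapping")
    fields = {f.name for f in cls.__dataclass_fields__.values()}
    unknown = set(obj) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {context!r}: {', '.join(sorted(unknown))}"
        )
    kwargs = dict(obj)
    if cls is ModelConfig and "head_layers" in kwargs:
        kwargs["head_layers"] = tuple(kwargs["head_layers"])
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad value in {context!r}: {exc}") from exc


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load YAML/JSON config; missing file sections fall back to defaults."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text)) or {}
    if overrides:
        data = _deep_merge(data, overrides)
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    unknown = set(data) - ({"seed"} | set(_SECTIONS))
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    if "seed" in data:
        if not isinstance(data["seed"], int):
            raise ConfigError("seed must be an integer")
        kwargs["seed"] = data["seed"]
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build_section(cls, data[name], name)
    cfg = RunConfig(**kwargs)
    cfg.reward.property_ranges()  # validate bounds early
    return cfg


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out
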