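"""Experiment configuration: one YAML file mirroring every stage's knobs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from vesselnoise.model import ModelConfig
from vesselnoise.patches import SamplingConfig
from vesselnoise.preprocessing import PreprocessConfig


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 0.1
    momentum: float = 0.9
    seed: int = 0

    def validate(self) -> "TrainConfig":
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch size >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        return self


@dataclass
class ExperimentConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    rotate: bool = True
    threshold: float = 0.5
    direction_mode: str = "zoom_in"
    seed: int = 0

    def validate(self) -> "ExperimentConfig":
        self.preprocess.validate()
        self.sampling.validate()
        self.model.validate()
        self.train.validate()
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        kwargs = dict(data)
        for name, sub in (
            ("preprocess", PreprocessConfig),
            ("sampling", SamplingConfig),
            ("model", ModelConfig),
            ("train", TrainConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        known = {f.name for f in fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
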