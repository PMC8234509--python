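"""Pipeline configuration: one YAML-serialisable object for a whole run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping

import yaml

from .scoring import TrainConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything a reproducible end-to-end run needs.

    The on-disk form is YAML; unknown keys are rejected so a typo in a
    config file fails instead of silently using a default.
    """

    n_cases: int = 5
    n_frames: int = 30
    image_size: int = 64
    trajectory: dict = field(default_factory=lambda: {"type": "random-walk", "start": 0.7, "step_sd": 0.08})
    occluder_mix: dict = field(
        default_factory=lambda: {"bubble": 1 / 3, "bile": 1 / 3, "debris": 1 / 3}
    )
    scorer: str = "rule-based"  # "rule-based" | "model"
    model_path: str | None = None
    grading_mode: str = "score"  # "score" (score<=2 proxy) | "fraction"
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scorer not in ("rule-based", "model"):
            raise ValueError("scorer must be 'rule-based' or 'model'")
        if self.scorer == "model" and not self.model_path:
            raise ValueError("scorer 'model' requires model_path")
        if self.grading_mode not in ("score", "fraction"):
            raise ValueError("grading_mode must be 'score' or 'fraction'")
        if self.n_cases < 1 or self.n_frames < 3:
            raise ValueError("need n_cases >= 1 and n_frames >= 3")
        if isinstance(self.train, Mapping):
            self.train = TrainConfig(**self.train)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["train"]["channels"] = list(self.train.channels)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "train" in d and isinstance(d["train"], Mapping):
            t = dict(d["train"])
            t_known = {f.name for f in fields(TrainConfig)}
            t_unknown = set(t) - t_known
            if t_unknown:
                raise ValueError(f"unknown train config key(s): {sorted(t_unknown)}")
            if "channels" in t:
                t["channels"] = tuple(t["channels"])
            d["train"] = TrainConfig(**t)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
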