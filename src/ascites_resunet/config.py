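"""Run configuration: one YAML document driving every pipeline stage.

A single global seed is fanned out to the stages through documented
offsets (numpy ``SeedSequence``-style tuple seeding), so each stage is
independently reproducible from (config, seed) alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import AugmentSpec, WindowSpec
from .model import ModelConfig
from .training import TrainConfig

#: per-stage seed offsets for the global-seed fan-out
STAGE_OFFSETS = {"phantom": 1, "augment": 2, "split": 3, "folds": 4, "weights": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed, stable across runs and below 2**31."""
    ss = np.random.SeedSequence([global_seed, STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PhantomConfig:
    n_subjects_ascites: int = 15
    n_subjects_control: int = 15
    slices_per_subject: int = 10
    grid_size: int = 512
    pixel_spacing_mm: float = 0.74
    slice_thickness_mm: float = 5.0
    noise_sd_hu: float = 10.0
    pocket_prob: float = 0.8
    confounder_prob: float = 0.3


@dataclass
class RunConfig:
    data_root: str = "data"
    output_root: str = "runs"
    seed: int = 0
    target_size: int = 256
    split_ratio: float = 0.8
    target_per_class: int = 300
    detection_threshold: float = 0.001
    binarize_threshold: float = 0.5
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["augment"] = asdict(self.augment)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "phantom" in kwargs:
            kwargs["phantom"] = PhantomConfig(**kwargs["phantom"])
        if "window" in kwargs:
            kwargs["window"] = WindowSpec(**kwargs["window"])
        if "augment" in kwargs:
            aug = dict(kwargs["augment"])
            if "rotation_range_deg" in aug:
                aug["rotation_range_deg"] = tuple(aug["rotation_range_deg"])
            kwargs["augment"] = AugmentSpec(**aug)
        if "model" in kwargs:
            kwargs["model"] = ModelConfig(**kwargs["model"])
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        return cls(**kwargs)
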