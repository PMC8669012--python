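"""Pipeline configuration: every stage parameter with its standard default."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class PipelineConfig(BaseModel):
    """Every stage parameter, validated on load; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # tiling
    tile_px: int = Field(default=220, ge=1)
    max_white: float = Field(default=2.0 / 3.0, ge=0.0, le=1.0)
    white_level: float = Field(default=0.94, gt=0.0, le=1.0)
    microns_per_pixel: float = Field(default=0.5, gt=0.0)
    # split
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_seed: int = 0
    # training
    epochs: int = Field(default=100, ge=1)
    lr0: float = Field(default=0.001, gt=0.0)
    lr_decay: float = Field(default=0.9, gt=0.0)
    decay_every: int = Field(default=5, ge=1)
    momentum: float = Field(default=0.9, gt=0.0)
    adam_epsilon: float = Field(default=1e-7, gt=0.0)
    batch_size: int = Field(default=100, ge=1)
    loss_weight: float = Field(default=1.5, gt=0.0)
    backbone: str = "tiny_cnn"
    train_seed: int = 0
    augment: bool = True
    # post-processing
    grid_step: float = Field(default=0.05, gt=0.0, lt=0.5)
    tma_radius_um: float = Field(default=500.0, gt=0.0)

    @field_validator("fractions")
    @classmethod
    def _fractions_sum_to_one(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_train_config(self):
        from .classifier import TrainConfig

        return TrainConfig(
            epochs=self.epochs,
            lr0=self.lr0,
            lr_decay=self.lr_decay,
            decay_every=self.decay_every,
            momentum=self.momentum,
            adam_epsilon=self.adam_epsilon,
            batch_size=self.batch_size,
            loss_weight=self.loss_weight,
            seed=self.train_seed,
            backbone=self.backbone,
            augment=self.augment,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
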