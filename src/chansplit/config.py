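"""Experiment configuration schema (pydantic) with YAML round-trip.

Cross-field validity — patch size vs hierarchy depth, mode IIb forcing LC
off — is enforced at load time so invalid presets fail before any compute.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator


class NoiseSection(BaseModel):
    gaussian_sigma: float = Field(10.0, ge=0)
    poisson_scale: float = Field(0.0, ge=0)


class TaskSection(BaseModel):
    k: int = Field(2, ge=2, le=4)
    kinds: list[str] = ["filaments", "puncta"]
    weights: Optional[list[float]] = None
    mode: Literal["I", "II", "IIb", "III"] = "I"
    density: float = Field(2e-4, ge=0)
    frame_size: int = Field(256, ge=64)
    noise: NoiseSection = NoiseSection()
    similarity_scale: Optional[float] = Field(None, ge=1)

    @model_validator(mode="after")
    def _check(self):
        if self.weights is not None and len(self.weights) != self.k:
            raise ValueError("weights length must equal k")
        if len(self.kinds) != self.k and self.similarity_scale is None:
            raise ValueError("kinds length must equal k")
        if self.similarity_scale is not None and self.k != 2:
            raise ValueError("similarity_scale only valid for k = 2")
        return self


class ModelSection(BaseModel):
    hierarchy_levels: int = Field(2, ge=2)
    base_filters: int = Field(16, ge=1)
    z_dim: int = Field(4, ge=1)
    L: int = Field(1, ge=0)
    variant: Literal["lean_lc", "deep_lc"] = "lean_lc"
    dims: Literal[2, 3] = 2
    predict_logvar: bool = True


class LossSection(BaseModel):
    w: float = Field(0.9, ge=0, le=1)
    alpha: Optional[float] = Field(None, gt=0)
    kl_free_nats: float = Field(0.0, ge=0)
    likelihood_variance_mode: Literal["fixed", "learned"] = "learned"
    fixed_sigma: float = Field(1.0, gt=0)


class TrainSection(BaseModel):
    batch_size: int = Field(32, ge=1)
    max_epoch: int = Field(400, ge=0)
    learning_rate: float = Field(0.001, gt=0)
    scheduler_patience: int = Field(150, ge=0)
    steps_per_epoch: int = Field(20, ge=1)
    val_batches: int = Field(2, ge=1)
    patch_size: int = Field(64, ge=16)


class InferenceSection(BaseModel):
    tile_size: int = Field(64, ge=8)
    center_size: int = Field(32, ge=4)
    samples: int = Field(50, ge=2)

    @model_validator(mode="after")
    def _check(self):
        if self.center_size > self.tile_size:
            raise ValueError("center_size must be <= tile_size")
        return self


class ExperimentConfig(BaseModel):
    task: TaskSection = TaskSection()
    model: ModelSection = ModelSection()
    loss: LossSection = LossSection()
    train: TrainSection = TrainSection()
    inference: InferenceSection = InferenceSection()
    calibration_bins: int = Field(20, ge=3)
    output_dir: str = "chansplit_run"
    seed: int = 0

    @model_validator(mode="after")
    def _cross_field(self):
        if self.task.mode == "IIb" and self.model.L > 0:
            raise ValueError("mode IIb requires L = 0 (LC disabled)")
        div = 2 ** self.model.hierarchy_levels
        if self.train.patch_size % div:
            raise ValueError(
                f"patch_size must be divisible by 2^hierarchy_levels = {div}"
            )
        if self.model.L > self.model.hierarchy_levels - 1:
            raise ValueError("L must be <= hierarchy_levels - 1")
        return self


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ExperimentConfig.model_validate(data)


def dump_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


def module_seed(global_seed: int, tag: str) -> int:
    """Derive a per-module seed from the global seed and a module tag."""
    ss = np.random.SeedSequence([global_seed, *tag.encode()])
    return int(ss.generate_state(1)[0])


TINY_2CH_PRESET = {
    "task": {"k": 2, "kinds": ["filaments", "puncta"], "mode": "I",
             "density": 3e-4, "frame_size": 256,
             "noise": {"gaussian_sigma": 10.0, "poisson_scale": 3.0}},
    "model": {"hierarchy_levels": 2, "base_filters": 16, "z_dim": 4, "L": 1},
    "loss": {"w": 0.9, "alpha": None},
    "train": {"batch_size": 8, "max_epoch": 6, "steps_per_epoch": 25,
              "patch_size": 64, "learning_rate": 0.003},
    "inference": {"tile_size": 64, "center_size": 32, "samples": 20},
    "output_dir": "tiny_2ch_run",
}
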