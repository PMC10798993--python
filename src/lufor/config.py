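"""Schema-validated pipeline configuration.

One YAML file drives the whole pipeline; sections mirror the stage
configs. Unknown keys are rejected. A single global seed fans out to
per-stage seeds through numpy's SeedSequence spawning, so stages are
individually reproducible without seed collisions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from lufor.active_learning import ALConfig
from lufor.model import FocalLossParams, ModelConfig, TrainConfig
from lufor.scenes import CorruptionConfig, SceneConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SceneSection(_Strict):
    height: int = 128
    width: int = 128
    pixel_size: float = 5.0
    n_scenes: int = 24
    annotated_fraction: float = 1 / 3
    test_fraction: float = 0.25
    noise_sd: float = 0.0
    loss_fraction: float = 0.5


class CorruptionSection(_Strict):
    boundary_shift_px: int = 0
    mislabel_fraction: float = 0.3
    drop_fraction: float = 0.3
    polygon_mix_fraction: float = 0.0


class ModelSection(_Strict):
    depth: int = 3
    base_filters: int = 12
    dropout_rate: float = 0.1
    batch_norm: bool = True


class LossSection(_Strict):
    gamma: float = 2.0
    alpha: float = 1.0


class TrainSection(_Strict):
    epochs: int = 45
    batch_size: int = 8
    learning_rate: float = 2e-3
    final_learning_rate: Optional[float] = 2e-4
    patch_size: int = 32


class ALSection(_Strict):
    entropy_threshold: float = 0.6
    entropy_scale: str = "nats"
    aggregation: str = "mean"
    n_cycles: int = 2


class AssessSection(_Strict):
    n_total: int = 400
    n_min: int = 5
    interpreter_error_rate: float = 0.0


class HotspotSection(_Strict):
    cell_size: float = 0.1
    bandwidth: float = 0.1
    kernel: str = "gaussian"
    sampling_stride: int = 1


class PipelineConfig(_Strict):
    seed: int = 0
    output_dir: str = "lufor_out"
    scenes: SceneSection = SceneSection()
    corruption: CorruptionSection = CorruptionSection()
    model: ModelSection = ModelSection()
    loss: LossSection = LossSection()
    train: TrainSection = TrainSection()
    active_learning: ALSection = ALSection()
    assessment: AssessSection = AssessSection()
    hotspots: HotspotSection = HotspotSection()

    # ---- derived stage configs -------------------------------------
    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % 2**31

    def scene_config(self) -> SceneConfig:
        s = self.scenes
        return SceneConfig(height=s.height, width=s.width, pixel_size=s.pixel_size,
                           noise_sd=s.noise_sd, loss_fraction=s.loss_fraction,
                           seed=self.stage_seed("scenes"))

    def corruption_config(self) -> CorruptionConfig:
        c = self.corruption
        return CorruptionConfig(boundary_shift_px=c.boundary_shift_px,
                                mislabel_fraction=c.mislabel_fraction,
                                drop_fraction=c.drop_fraction,
                                polygon_mix_fraction=c.polygon_mix_fraction,
                                seed=self.stage_seed("corruption"))

    def segmentation_model_config(self) -> ModelConfig:
        m = self.model
        return ModelConfig(depth=m.depth, base_filters=m.base_filters,
                           dropout_rate=m.dropout_rate, batch_norm=m.batch_norm,
                           seed=self.stage_seed("model"))

    def train_config(self) -> TrainConfig:
        t = self.train
        return TrainConfig(epochs=t.epochs, batch_size=t.batch_size,
                           learning_rate=t.learning_rate,
                           final_learning_rate=t.final_learning_rate,
                           patch_size=t.patch_size, seed=self.stage_seed("train"))

    def loss_params(self) -> FocalLossParams:
        return FocalLossParams(alpha=self.loss.alpha, gamma=self.loss.gamma)

    def al_config(self) -> ALConfig:
        a = self.active_learning
        return ALConfig(entropy_threshold=a.entropy_threshold,
                        entropy_scale=a.entropy_scale, aggregation=a.aggregation,
                        n_cycles=a.n_cycles, seed=self.stage_seed("al"))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
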