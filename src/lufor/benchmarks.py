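"""Bundled desk-scale benchmarks.

Two fixed experimental setups shared by the test suite, the acceptance
script and the examples:

* the active-learning benchmark: 24 scenes of 128x128 over 15 classes,
  8 initially annotated with corrupted labels (30% mislabeled pixels, 30%
  dropped), 2 AL cycles with the literal published selection rule (mean
  per-pixel entropy over forest-loss pixels > 0.6 nats);
* the clean-recovery benchmark: the same data with zero corruption,
  checking that the model family can solve the separable problem.

Model and optimizer sizes are desk-scale (depth 3, 12 base filters,
patch 32, tens of epochs with an exponentially decayed Adam step) so a
full benchmark run fits on a single CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from lufor.active_learning import ALConfig, ALCycleReport, run_al_loop
from lufor.model import FocalLossParams, ModelConfig, TrainConfig
from lufor.pools import DataPools
from lufor.scenes import CorruptionConfig, SceneConfig, generate_dataset

N_SCENES = 24
SCENE_SIZE = 128
ANNOTATED_FRACTION = 1 / 3   # 8 of 24
TEST_FRACTION = 0.25         # 4 test scenes, 12 unannotated

AL_CORRUPTION = dict(mislabel_fraction=0.3, drop_fraction=0.3)


def benchmark_scene_config() -> SceneConfig:
    return SceneConfig(height=SCENE_SIZE, width=SCENE_SIZE)


def benchmark_model_config(seed: int = 0) -> ModelConfig:
    return ModelConfig(depth=3, base_filters=12, seed=seed)


def benchmark_train_config(seed: int = 0, epochs: int = 15,
                           overlap: bool = False) -> TrainConfig:
    """Desk-scale recipe: patch 32, batch 8, Adam 2e-3 decayed to 2e-4.

    overlap=True halves the tiling stride (4x the patches per scene), which
    buys accuracy at ~4x the epoch cost; the AL benchmark keeps the cheap
    non-overlapping tiling since it trains nine models."""
    return TrainConfig(epochs=epochs, batch_size=8, learning_rate=2e-3,
                       final_learning_rate=2e-4, patch_size=32,
                       patch_stride=16 if overlap else None, seed=seed)


def benchmark_al_config(seed: int = 0) -> ALConfig:
    return ALConfig(entropy_threshold=0.6, entropy_scale="nats",
                    aggregation="mean", n_cycles=2, seed=seed)


def make_benchmark_pools(seed: int, corrupted: bool = True) -> DataPools:
    corruption = CorruptionConfig(**AL_CORRUPTION) if corrupted else CorruptionConfig()
    return generate_dataset(
        N_SCENES, benchmark_scene_config(), corruption,
        annotated_fraction=ANNOTATED_FRACTION, test_fraction=TEST_FRACTION,
        seed=seed,
    )


def run_al_benchmark(seed: int, epochs: int = 15) -> List[ALCycleReport]:
    """One seed of the corrupted-label active-learning benchmark."""
    pools = make_benchmark_pools(seed, corrupted=True)
    return run_al_loop(
        pools,
        benchmark_model_config(seed),
        benchmark_train_config(seed, epochs=epochs),
        benchmark_al_config(seed),
        FocalLossParams(),
    )


def run_clean_benchmark(seed: int, epochs: int = 30):
    """Clean-data parameter recovery: returns (macro F1, per-class F1)."""
    from lufor.active_learning import evaluate_on_test
    from lufor.metrics import f1_scores
    from lufor.model import build_model, train

    pools = make_benchmark_pools(seed, corrupted=False)
    model = build_model(benchmark_model_config(seed))
    model, _ = train(model, pools,
                     benchmark_train_config(seed, epochs=epochs, overlap=True),
                     FocalLossParams())
    cm = evaluate_on_test(model, pools)
    f1, macro, micro = f1_scores(cm)
    return macro, f1
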