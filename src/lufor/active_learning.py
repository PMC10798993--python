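"""Pool-based active learning with entropy uncertainty sampling.

The loop: train on the annotated pool, score every unannotated scene by
the entropy of its predicted class distribution,

    H(Y) = -sum_i p_i log p_i,

select the scenes whose aggregated (default: mean per-pixel, over
forest-loss pixels when a mask exists) entropy exceeds a threshold, reveal
their clean labels through a simulated annotator, retrain from scratch on
the enlarged pool, and report per-cycle accuracy on a fixed independent
test set.

The threshold scale is configurable: "normalized" divides by ln K so the
score lies in [0, 1] (the library default); "nats" applies the threshold
to raw entropy, which is the literal form of the published selection rule
(entropy > 0.6) that the bundled benchmark uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from lufor.metrics import confusion, f1_scores
from lufor.model import (
    FocalLossParams,
    ModelConfig,
    SegmentationModel,
    TrainConfig,
    argmax_map,
    build_model,
    predict,
    train,
)
from lufor.pools import DataPools, SceneRecord
from lufor.preprocessing import make_image_stack


@dataclass(frozen=True)
class ALConfig:
    entropy_threshold: float = 0.6
    entropy_scale: str = "normalized"  # {"normalized", "nats"}
    aggregation: str = "mean"          # {"mean", "max", "fraction_above"}
    fraction_tau: float = 0.5          # pixel cutoff for fraction_above
    n_cycles: int = 2
    loss_pixels_only: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.entropy_threshold <= 0:
            raise ValueError("entropy_threshold must be > 0")
        if self.entropy_scale not in ("normalized", "nats"):
            raise ValueError("entropy_scale must be 'normalized' or 'nats'")
        if self.entropy_scale == "normalized" and self.entropy_threshold > 1.0:
            # normalized scores cap at 1; a threshold of exactly 1 is legal
            # and selects nothing (selection is strict >)
            raise ValueError("normalized threshold must be <= 1")
        if self.aggregation not in ("mean", "max", "fraction_above"):
            raise ValueError("unknown aggregation")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")


@dataclass
class ALCycleReport:
    cycle: int
    selected_ids: List[str]
    pool_sizes: Tuple[int, int, int]  # (annotated, unannotated, test)
    per_class_f1: np.ndarray
    macro_f1: float
    micro_f1: float
    train_history: List[float] = field(default_factory=list)


def split_pools(n_annotated: int, train_fraction: float = 0.8,
                seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle split of annotated scene indices into train/test.

    |train| = floor(train_fraction * n); the remainder is the independent
    test set (e.g. 895 at 0.8 -> 716 train, 179 test).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if n_annotated < 2:
        raise ValueError("need at least 2 annotated items to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_annotated)
    n_train = int(math.floor(train_fraction * n_annotated))
    return np.sort(order[:n_train]), np.sort(order[n_train:])


def pixel_entropy(probs: np.ndarray) -> np.ndarray:
    """Per-pixel Shannon entropy (nats) of an (H, W, K) probability map.

    0 * log 0 counts as 0; values lie in [0, ln K].
    """
    p = np.asarray(probs, dtype=float)
    if (p < 0).any() or np.abs(p.sum(axis=-1) - 1.0).max() > 1e-5:
        raise ValueError("probs must form a per-pixel simplex")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log(p), 0.0)
    return -term.sum(axis=-1) + 0.0  # + 0.0 normalizes -0.0


def image_uncertainty(
    entropy_map: np.ndarray,
    n_classes: int,
    aggregation: str = "mean",
    entropy_scale: str = "normalized",
    mask: Optional[np.ndarray] = None,
    fraction_tau: float = 0.5,
) -> float:
    """Aggregate a per-pixel entropy map into one scalar score per image.

    With entropy_scale="normalized" entropies are divided by ln K first, so
    mean/max scores lie in [0, 1]. With a mask, only masked (forest-loss)
    pixels are aggregated; an empty mask scores 0.
    """
    h = np.asarray(entropy_map, dtype=float)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != h.shape:
            raise ValueError("mask shape must match entropy map")
        h = h[m]
        if h.size == 0:
            return 0.0
    if entropy_scale == "normalized":
        h = h / math.log(n_classes)
    elif entropy_scale != "nats":
        raise ValueError("entropy_scale must be 'normalized' or 'nats'")
    if aggregation == "mean":
        return float(h.mean())
    if aggregation == "max":
        return float(h.max())
    if aggregation == "fraction_above":
        return float((h > fraction_tau).mean())
    raise ValueError(f"unknown aggregation: {aggregation!r}")


def _scene_score(model: SegmentationModel, rec: SceneRecord, config: ALConfig) -> float:
    stack = make_image_stack(rec.scene.bands)
    prob_map = predict(model, stack)
    ent = pixel_entropy(prob_map.probs)
    mask = rec.scene.loss_mask if config.loss_pixels_only else None
    return image_uncertainty(
        ent, model.n_classes, config.aggregation, config.entropy_scale,
        mask=mask, fraction_tau=config.fraction_tau,
    )


def select_for_annotation(
    pools: DataPools, model: SegmentationModel, al_config: ALConfig,
) -> List[str]:
    """Ids of unannotated scenes with uncertainty strictly above threshold."""
    if not pools.unannotated:
        raise ValueError("unannotated pool is empty")
    scores = {
        sid: _scene_score(model, rec, al_config)
        for sid, rec in sorted(pools.unannotated.items())
    }
    return [sid for sid, s in scores.items() if s > al_config.entropy_threshold]


def simulated_annotator(selected_ids: Sequence[str], pools: DataPools,
                        cycle: int = 1) -> DataPools:
    """Move selected scenes to the annotated pool with clean oracle labels."""
    for sid in selected_ids:
        if sid not in pools.unannotated:
            raise KeyError(f"{sid} is not in the unannotated pool")
    for sid in selected_ids:
        rec = pools.unannotated.pop(sid)
        rec.labels = rec.scene.truth_mask.copy()
        pools.annotated[sid] = rec
        pools.cycle_of_annotation[sid] = cycle
    pools.validate()
    return pools


def evaluate_on_test(model: SegmentationModel, pools: DataPools):
    """Pooled pixel confusion over the clean test scenes."""
    k = model.n_classes
    total = np.zeros((k, k), dtype=np.int64)
    for sid, rec in sorted(pools.test.items()):
        stack = make_image_stack(rec.scene.bands)
        pred = argmax_map(predict(model, stack))
        cm = confusion(pred, rec.labels, k)
        total += cm.counts
    from lufor.metrics import ConfusionMatrix

    return ConfusionMatrix(total)


def run_al_loop(
    pools: DataPools,
    model_config: ModelConfig,
    train_config: TrainConfig,
    al_config: ALConfig,
    loss_params: Optional[FocalLossParams] = None,
) -> List[ALCycleReport]:
    """Full iterative loop; returns n_cycles + 1 reports (initial + rounds).

    Each cycle retrains a fresh model from scratch on the enlarged
    annotated pool (seeds derived from al_config.seed per cycle), scores
    the unannotated pool, and evaluates on the fixed test set.
    """
    pools.validate()
    if not pools.test:
        raise ValueError("test pool is empty")
    reports: List[ALCycleReport] = []
    seed_seq = np.random.SeedSequence(al_config.seed)
    cycle_seeds = [int(s.generate_state(1)[0] % 2**31) for s in
                   seed_seq.spawn(al_config.n_cycles + 1)]

    selected: List[str] = []
    for cycle in range(al_config.n_cycles + 1):
        mc = replace(model_config, seed=cycle_seeds[cycle])
        tc = replace(train_config, seed=cycle_seeds[cycle])
        model = build_model(mc)
        model, history = train(model, pools, tc, loss_params)
        cm = evaluate_on_test(model, pools)
        f1, macro, micro = f1_scores(cm)
        reports.append(ALCycleReport(
            cycle=cycle,
            selected_ids=list(selected),
            pool_sizes=pools.sizes(),
            per_class_f1=f1,
            macro_f1=macro,
            micro_f1=micro,
            train_history=history,
        ))
        if cycle < al_config.n_cycles and pools.unannotated:
            selected = select_for_annotation(pools, model, al_config)
            simulated_annotator(selected, pools, cycle=cycle + 1)
        else:
            selected = []
    return reports


def reports_to_frame(reports: List[ALCycleReport]):
    """Cycle reports as a tidy DataFrame (one row per cycle)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "cycle": r.cycle,
            "n_selected": len(r.selected_ids),
            "n_annotated": r.pool_sizes[0],
            "n_unannotated": r.pool_sizes[1],
            "n_test": r.pool_sizes[2],
            "macro_f1": r.macro_f1,
            "micro_f1": r.micro_f1,
        }
        for r in reports
    ])
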