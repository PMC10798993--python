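"""Attention U-Net segmentation with focal loss.

The per-pixel focal loss for a pixel whose true class is t with predicted
probability p_t is

    FL(p_t) = -w_t * alpha_t * (1 - p_t)^gamma * log(p_t)

averaged over non-ignored pixels; gamma focuses the loss on hard pixels and
the per-class factors alpha_t and w_t (class weights) counteract class
imbalance. Unlabeled pixels (code -1) contribute exactly zero and their
gradients are masked out, so corrupted annotations never teach the model a
fake class.

Defaults follow the reference training recipe (Adam, lr 1e-4, batch 64,
dropout 0.1, BatchNorm, same padding, 200 epochs); desk-scale experiments
use far smaller models and epoch counts, set explicitly where they run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from lufor import nn
from lufor.preprocessing import ImageStack, make_image_stack, extract_patches

IGNORE_LABEL = -1
NODATA_CLASS = 255


@dataclass(frozen=True)
class ModelConfig:
    n_channels: int = 7
    n_classes: int = 15
    depth: int = 3
    base_filters: int = 16
    dropout_rate: float = 0.1
    batch_norm: bool = True
    padding: str = "same"
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.padding != "same":
            raise ValueError("only 'same' padding is supported")


@dataclass
class FocalLossParams:
    alpha: Union[float, np.ndarray] = 1.0
    gamma: float = 2.0
    class_weights: Optional[np.ndarray] = None  # None -> inverse frequency at train time
    ignore_label: int = IGNORE_LABEL

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    def alpha_vector(self, k: int) -> np.ndarray:
        a = np.asarray(self.alpha, dtype=float)
        if a.ndim == 0:
            a = np.full(k, float(a))
        if a.shape != (k,) or (a <= 0).any():
            raise ValueError("alpha must be a positive scalar or length-K vector")
        return a

    def weight_vector(self, k: int) -> np.ndarray:
        if self.class_weights is None:
            return np.ones(k)
        w = np.asarray(self.class_weights, dtype=float)
        if w.shape != (k,):
            raise ValueError("class_weights must have length K")
        return w


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0
    patch_size: int = 64
    patch_stride: Optional[int] = None  # default: patch_size (non-overlapping)
    final_learning_rate: Optional[float] = None  # exponential decay target

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.final_learning_rate is not None and self.final_learning_rate <= 0:
            raise ValueError("final_learning_rate must be positive")
        if self.optimizer.lower() != "adam":
            raise ValueError("only Adam is supported")


@dataclass
class ProbabilityMap:
    probs: np.ndarray  # (H, W, K), rows of the last axis on the simplex

    def __post_init__(self):
        p = self.probs
        if p.ndim != 3:
            raise ValueError("probs must be (H, W, K)")
        if (p < 0).any() or np.abs(p.sum(axis=-1) - 1.0).max() > 1e-5:
            raise ValueError("per-pixel probabilities must form a simplex")


class SegmentationModel:
    """Model handle: the network plus its config and training history."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.net = nn.AttentionUNet(
            n_channels=config.n_channels,
            n_classes=config.n_classes,
            depth=config.depth,
            base_filters=config.base_filters,
            dropout=config.dropout_rate,
            batch_norm=config.batch_norm,
            seed=config.seed,
        )
        self.history: List[float] = []

    @property
    def n_classes(self) -> int:
        return self.config.n_classes


def build_model(config: ModelConfig) -> SegmentationModel:
    return SegmentationModel(config)


def _validate_targets(targets: np.ndarray, k: int, ignore: int) -> None:
    bad = (targets != ignore) & ((targets < 0) | (targets >= k))
    if bad.any():
        raise ValueError("target codes outside 0..K-1 (other than the ignore code)")


def focal_loss(probs: np.ndarray, targets: np.ndarray, params: FocalLossParams) -> float:
    """Mean focal loss over non-ignored pixels.

    probs has class probabilities on its last axis; targets matches the
    leading shape. Returns 0.0 when no pixel is scored.
    """
    probs = np.asarray(probs, dtype=float)
    targets = np.asarray(targets)
    k = probs.shape[-1]
    if targets.shape != probs.shape[:-1]:
        raise ValueError("targets shape must match probs leading dims")
    _validate_targets(targets, k, params.ignore_label)
    valid = targets != params.ignore_label
    if not valid.any():
        return 0.0
    t = targets[valid]
    pt = np.take_along_axis(probs[valid], t[:, None], axis=1)[:, 0]
    pt = np.clip(pt, 1e-12, 1.0)
    a = params.alpha_vector(k)[t]
    w = params.weight_vector(k)[t]
    per_pixel = -w * a * (1.0 - pt) ** params.gamma * np.log(pt)
    return float(per_pixel.mean())


def _focal_loss_and_grad(
    logits: np.ndarray, targets: np.ndarray, params: FocalLossParams,
    alpha: np.ndarray, weights: np.ndarray,
) -> Tuple[float, np.ndarray]:
    """Loss and gradient wrt logits for a (N, K, H, W) batch.

    With p = softmax(z) and per-pixel factor W = w_t * alpha_t:
        dL/dp_t = W * (gamma*(1-p_t)^(gamma-1)*log(p_t) - (1-p_t)^gamma / p_t)
        dL/dz_j = dL/dp_t * p_t * (delta_tj - p_j)
    averaged over valid pixels.
    """
    n, k, h, w = logits.shape
    p = nn.softmax(logits, axis=1)
    valid = targets != params.ignore_label
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("batch contains only ignored labels")
    t_safe = np.where(valid, targets, 0)
    pt = np.take_along_axis(p, t_safe[:, None], axis=1)[:, 0]  # (N, H, W)
    pt = np.clip(pt, 1e-7, 1.0)
    fac = (weights[t_safe] * alpha[t_safe]).astype(np.float32)
    g = params.gamma
    one_m = 1.0 - pt
    logpt = np.log(pt)
    loss_pix = -fac * one_m ** g * logpt
    loss = float(loss_pix[valid].sum() / n_valid)
    if g == 0:
        dldpt = -fac / pt
    else:
        dldpt = fac * (g * one_m ** (g - 1) * logpt - one_m ** g / pt)
    coef = (dldpt * pt * valid).astype(np.float32) / n_valid  # (N, H, W)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, t_safe[:, None], 1.0, axis=1)
    dz = coef[:, None] * (onehot - p)
    return loss, dz.astype(np.float32)


def inverse_frequency_weights(labels: Sequence[np.ndarray], k: int,
                              ignore_label: int = IGNORE_LABEL) -> np.ndarray:
    """Per-class weights proportional to 1/pixel-frequency, mean 1 over
    classes present; absent classes get weight 1."""
    counts = np.zeros(k)
    for lab in labels:
        lab = np.asarray(lab)
        sel = lab[lab != ignore_label]
        counts += np.bincount(sel.ravel(), minlength=k)[:k]
    w = np.ones(k)
    present = counts > 0
    if present.any():
        inv = 1.0 / counts[present]
        w[present] = inv / inv.mean()
    return w


def _pools_to_patches(pools, train_config: TrainConfig):
    """Annotated pool -> list of (7,H,W) float patches + label patches."""
    records = list(pools.annotated.values())
    if not records:
        raise ValueError("annotated pool is empty")
    stride = train_config.patch_stride or train_config.patch_size
    xs, ys = [], []
    for rec in sorted(records, key=lambda r: r.scene_id):
        stack = make_image_stack(rec.scene.bands).channels
        for _, _, patch, lab in extract_patches(stack, rec.labels,
                                                train_config.patch_size, stride):
            xs.append(patch.transpose(2, 0, 1).astype(np.float32))
            ys.append(lab.astype(np.int64))
    return np.stack(xs), np.stack(ys)


def train(
    model: SegmentationModel,
    pools,
    train_config: TrainConfig,
    loss_params: Optional[FocalLossParams] = None,
) -> Tuple[SegmentationModel, List[float]]:
    """Train on the annotated pool; returns (model, per-epoch loss history)."""
    loss_params = loss_params or FocalLossParams()
    x, y = _pools_to_patches(pools, train_config)
    if (y == loss_params.ignore_label).all():
        raise ValueError("all training labels are ignored")
    k = model.n_classes
    _validate_targets(y, k, loss_params.ignore_label)
    alpha = loss_params.alpha_vector(k)
    if loss_params.class_weights is None:
        weights = inverse_frequency_weights([y], k, loss_params.ignore_label)
    else:
        weights = loss_params.weight_vector(k)

    rng = np.random.default_rng(train_config.seed)
    opt = nn.Adam(model.net.params(), lr=train_config.learning_rate)
    n = x.shape[0]
    bs = min(train_config.batch_size, n)
    lr0 = train_config.learning_rate
    lr1 = train_config.final_learning_rate
    history = []
    for epoch in range(train_config.epochs):
        if lr1 is not None and train_config.epochs > 1:
            opt.lr = lr0 * (lr1 / lr0) ** (epoch / (train_config.epochs - 1))
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, bs):
            idx = order[i:i + bs]
            logits = model.net.forward(x[idx], train=True)
            loss, dz = _focal_loss_and_grad(logits, y[idx], loss_params, alpha, weights)
            opt.zero_grad()
            model.net.backward(dz)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    model.history.extend(history)
    return model, history


def predict(model: SegmentationModel, stack: Union[ImageStack, np.ndarray]) -> ProbabilityMap:
    """Per-pixel class probabilities for a 7-channel stack of any size.

    Inputs whose sides are not divisible by 2**depth are reflect-padded for
    the forward pass and cropped back.
    """
    channels = stack.channels if isinstance(stack, ImageStack) else np.asarray(stack)
    if channels.ndim != 3 or channels.shape[2] != model.config.n_channels:
        raise ValueError(f"expected (H, W, {model.config.n_channels}) stack")
    h, w = channels.shape[:2]
    m = 2 ** model.config.depth
    ph, pw = (-h) % m, (-w) % m
    x = channels.transpose(2, 0, 1)[None].astype(np.float32)
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    logits = model.net.forward(x, train=False)
    probs = nn.softmax(logits, axis=1)[0, :, :h, :w].transpose(1, 2, 0)
    probs = probs.astype(np.float64)
    probs /= probs.sum(axis=-1, keepdims=True)
    return ProbabilityMap(probs)


def argmax_map(
    prob_map: Union[ProbabilityMap, np.ndarray],
    loss_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-pixel argmax class (ties -> lowest class id, numpy convention).

    With a loss_mask, pixels outside it get the reserved no-data code 255 —
    inference is meaningful only where forest loss occurred.
    """
    probs = prob_map.probs if isinstance(prob_map, ProbabilityMap) else np.asarray(prob_map)
    out = probs.argmax(axis=-1).astype(np.int16)
    if loss_mask is not None:
        out = np.where(np.asarray(loss_mask, dtype=bool), out, NODATA_CLASS).astype(np.int16)
    return out


def save_model(model: SegmentationModel, path: Union[str, Path]) -> None:
    path = Path(path)
    arrs = model.net.state_arrays()
    np.savez(path.with_suffix(".npz"), *arrs)
    sidecar = {"model_config": asdict(model.config), "history": model.history}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: Union[str, Path]) -> SegmentationModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = SegmentationModel(ModelConfig(**sidecar["model_config"]))
    model.history = list(sidecar["history"])
    with np.load(path.with_suffix(".npz")) as data:
        arrs = [data[k] for k in data.files]
    model.net.load_state_arrays(arrs)
    return model
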