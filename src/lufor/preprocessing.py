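"""Band normalization, vegetation indices, loss-patch filtering, tiling.

The model consumes a fixed 7-channel stack: the four reflectance bands
(blue, green, red, nir) in [0, 1] plus three indices computed from them:

    ndvi = (nir - red) / (nir + red)
    savi = (nir - red) / (nir + red + 0.5) * 1.5
    ndmi = (green - nir) / (green + nir)

ndmi is deliberately computed from green and nir, as in the mapping
methodology this package reproduces (4-band imagery has no SWIR band, which
the conventional moisture index would use). Zero-denominator pixels map to
0 so stacks stay finite for training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage

CHANNEL_NAMES: Tuple[str, ...] = ("blue", "green", "red", "nir", "ndvi", "savi", "ndmi")


@dataclass
class ImageStack:
    channels: np.ndarray  # (H, W, 7)

    def __post_init__(self):
        if self.channels.ndim != 3 or self.channels.shape[2] != len(CHANNEL_NAMES):
            raise ValueError(f"expected (H, W, {len(CHANNEL_NAMES)}) channel stack")
        if not np.isfinite(self.channels).all():
            raise ValueError("channels must be finite")

    @property
    def channel_names(self) -> Tuple[str, ...]:
        return CHANNEL_NAMES

    @property
    def shape(self) -> Tuple[int, int]:
        return self.channels.shape[:2]


def normalize_bands(bands: np.ndarray, mode: str = "fixed") -> np.ndarray:
    """Scale 4 raw bands into [0, 1].

    mode="fixed" assumes inputs already on the canonical [0, 1] scale and
    clips; mode="minmax" rescales each band by its per-scene min/max, with
    constant bands mapping to 0.
    """
    bands = np.asarray(bands, dtype=float)
    if bands.ndim != 3 or bands.shape[2] != 4:
        raise ValueError("expected (H, W, 4) band stack")
    if not np.isfinite(bands).all():
        raise ValueError("bands must be finite")
    if (bands < 0).any():
        raise ValueError("bands must be nonnegative")
    if mode == "fixed":
        return np.clip(bands, 0.0, 1.0)
    if mode == "minmax":
        lo = bands.min(axis=(0, 1), keepdims=True)
        hi = bands.max(axis=(0, 1), keepdims=True)
        span = hi - lo
        out = np.where(span > 0, (bands - lo) / np.where(span > 0, span, 1.0), 0.0)
        return out
    raise ValueError(f"unknown normalization mode: {mode!r}")


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den != 0)
    return out


def compute_indices(bands: np.ndarray) -> np.ndarray:
    """(H, W, 4) normalized bands -> (H, W, 3) stack of ndvi, savi, ndmi."""
    bands = np.asarray(bands, dtype=float)
    if bands.ndim != 3 or bands.shape[2] != 4:
        raise ValueError("expected (H, W, 4) band stack")
    _, green, red, nir = (bands[..., i] for i in range(4))
    ndvi = _safe_ratio(nir - red, nir + red)
    savi = _safe_ratio(nir - red, nir + red + 0.5) * 1.5
    ndmi = _safe_ratio(green - nir, green + nir)
    return np.stack([ndvi, savi, ndmi], axis=-1)


def make_image_stack(bands: np.ndarray, mode: str = "fixed") -> ImageStack:
    """Normalize bands and append the three indices into the 7-channel stack."""
    norm = normalize_bands(bands, mode=mode)
    return ImageStack(np.concatenate([norm, compute_indices(norm)], axis=-1))


def filter_min_patch(
    loss_mask: np.ndarray,
    pixel_size: float,
    min_area_ha: float = 3.8,
    connectivity: int = 8,
) -> np.ndarray:
    """Drop loss components smaller than min_area_ha (default 3.8 ha).

    At 5 m pixels, 3.8 ha is 1520 pixels. Connectivity is 8 by default
    (the less aggressive filter), 4 available.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    loss_mask = np.asarray(loss_mask, dtype=bool)
    min_pixels = min_area_ha * 10_000.0 / (pixel_size ** 2)
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    comp, n = ndimage.label(loss_mask, structure)
    if n == 0:
        return loss_mask.copy()
    sizes = ndimage.sum_labels(loss_mask, comp, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_pixels) + 1
    return np.isin(comp, keep)


def extract_patches(
    stack: np.ndarray,
    labels: np.ndarray | None,
    patch_size: int,
    stride: int,
) -> List[Tuple[int, int, np.ndarray, np.ndarray | None]]:
    """Tile an (H, W, C) stack into (row0, col0, patch, label_patch) tuples.

    Tiles cover the full image; when dimensions are not multiples of the
    stride the last tile in each direction is shifted inward (overlapping)
    so no edge padding is needed and reassembly crops nothing.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    h, w = stack.shape[:2]
    if patch_size > h or patch_size > w:
        raise ValueError("patch_size exceeds image dimensions")

    def _starts(extent: int) -> List[int]:
        s = list(range(0, extent - patch_size + 1, stride))
        if s[-1] + patch_size < extent:
            s.append(extent - patch_size)
        return s

    out = []
    for r0 in _starts(h):
        for c0 in _starts(w):
            patch = stack[r0:r0 + patch_size, c0:c0 + patch_size]
            lab = None
            if labels is not None:
                lab = labels[r0:r0 + patch_size, c0:c0 + patch_size]
            out.append((r0, c0, patch, lab))
    return out


def reassemble_patches(
    patches: List[Tuple[int, int, np.ndarray]],
    shape: Tuple[int, int],
) -> np.ndarray:
    """Rebuild a full-size map from (row0, col0, patch) pieces.

    Later patches overwrite overlaps; with the tiling of extract_patches
    the result covers every pixel of `shape`.
    """
    first = patches[0][2]
    if first.ndim == 2:
        out = np.zeros(shape, dtype=first.dtype)
    else:
        out = np.zeros(shape + first.shape[2:], dtype=first.dtype)
    for r0, c0, patch in patches:
        out[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] = patch
    return out
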