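"""Synthetic multi-band scene generation.

Emulates ~5 m resolution 4-band (blue, green, red, nir) annual mosaics over
deforestation frontiers: each of 15 land-use classes has a spectral
signature (band means + noise) and a geometry kind (fields, tree-crop
lattices, roads, meandering rivers, blobs, settlement/mining clusters).
Scenes carry a clean ground-truth class mask, a forest-loss mask with a
per-pixel loss year in 2001-2020, and a north-up geotransform, so the full
downstream pipeline (indices, segmentation, active learning, stratified
assessment, hotspot analytics) is testable without any satellite download.

A corruption model degrades the clean truth into realistic reference
annotations: boundary dilation/erosion, whole-object class mixing, random
mislabeling, and dropped (unlabeled) pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from lufor.geo import Affine

UNLABELED = -1

GeometryKind = str  # {"field","lattice_plantation","polyline","meander","blob","cluster","texture"}

#: The 15 land-use-following-deforestation classes, with invented but
#: plausible reflectance signatures (blue, green, red, nir) in [0, 1].
#: Signatures are pairwise well separated relative to the default noise so
#: that a nearest-centroid classifier recovers the truth as noise -> 0.
#: Minimum pairwise L2 separation of the signatures is ~0.19, i.e. several
#: noise standard deviations at the default band_sd, by construction.
_DEFAULT_PALETTE: List[Tuple[str, Tuple[float, float, float, float], GeometryKind]] = [
    ("small-scale cropland", (0.14, 0.32, 0.34, 0.52), "field"),
    ("large-scale cropland", (0.14, 0.44, 0.36, 0.76), "field"),
    ("pasture", (0.08, 0.52, 0.20, 0.42), "blob"),
    ("mining", (0.40, 0.46, 0.58, 0.44), "cluster"),
    ("roads", (0.32, 0.34, 0.36, 0.20), "polyline"),
    ("other-land with tree cover", (0.06, 0.24, 0.10, 0.46), "texture"),
    ("plantation forest", (0.03, 0.18, 0.05, 0.68), "field"),
    ("coffee", (0.12, 0.32, 0.18, 0.28), "blob"),
    ("settlement", (0.62, 0.58, 0.52, 0.36), "cluster"),
    ("tea plantation", (0.06, 0.52, 0.14, 0.82), "field"),
    ("water", (0.16, 0.20, 0.10, 0.04), "meander"),
    ("oil palm", (0.04, 0.34, 0.10, 0.88), "lattice_plantation"),
    ("rubber", (0.06, 0.22, 0.24, 0.64), "lattice_plantation"),
    ("cashew", (0.20, 0.42, 0.30, 0.38), "lattice_plantation"),
    ("cacao", (0.02, 0.14, 0.08, 0.26), "blob"),
]


@dataclass(frozen=True)
class ClassSpec:
    class_id: int
    name: str
    band_means: Tuple[float, float, float, float]
    band_sd: float = 0.02
    geometry_kind: GeometryKind = "blob"

    def __post_init__(self):
        if len(self.band_means) != 4:
            raise ValueError("band_means must have 4 entries")
        if not all(0.0 <= m <= 1.0 for m in self.band_means):
            raise ValueError("band_means must lie in [0, 1]")


def default_classes(band_sd: float = 0.02) -> List[ClassSpec]:
    """The default 15-class legend."""
    return [
        ClassSpec(i, name, means, band_sd, kind)
        for i, (name, means, kind) in enumerate(_DEFAULT_PALETTE)
    ]


@dataclass(frozen=True)
class SceneConfig:
    height: int = 128
    width: int = 128
    pixel_size: float = 5.0
    classes: List[ClassSpec] = field(default_factory=default_classes)
    n_objects_per_class: Tuple[int, int] = (1, 3)
    noise_sd: float = 0.0
    loss_fraction: float = 0.5
    background_class_id: int = 5  # other-land with tree cover
    region_id: int = 0
    country_id: int = 0
    origin_lon: float = 20.0
    origin_lat: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise ValueError("scene dimensions must be >= 32")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        ids = [c.class_id for c in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError("class_ids must be unique")


@dataclass
class Scene:
    bands: np.ndarray          # (H, W, 4) float in [0, 1]
    truth_mask: np.ndarray     # (H, W) int in 0..K-1
    loss_mask: np.ndarray      # (H, W) bool
    loss_year: np.ndarray      # (H, W) int, 0 off-loss, 2001..2020 on loss
    geotransform: Affine
    pixel_size: float = 5.0
    region_id: int = 0
    country_id: int = 0

    @property
    def shape(self) -> Tuple[int, int]:
        return self.truth_mask.shape

    def validate(self) -> None:
        if not np.isfinite(self.bands).all():
            raise ValueError("bands must be finite")
        if self.bands.min() < 0 or self.bands.max() > 1:
            raise ValueError("bands must lie in [0, 1]")
        if ((self.loss_year > 0) != self.loss_mask).any():
            raise ValueError("loss_year must be positive exactly on loss pixels")


@dataclass(frozen=True)
class CorruptionConfig:
    boundary_shift_px: int = 0
    mislabel_fraction: float = 0.0
    drop_fraction: float = 0.0
    polygon_mix_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("mislabel_fraction", "drop_fraction", "polygon_mix_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.boundary_shift_px < 0:
            raise ValueError("boundary_shift_px must be >= 0")


# ---------------------------------------------------------------------------
# geometry painters — each stamps class_id pixels onto `mask` in place
# ---------------------------------------------------------------------------

def _paint_rect(mask, cid, rng, small=False):
    h, w = mask.shape
    lo, hi = (h // 10, h // 4) if small else (h // 6, h // 2)
    rh, rw = rng.integers(lo, hi + 1, size=2)
    r0 = int(rng.integers(0, max(1, h - rh)))
    c0 = int(rng.integers(0, max(1, w - rw)))
    mask[r0:r0 + rh, c0:c0 + rw] = cid


def _paint_blob(mask, cid, rng):
    h, w = mask.shape
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    ry = rng.uniform(h / 12, h / 4)
    rx = rng.uniform(w / 12, w / 4)
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    y, x = yy - cy, xx - cx
    u = x * np.cos(theta) + y * np.sin(theta)
    v = -x * np.sin(theta) + y * np.cos(theta)
    mask[(u / rx) ** 2 + (v / ry) ** 2 <= 1.0] = cid


def _paint_cluster(mask, cid, rng):
    """Village/mine compound: several adjoining rectangles near a center.

    At 5 m pixels a compound spans tens of metres, i.e. >= 4 px blocks."""
    h, w = mask.shape
    cy, cx = rng.integers(0, h), rng.integers(0, w)
    for _ in range(int(rng.integers(4, 10))):
        sh, sw = rng.integers(4, max(5, h // 12) + 1, size=2)
        r0 = int(np.clip(cy + rng.integers(-h // 8, h // 8 + 1), 0, h - sh))
        c0 = int(np.clip(cx + rng.integers(-w // 8, w // 8 + 1), 0, w - sw))
        mask[r0:r0 + sh, c0:c0 + sw] = cid


def _paint_polyline(mask, cid, rng):
    """Random-walk road crossing the scene, 2-3 px (10-15 m) wide."""
    h, w = mask.shape
    r = float(rng.integers(0, h))
    width = int(rng.integers(2, 4))
    for c in range(w):
        r += rng.normal(0, 1.0)
        r = float(np.clip(r, 0, h - 1))
        ri = int(r)
        mask[ri:min(ri + width, h), c] = cid


def _paint_meander(mask, cid, rng):
    """Sinusoidal river crossing the scene, ~3 px wide."""
    h, w = mask.shape
    amp = rng.uniform(h / 10, h / 4)
    period = rng.uniform(w / 2, w * 1.5)
    phase = rng.uniform(0, 2 * np.pi)
    mid = rng.uniform(h / 4, 3 * h / 4)
    width = int(rng.integers(2, 5))
    cols = np.arange(w)
    rows = mid + amp * np.sin(2 * np.pi * cols / period + phase)
    for c, r in zip(cols, rows):
        ri = int(np.clip(r, 0, h - 1))
        mask[max(0, ri - width // 2):min(ri + (width + 1) // 2, h), c] = cid


_PAINTERS = {
    "field": lambda m, c, r: _paint_rect(m, c, r, small=False),
    "lattice_plantation": lambda m, c, r: _paint_rect(m, c, r, small=False),
    "polyline": _paint_polyline,
    "meander": _paint_meander,
    "blob": _paint_blob,
    "cluster": _paint_cluster,
    "texture": _paint_blob,
}


def _smooth_field(shape, rng, scale=8):
    """Spatially coherent standard-normal-ish random surface."""
    h, w = shape
    coarse = rng.normal(size=(max(2, h // scale), max(2, w // scale)))
    zoom = (h / coarse.shape[0], w / coarse.shape[1])
    fieldv = ndimage.zoom(coarse, zoom, order=1)[:h, :w]
    return fieldv


def generate_scene(config: SceneConfig) -> Scene:
    """Generate one scene deterministically from its config (incl. seed).

    The truth mask is painted object-by-object over a uniform background;
    painting order puts thin linear features (rivers, roads) last so they
    survive. Every configured class is guaranteed at least one pixel when
    its object count is positive. Reflectances are class means plus i.i.d.
    Gaussian noise (class band_sd and scene noise_sd combined in
    quadrature), clipped to [0, 1]; tree-crop lattices get a small periodic
    brightness modulation emulating planting rows.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    classes = {c.class_id: c for c in cfg.classes}
    bg = cfg.background_class_id if cfg.background_class_id in classes else cfg.classes[0].class_id
    truth = np.full((h, w), bg, dtype=np.int16)

    order = {"field": 0, "blob": 1, "texture": 1, "lattice_plantation": 2,
             "cluster": 3, "meander": 4, "polyline": 5}
    painted = sorted((c for c in cfg.classes if c.class_id != bg),
                     key=lambda c: (order.get(c.geometry_kind, 1), c.class_id))
    lo, hi = cfg.n_objects_per_class
    for spec in painted:
        n = int(rng.integers(lo, hi + 1))
        for _ in range(n):
            _PAINTERS[spec.geometry_kind](truth, spec.class_id, rng)

    # guarantee presence of every class (small stamp; a few retries in case
    # a later stamp overwrote an earlier one)
    if lo > 0:
        for _ in range(10):
            present = set(np.unique(truth))
            missing = [c for c in cfg.classes if c.class_id not in present]
            if not missing:
                break
            for spec in missing:
                sh = max(3, h // 24)
                r0 = int(rng.integers(0, h - sh))
                c0 = int(rng.integers(0, w - sh))
                truth[r0:r0 + sh, c0:c0 + sh] = spec.class_id

    # spectral synthesis
    kmax = max(classes) + 1
    means = np.zeros((kmax, 4))
    sds = np.zeros(kmax)
    for cid, spec in classes.items():
        means[cid] = spec.band_means
        sds[cid] = spec.band_sd
    bands = means[truth]  # (H, W, 4)
    lattice_ids = [c.class_id for c in cfg.classes if c.geometry_kind == "lattice_plantation"]
    if lattice_ids:
        yy, xx = np.mgrid[0:h, 0:w]
        ripple = 0.02 * np.sin(2 * np.pi * xx / 4.0) * np.sin(2 * np.pi * yy / 4.0)
        sel = np.isin(truth, lattice_ids)
        bands[..., 1][sel] += ripple[sel]
        bands[..., 3][sel] += ripple[sel]
    sd_total = np.sqrt(sds[truth] ** 2 + cfg.noise_sd ** 2)
    bands = bands + rng.normal(size=bands.shape) * sd_total[..., None]
    bands = np.clip(bands, 0.0, 1.0)

    # forest-loss mask: coherent random field thresholded on non-water pixels
    water_ids = [c.class_id for c in cfg.classes if c.name == "water"]
    non_water = ~np.isin(truth, water_ids)
    loss = np.zeros((h, w), dtype=bool)
    if cfg.loss_fraction > 0 and non_water.any():
        surf = _smooth_field((h, w), rng)
        vals = surf[non_water]
        thresh = np.quantile(vals, 1.0 - cfg.loss_fraction)
        loss = (surf >= thresh) & non_water
    loss_year = np.zeros((h, w), dtype=np.int16)
    loss_year[loss] = rng.integers(2001, 2021, size=int(loss.sum()))

    scene = Scene(
        bands=bands,
        truth_mask=truth,
        loss_mask=loss,
        loss_year=loss_year,
        geotransform=Affine.north_up(cfg.origin_lon, cfg.origin_lat, cfg.pixel_size),
        pixel_size=cfg.pixel_size,
        region_id=cfg.region_id,
        country_id=cfg.country_id,
    )
    scene.validate()
    return scene


def corrupt_annotations(truth_mask: np.ndarray, corruption: CorruptionConfig) -> np.ndarray:
    """Degrade clean truth into imperfect reference labels.

    Applied in order: boundary dilation/erosion per class, whole-object
    class mixing (a fraction of connected components relabeled wholesale,
    emulating mixed-class polygons), random per-pixel mislabeling at an
    exact calibrated rate, and label dropping to the unlabeled code -1.
    Deterministic per seed.
    """
    cc = corruption
    rng = np.random.default_rng(cc.seed)
    labels = np.asarray(truth_mask).copy().astype(np.int16)
    class_ids = np.unique(truth_mask)

    if cc.boundary_shift_px > 0:
        structure = ndimage.generate_binary_structure(2, 2)
        for cid in rng.permutation(class_ids):
            region = labels == cid
            if not region.any() or region.all():
                continue
            grown = ndimage.binary_dilation(region, structure, iterations=cc.boundary_shift_px)
            labels[grown] = cid

    if cc.polygon_mix_fraction > 0 and len(class_ids) > 1:
        structure = ndimage.generate_binary_structure(2, 2)
        for cid in class_ids:
            comp, n = ndimage.label(labels == cid, structure)
            for obj in range(1, n + 1):
                if rng.uniform() < cc.polygon_mix_fraction:
                    others = class_ids[class_ids != cid]
                    labels[comp == obj] = rng.choice(others)

    if cc.mislabel_fraction > 0 and len(class_ids) > 1:
        n_pix = labels.size
        flat_truth = np.asarray(truth_mask).ravel()
        flat = labels.ravel()
        n_target = int(round(cc.mislabel_fraction * n_pix))
        # flip pixels still agreeing with truth until the differing count is hit
        agree = np.flatnonzero(flat == flat_truth)
        already = n_pix - agree.size
        n_flip = max(0, n_target - already)
        if n_flip > 0 and agree.size:
            pick = rng.choice(agree, size=min(n_flip, agree.size), replace=False)
            offsets = rng.integers(1, len(class_ids), size=pick.size)
            idx_of = {cid: i for i, cid in enumerate(class_ids)}
            cur = np.array([idx_of[c] for c in flat[pick]])
            flat[pick] = class_ids[(cur + offsets) % len(class_ids)]
        labels = flat.reshape(labels.shape)

    if cc.drop_fraction > 0:
        n_drop = int(round(cc.drop_fraction * labels.size))
        if n_drop:
            pick = rng.choice(labels.size, size=n_drop, replace=False)
            flat = labels.ravel()
            flat[pick] = UNLABELED
            labels = flat.reshape(labels.shape)

    return labels


# four coarse regions (W/C/E/S Africa analogue) and two countries each
_REGION_EXTENTS = {
    0: (-15.0, 5.0, 4.0, 14.0),    # west:  lon range, lat range
    1: (8.0, 28.0, -5.0, 8.0),     # central
    2: (28.0, 42.0, -8.0, 8.0),    # east
    3: (12.0, 35.0, -28.0, -10.0), # south
}


def generate_dataset(
    n_scenes: int,
    scene_config: SceneConfig,
    corruption: CorruptionConfig,
    annotated_fraction: float,
    seed: int = 0,
    test_fraction: float = 0.2,
):
    """Build the three disjoint data pools from seeded synthetic scenes.

    floor(annotated_fraction * n_scenes) scenes form the annotated pool and
    carry corrupted labels; of the remainder, floor(test_fraction * rest)
    form the independent test pool with clean labels, and the rest are
    unannotated (clean truth hidden, revealed only by the oracle annotator).
    Scene origins are scattered over four region extents; region and
    country ids derive from the origin.
    """
    from lufor.pools import DataPools, SceneRecord

    if n_scenes < 3:
        raise ValueError("need at least 3 scenes to populate three pools")
    if not 0.0 <= annotated_fraction <= 1.0:
        raise ValueError("annotated_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_annot = int(np.floor(annotated_fraction * n_scenes))
    rest = n_scenes - n_annot
    n_test = max(1, int(np.floor(test_fraction * rest))) if rest else 0

    scene_seeds = rng.integers(0, 2**31 - 1, size=n_scenes)
    corrupt_seeds = rng.integers(0, 2**31 - 1, size=n_scenes)
    order = rng.permutation(n_scenes)

    pools = DataPools()
    for rank, idx in enumerate(order):
        region = int(rng.integers(0, 4))
        lon0, lon1, lat0, lat1 = _REGION_EXTENTS[region]
        lon = float(rng.uniform(lon0, lon1))
        lat = float(rng.uniform(lat0, lat1))
        country = region * 2 + int(lon > (lon0 + lon1) / 2)
        cfg = replace(
            scene_config,
            seed=int(scene_seeds[idx]),
            region_id=region,
            country_id=country,
            origin_lon=lon,
            origin_lat=lat,
        )
        scene = generate_scene(cfg)
        sid = f"scene_{idx:04d}"
        rec = SceneRecord(scene_id=sid, scene=scene)
        if rank < n_annot:
            rec.labels = corrupt_annotations(
                scene.truth_mask, replace(corruption, seed=int(corrupt_seeds[idx]))
            )
            pools.annotated[sid] = rec
            pools.cycle_of_annotation[sid] = 0
        elif rank < n_annot + n_test:
            rec.labels = scene.truth_mask.copy()
            pools.test[sid] = rec
        else:
            pools.unannotated[sid] = rec
    pools.validate()
    return pools
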