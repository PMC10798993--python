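"""Raster and manifest IO.

Rasters are plain (multi-band) TIFF written with tifffile; georeferencing
and ids travel in a JSON sidecar (<name>.aux.json) holding the affine
geotransform, pixel size, and region/country ids. Pool manifests are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from lufor.geo import Affine

PathLike = Union[str, Path]


def write_raster(
    path: PathLike,
    array: np.ndarray,
    geotransform: Optional[Affine] = None,
    pixel_size: Optional[float] = None,
    **aux,
) -> None:
    """Write (H, W) or (H, W, C) arrays as TIFF plus a JSON sidecar."""
    path = Path(path)
    data = np.asarray(array)
    if data.ndim == 3:
        data = np.moveaxis(data, -1, 0)  # bands-first layout in the file
        tifffile.imwrite(path, data, photometric="minisblack", planarconfig="separate")
    else:
        tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = dict(aux)
    if geotransform is not None:
        sidecar["geotransform"] = list(geotransform)
    if pixel_size is not None:
        sidecar["pixel_size"] = pixel_size
    if sidecar:
        path.with_suffix(path.suffix + ".aux.json").write_text(
            json.dumps(sidecar, indent=2))


def read_raster(path: PathLike) -> Tuple[np.ndarray, dict]:
    """Read a TIFF written by write_raster; returns (array, sidecar dict).

    Multi-band files come back as (H, W, C)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = np.moveaxis(data, 0, -1)
    aux_path = path.with_suffix(path.suffix + ".aux.json")
    aux = json.loads(aux_path.read_text()) if aux_path.exists() else {}
    if "geotransform" in aux:
        aux["geotransform"] = Affine(*aux["geotransform"])
    return data, aux


def write_pool_manifest(pools, out_dir: PathLike) -> Path:
    """CSV manifest (scene_id, pool, path, region_id, country_id)."""
    out_dir = Path(out_dir)
    rows = []
    for pool_name in ("annotated", "unannotated", "test"):
        for sid, rec in sorted(getattr(pools, pool_name).items()):
            rows.append({
                "scene_id": sid,
                "pool": pool_name,
                "path": f"scenes/{sid}.tif",
                "region_id": rec.scene.region_id,
                "country_id": rec.scene.country_id,
            })
    manifest = out_dir / "pools.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_pools(pools, out_dir: PathLike) -> Path:
    """Write every scene (bands, truth, loss year, labels) and the manifest."""
    out_dir = Path(out_dir)
    scene_dir = out_dir / "scenes"
    scene_dir.mkdir(parents=True, exist_ok=True)
    for pool_name in ("annotated", "unannotated", "test"):
        for sid, rec in sorted(getattr(pools, pool_name).items()):
            s = rec.scene
            write_raster(scene_dir / f"{sid}.tif", s.bands.astype(np.float32),
                         geotransform=s.geotransform, pixel_size=s.pixel_size,
                         region_id=s.region_id, country_id=s.country_id)
            write_raster(scene_dir / f"{sid}_truth.tif", s.truth_mask)
            write_raster(scene_dir / f"{sid}_loss_year.tif", s.loss_year)
            if rec.labels is not None:
                write_raster(scene_dir / f"{sid}_labels.tif", rec.labels)
    return write_pool_manifest(pools, out_dir)
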