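"""Hotspot density grids and lustrum/region/country analytics.

Hotspots: per-class kernel density estimation on a regular 0.1 degree by
0.1 degree geographic grid. Class pixels become points at their centers,
are binned onto the grid, and smoothed with a Gaussian kernel whose
bandwidth defaults to one cell (0.1 degree). Densities are per square
degree and conserve mass: density times cell area integrates to the input
point count (the grid extent is padded by four bandwidths so edge leakage
stays well under 1%). Geographic distortion of degree cells away from the
equator is ignored — a documented desk-scale simplification.

Trends: per (region, lustrum) class areas and within-group proportions;
per-country class percentages. The log10 display transform of the area
trend is left to presentation code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from lufor.assessment import LustrumPartition
from lufor.geo import Affine
from lufor.model import NODATA_CLASS


@dataclass
class DensityGrid:
    values: np.ndarray      # (n_lat, n_lon) density per square degree
    lon_edges: np.ndarray   # (n_lon + 1,) ascending
    lat_edges: np.ndarray   # (n_lat + 1,) ascending
    cell_size: float
    class_id: Optional[int] = None

    @property
    def extent(self) -> Tuple[float, float, float, float]:
        return (float(self.lon_edges[0]), float(self.lon_edges[-1]),
                float(self.lat_edges[0]), float(self.lat_edges[-1]))

    @property
    def total_mass(self) -> float:
        return float(self.values.sum() * self.cell_size ** 2)


def class_points(
    class_map: np.ndarray,
    geotransform: Affine,
    class_id: int,
    sampling_stride: int = 1,
) -> np.ndarray:
    """(n, 2) lon/lat of (strided) pixel centers belonging to class_id."""
    if sampling_stride < 1:
        raise ValueError("sampling_stride must be >= 1")
    class_map = np.asarray(class_map)
    rows, cols = np.nonzero(class_map == class_id)
    if sampling_stride > 1:
        keep = (rows % sampling_stride == 0) & (cols % sampling_stride == 0)
        rows, cols = rows[keep], cols[keep]
    lon, lat = geotransform.pixel_center(rows, cols)
    return np.stack([lon, lat], axis=1)


def kde_hotspots(
    points: np.ndarray,
    cell_size: float = 0.1,
    bandwidth: float = 0.1,
    kernel: str = "gaussian",
    extent: Optional[Tuple[float, float, float, float]] = None,
    class_id: Optional[int] = None,
) -> DensityGrid:
    """Kernel density surface of a point set on a regular lon/lat grid.

    extent is (lon_min, lon_max, lat_min, lat_max); by default the point
    bounding box padded by 4 bandwidths, snapped to whole cells.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] == 0:
        raise ValueError("points must be a nonempty (n, 2) lon/lat array")
    if kernel not in ("gaussian", "box"):
        raise ValueError("kernel must be 'gaussian' or 'box'")
    pad = 4.0 * bandwidth + cell_size
    if extent is None:
        lon_min, lat_min = points.min(axis=0) - pad
        lon_max, lat_max = points.max(axis=0) + pad
    else:
        lon_min, lon_max, lat_min, lat_max = extent
    n_lon = max(1, int(np.ceil((lon_max - lon_min) / cell_size)))
    n_lat = max(1, int(np.ceil((lat_max - lat_min) / cell_size)))
    lon_edges = lon_min + cell_size * np.arange(n_lon + 1)
    lat_edges = lat_min + cell_size * np.arange(n_lat + 1)
    counts, _, _ = np.histogram2d(points[:, 1], points[:, 0],
                                  bins=[lat_edges, lon_edges])
    sigma_cells = bandwidth / cell_size
    if kernel == "gaussian":
        smooth = ndimage.gaussian_filter(counts, sigma=sigma_cells,
                                         mode="constant", truncate=6.0)
    else:
        size = max(1, int(round(2 * sigma_cells)) * 2 + 1)
        smooth = ndimage.uniform_filter(counts, size=size, mode="constant")
    density = smooth / cell_size ** 2
    return DensityGrid(density, lon_edges, lat_edges, cell_size, class_id)


def lustrum_region_trend(
    class_map: np.ndarray,
    loss_year: np.ndarray,
    region_map: np.ndarray,
    pixel_size: float,
    partition: LustrumPartition = LustrumPartition(),
) -> pd.DataFrame:
    """Tidy table of (region_id, class_id, lustrum, area_ha, proportion).

    Area is pixel count times pixel area; proportion normalizes areas over
    classes within each (region, lustrum) group. Only classified loss
    pixels (class != no-data, loss year inside a bin) are counted.
    """
    class_map = np.asarray(class_map)
    loss_year = np.asarray(loss_year)
    region_map = np.asarray(region_map)
    if not (class_map.shape == loss_year.shape == region_map.shape):
        raise ValueError("rasters must be aligned")
    bins = partition.bin_of(loss_year)
    sel = (bins > 0) & (class_map != NODATA_CLASS)
    df = pd.DataFrame({
        "region_id": region_map[sel].ravel(),
        "class_id": class_map[sel].ravel(),
        "lustrum": bins[sel].ravel(),
    })
    pixel_area_ha = pixel_size ** 2 / 10_000.0
    out = (df.groupby(["region_id", "class_id", "lustrum"], as_index=False)
             .size().rename(columns={"size": "n_pixels"}))
    out["area_ha"] = out["n_pixels"] * pixel_area_ha
    out["proportion"] = (out.groupby(["region_id", "lustrum"])["area_ha"]
                           .transform(lambda a: a / a.sum()))
    return out.drop(columns="n_pixels")


def country_proportions(
    class_map: np.ndarray,
    country_map: np.ndarray,
) -> pd.DataFrame:
    """Per-country class percentages over classified pixels (sum to 100)."""
    class_map = np.asarray(class_map)
    country_map = np.asarray(country_map)
    if class_map.shape != country_map.shape:
        raise ValueError("rasters must be aligned")
    sel = class_map != NODATA_CLASS
    if not sel.any():
        raise ValueError("no classified pixels")
    df = pd.DataFrame({
        "country_id": country_map[sel].ravel(),
        "class_id": class_map[sel].ravel(),
    })
    out = df.groupby(["country_id", "class_id"], as_index=False).size()
    out["percent"] = (out.groupby("country_id")["size"]
                        .transform(lambda n: 100.0 * n / n.sum()))
    return out.drop(columns="size")
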