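"""Minimal north-up affine georeferencing.

A six-parameter affine maps pixel (col, row) to geographic (lon, lat):

    lon = c + a * col + b * row
    lat = f + d * col + e * row

For the north-up grids used here b = d = 0 and e < 0 (latitude decreases
down the raster). Degrees-per-pixel is derived from the metric pixel size
with the small-angle equatorial scale of ~111.32 km per degree; geographic
distortion away from the equator is deliberately ignored (the downstream
density grids bin at 0.1 degree).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

METRES_PER_DEGREE = 111_320.0


class Affine(NamedTuple):
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def north_up(cls, origin_lon: float, origin_lat: float, pixel_size_m: float) -> "Affine":
        deg = pixel_size_m / METRES_PER_DEGREE
        return cls(deg, 0.0, origin_lon, 0.0, -deg, origin_lat)

    def pixel_center(self, row, col):
        """(lon, lat) of pixel centers; accepts scalars or arrays."""
        col = np.asarray(col, dtype=float) + 0.5
        row = np.asarray(row, dtype=float) + 0.5
        lon = self.c + self.a * col + self.b * row
        lat = self.f + self.d * col + self.e * row
        return lon, lat
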