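"""Suitability classification, area bookkeeping, and centroid shifts.

Continuous suitability (0-1) is reclassified into four classes:

    unsuitable  [0, 0.2]
    general     (0.2, 0.4)
    moderate    [0.4, 0.6)
    high        [0.6, 1]

0.2 is unsuitable (the class is defined as <= 0.2); the 0.4 and 0.6
boundaries are assigned upward.  "Suitable" for change and centroid
analysis means any of the three suitable classes (> 0.2).

All areas are spherical (mean Earth radius) and reported in 10^4 km^2;
distances are great-circle (haversine).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .grids import EARTH_RADIUS_KM, GridSpec, cell_area_km2

CLASS_CODES = {"unsuitable": 0, "general": 1, "moderate": 2, "high": 3}
CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}
NODATA_CODE = -1

DEFAULT_BOUNDS = (0.2, 0.4, 0.6)

OCTANTS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


@dataclass
class ClassifiedRaster:
    grid: GridSpec
    codes: np.ndarray  # int array, -1 = nodata

    def suitable_mask(self) -> np.ndarray:
        return self.codes >= CLASS_CODES["general"]


def classify(
    grid: GridSpec, suitability: np.ndarray, bounds: Tuple[float, float, float] = DEFAULT_BOUNDS
) -> ClassifiedRaster:
    """Reclassify a continuous suitability raster into the four classes.

    ``bounds`` are the (unsuitable|general, general|moderate,
    moderate|high) cut points; the lowest cut belongs to unsuitable, the
    upper two to the class above.  Nodata (NaN) propagates.
    """
    b1, b2, b3 = bounds
    if not (0.0 < b1 < b2 < b3 < 1.0):
        raise ValueError("class bounds must be ascending within (0, 1)")
    s = np.asarray(suitability, dtype=float)
    codes = np.full(s.shape, NODATA_CODE, dtype=int)
    data = ~np.isnan(s)
    codes[data & (s <= b1)] = CLASS_CODES["unsuitable"]
    codes[data & (s > b1) & (s < b2)] = CLASS_CODES["general"]
    codes[data & (s >= b2) & (s < b3)] = CLASS_CODES["moderate"]
    codes[data & (s >= b3)] = CLASS_CODES["high"]
    return ClassifiedRaster(grid, codes)


def class_areas(classified: ClassifiedRaster) -> Dict[str, float]:
    """Per-class total area in 10^4 km^2 (spherical cell areas)."""
    areas = {}
    row_area = cell_area_km2(classified.grid, np.arange(classified.grid.n_rows))
    area_grid = np.broadcast_to(row_area[:, None], classified.grid.shape)
    for name, code in CLASS_CODES.items():
        areas[name] = float(area_grid[classified.codes == code].sum() / 1e4)
    return areas


@dataclass
class ChangeSummary:
    """Suitable-range change between two periods, areas in 10^4 km^2."""

    gained: float
    lost: float
    net: float
    scenario: str = ""
    period: str = ""


def change_map(
    current: ClassifiedRaster, future: ClassifiedRaster, scenario: str = "", period: str = ""
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, ChangeSummary]:
    """Gained / lost / stable suitable-range masks plus the area summary.

    A cell is suitable when its class is general, moderate, or high.
    gained = suitable in the future but not now; lost = the converse;
    net = gained − lost exactly.
    """
    if not current.grid.approx_equal(future.grid):
        raise ValueError("classified rasters on different grids")
    cur = current.suitable_mask()
    fut = future.suitable_mask()
    gained = fut & ~cur
    lost = cur & ~fut
    stable = cur & fut
    row_area = cell_area_km2(current.grid, np.arange(current.grid.n_rows))
    area_grid = np.broadcast_to(row_area[:, None], current.grid.shape)
    g = float(area_grid[gained].sum() / 1e4)
    l = float(area_grid[lost].sum() / 1e4)
    return gained, lost, stable, ChangeSummary(g, l, g - l, scenario, period)


def centroid(
    classified: ClassifiedRaster, weights: Optional[np.ndarray] = None
) -> Optional[Tuple[float, float]]:
    """Area-weighted mean (lon, lat) of the suitable range.

    By default cells weigh by their spherical area; ``weights`` (e.g. the
    suitability surface) multiplies the area weights.  Returns None when no
    cell is suitable ("no range").
    """
    mask = classified.suitable_mask()
    if not mask.any():
        return None
    rows, cols = np.nonzero(mask)
    lon, lat = classified.grid.cell_center(rows, cols)
    w = cell_area_km2(classified.grid, rows)
    if weights is not None:
        w = w * np.asarray(weights, dtype=float)[rows, cols]
    return float(np.average(lon, weights=w)), float(np.average(lat, weights=w))


def haversine_km(a: Tuple[float, float], b: Tuple[float, float]) -> float:
    """Great-circle distance between (lon, lat) points, km."""
    lon1, lat1, lon2, lat2 = map(np.deg2rad, (*a, *b))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def initial_bearing_deg(a: Tuple[float, float], b: Tuple[float, float]) -> float:
    """Initial great-circle bearing from a to b, degrees clockwise from north."""
    lon1, lat1, lon2, lat2 = map(np.deg2rad, (*a, *b))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return float(np.rad2deg(np.arctan2(y, x)) % 360.0)


def bearing_octant(bearing: float) -> str:
    """Compass octant (N/NE/.../NW) containing the bearing (±22.5°)."""
    return OCTANTS[int(((bearing + 22.5) % 360) // 45)]


@dataclass
class CentroidShift:
    origin: Tuple[float, float]
    destination: Tuple[float, float]
    distance_km: float
    bearing_deg: Optional[float]
    octant: str


def centroid_shift(a: Tuple[float, float], b: Tuple[float, float]) -> CentroidShift:
    """Displacement between two range centroids (haversine + bearing)."""
    d = haversine_km(a, b)
    if d == 0.0:
        return CentroidShift(a, b, 0.0, None, "none")
    brg = initial_bearing_deg(a, b)
    return CentroidShift(a, b, d, brg, bearing_octant(brg))
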