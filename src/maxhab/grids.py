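"""Geographic grid definition and ESRI ASCII grid I/O.

Conventions (fixed across the whole package):

* corner registration — ``x_min``/``y_min`` are the outer edges of the
  south-west cell;
* half-open cells ``[edge, edge + cell_size)`` in both axes;
* array row 0 is the **northernmost** row, matching ESRI ASCII body order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import numpy as np

#: Mean Earth radius (IUGG), km.  Used for all spherical geometry.
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid with corner registration.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (>= 1 each).
    x_min, y_min
        Longitude/latitude of the outer corner of the south-west cell,
        decimal degrees (WGS84).
    cell_size
        Cell edge length in degrees (> 0); cells are square in degrees.
    nodata_value
        Sentinel written to/read from ASCII grids for missing cells.
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_min: float
    cell_size: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not (-180.0 <= self.x_min and self.x_max <= 180.0 + 1e-9):
            raise ValueError("grid longitudes outside [-180, 180]")
        if not (-90.0 <= self.y_min and self.y_max <= 90.0 + 1e-9):
            raise ValueError("grid latitudes outside [-90, 90]")

    # -- extent ------------------------------------------------------------
    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    # -- coordinate <-> index ----------------------------------------------
    def cell_index(self, longitude, latitude):
        """Array (row, col) of the cell containing each point.

        Half-open convention: a point on a shared edge belongs to the cell
        whose low edge it sits on.  Row 0 is the northern row.  Points
        outside the extent raise ``ValueError``.
        """
        lon = np.asarray(longitude, dtype=float)
        lat = np.asarray(latitude, dtype=float)
        col = np.floor((lon - self.x_min) / self.cell_size).astype(int)
        row_south = np.floor((lat - self.y_min) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row_south >= 0) & (row_south < self.n_rows)
        if not np.all(inside):
            bad = np.argwhere(~np.atleast_1d(inside)).ravel().tolist()
            raise ValueError(f"points outside grid extent at positions {bad}")
        row = self.n_rows - 1 - row_south
        return row, col

    def cell_center(self, row, col):
        """Longitude/latitude of cell centers (row 0 = north)."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.x_min + (col + 0.5) * self.cell_size
        lat = self.y_min + (self.n_rows - 1 - row + 0.5) * self.cell_size
        return lon, lat

    def row_latitudes(self):
        """Cell-center latitudes per array row, north to south."""
        rows = np.arange(self.n_rows)
        _, lat = self.cell_center(rows, np.zeros_like(rows))
        return lat

    def approx_equal(self, other: "GridSpec", origin_tol: float = 1e-6, size_tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.x_min - other.x_min) <= origin_tol
            and abs(self.y_min - other.y_min) <= origin_tol
            and abs(self.cell_size - other.cell_size) <= size_tol
        )


def cell_area_km2(grid: GridSpec, row) -> np.ndarray:
    """Spherical area (km^2) of cells in the given array row(s).

    area = R^2 * dlambda * (sin(phi_n) - sin(phi_s)); identical for every
    cell in a row, so only latitude enters.
    """
    row = np.asarray(row)
    lat_s = grid.y_min + (grid.n_rows - 1 - row) * grid.cell_size
    lat_n = lat_s + grid.cell_size
    dlam = np.deg2rad(grid.cell_size)
    return EARTH_RADIUS_KM**2 * dlam * (np.sin(np.deg2rad(lat_n)) - np.sin(np.deg2rad(lat_s)))


def read_ascii_grid(path) -> Tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid.

    Header keys are case-insensitive; both ``XLLCORNER`` and ``XLLCENTER``
    registrations are accepted and normalized to corner registration.
    Returns the grid spec and a masked-by-NaN float array (nodata cells are
    NaN; the sentinel is kept in the spec).
    """
    path = Path(path)
    header: dict[str, float] = {}
    body_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    required = {"ncols", "nrows", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise ValueError(f"{path}: missing header keys {sorted(missing)}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x_min = header["xllcorner"]
    elif "xllcenter" in header:
        x_min = header["xllcenter"] - cell / 2.0
    else:
        raise ValueError(f"{path}: no XLLCORNER/XLLCENTER")
    if "yllcorner" in header:
        y_min = header["yllcorner"]
    elif "yllcenter" in header:
        y_min = header["yllcenter"] - cell / 2.0
    else:
        raise ValueError(f"{path}: no YLLCORNER/YLLCENTER")
    nodata = header.get("nodata_value", -9999.0)

    tokens = " ".join(lines[body_start:]).split()
    try:
        values = np.array(tokens, dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: unparseable value in grid body: {exc}") from None
    if values.size != n_rows * n_cols:
        raise ValueError(
            f"{path}: body has {values.size} values, header declares {n_rows * n_cols}"
        )
    arr = values.reshape(n_rows, n_cols)
    arr = np.where(np.isclose(arr, nodata), np.nan, arr)
    spec = GridSpec(n_rows, n_cols, x_min, y_min, cell, nodata)
    return spec, arr


def write_ascii_grid(spec: GridSpec, array: np.ndarray, path, fmt: str = "%.6g") -> None:
    """Write an ESRI ASCII grid (corner registration, NaN -> nodata)."""
    array = np.asarray(array, dtype=float)
    if array.shape != spec.shape:
        raise ValueError(f"array shape {array.shape} != grid shape {spec.shape}")
    out = np.where(np.isnan(array), spec.nodata_value, array)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"NCOLS {spec.n_cols}\n")
        fh.write(f"NROWS {spec.n_rows}\n")
        fh.write(f"XLLCORNER {spec.x_min:.10g}\n")
        fh.write(f"YLLCORNER {spec.y_min:.10g}\n")
        fh.write(f"CELLSIZE {spec.cell_size:.10g}\n")
        fh.write(f"NODATA_VALUE {spec.nodata_value:.10g}\n")
        for row in out:
            fh.write(" ".join(fmt % v for v in row) + "\n")
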