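"""Aligned environmental raster stacks and presence/background design matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grids import GridSpec, read_ascii_grid, write_ascii_grid


@dataclass
class EnvStack:
    """Named environmental layers sharing one geographic grid.

    Layers are 2-D float arrays with NaN for nodata.  The stack's nodata
    mask is the union of the per-layer masks: a cell is usable only when
    every layer has data there.
    """

    grid: GridSpec
    layers: Dict[str, np.ndarray]
    units: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r}: shape {arr.shape} != grid {self.grid.shape}")

    @property
    def layer_names(self) -> List[str]:
        return list(self.layers)

    def nodata_mask(self) -> np.ndarray:
        """Boolean mask, True where ANY layer is nodata."""
        mask = np.zeros(self.grid.shape, dtype=bool)
        for arr in self.layers.values():
            mask |= np.isnan(arr)
        return mask

    def data_cells(self) -> Tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of cells with data in every layer, row-major order."""
        rows, cols = np.nonzero(~self.nodata_mask())
        return rows, cols

    def values_at(self, rows, cols, names: Optional[Sequence[str]] = None) -> pd.DataFrame:
        names = list(names) if names is not None else self.layer_names
        return pd.DataFrame({n: self.layers[n][rows, cols] for n in names})

    def subset(self, names: Sequence[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack(
            self.grid,
            {n: self.layers[n] for n in names},
            {n: self.units[n] for n in names if n in self.units},
        )

    def write(self, directory) -> None:
        """Write every layer as <directory>/<name>.asc."""
        for name, arr in self.layers.items():
            write_ascii_grid(self.grid, arr, f"{directory}/{name}.asc")


def build_stack(paths: Mapping[str, str], units: Optional[Mapping[str, str]] = None) -> EnvStack:
    """Load named ASCII grids and verify they share one grid.

    A mismatch names the offending layer and the differing field; the first
    layer read defines the reference grid (origin tolerance 1e-6 degrees,
    cell-size tolerance 1e-9).
    """
    if not paths:
        raise ValueError("no layers given")
    layers: Dict[str, np.ndarray] = {}
    ref: Optional[GridSpec] = None
    ref_name = ""
    for name, path in paths.items():
        spec, arr = read_ascii_grid(path)
        if ref is None:
            ref, ref_name = spec, name
        elif not spec.approx_equal(ref):
            for fld in ("n_rows", "n_cols", "x_min", "y_min", "cell_size"):
                if getattr(spec, fld) != getattr(ref, fld):
                    raise ValueError(
                        f"layer {name!r} disagrees with {ref_name!r} on {fld}: "
                        f"{getattr(spec, fld)} vs {getattr(ref, fld)}"
                    )
            raise ValueError(f"layer {name!r} grid mismatch vs {ref_name!r}")
        layers[name] = arr
    return EnvStack(ref, layers, dict(units or {}))


@dataclass
class SampleMatrix:
    """Presence/background design matrix in layer units.

    ``data`` has one column per layer; ``is_presence`` marks presence rows;
    ``cells`` carries each row's (row, col) grid cell so the model landscape
    can be deduplicated by cell.
    """

    data: pd.DataFrame
    is_presence: np.ndarray
    cells: np.ndarray  # (n, 2) int array of (row, col)

    def __post_init__(self) -> None:
        self.is_presence = np.asarray(self.is_presence, dtype=bool)
        self.cells = np.asarray(self.cells, dtype=int)
        if len(self.data) != len(self.is_presence) or len(self.data) != len(self.cells):
            raise ValueError("data, is_presence, cells must have equal length")
        if self.data.isna().any().any():
            raise ValueError("sample matrix contains nodata values")

    @property
    def variables(self) -> List[str]:
        return list(self.data.columns)

    @property
    def n_presence(self) -> int:
        return int(self.is_presence.sum())

    @property
    def n_background(self) -> int:
        return int((~self.is_presence).sum())

    def presence(self) -> pd.DataFrame:
        return self.data[self.is_presence]

    def background(self) -> pd.DataFrame:
        return self.data[~self.is_presence]

    def subset_variables(self, names: Sequence[str]) -> "SampleMatrix":
        return SampleMatrix(self.data[list(names)].copy(), self.is_presence.copy(), self.cells.copy())

    def subset_rows(self, index: np.ndarray) -> "SampleMatrix":
        index = np.asarray(index)
        return SampleMatrix(
            self.data.iloc[index].reset_index(drop=True),
            self.is_presence[index],
            self.cells[index],
        )


def extract(stack: EnvStack, occurrences) -> Tuple[pd.DataFrame, np.ndarray, dict]:
    """Presence rows: layer values at the cell containing each record.

    Returns (values, cells, report); records landing in nodata cells are
    dropped and listed in the report.
    """
    lon = occurrences.records["longitude"].to_numpy(dtype=float)
    lat = occurrences.records["latitude"].to_numpy(dtype=float)
    rows, cols = stack.grid.cell_index(lon, lat)
    rows = np.atleast_1d(rows)
    cols = np.atleast_1d(cols)
    mask = stack.nodata_mask()
    in_nodata = mask[rows, cols]
    report = {
        "n_points": int(len(rows)),
        "n_dropped_nodata": int(in_nodata.sum()),
        "dropped_indices": np.nonzero(in_nodata)[0].tolist(),
    }
    keep = ~in_nodata
    values = stack.values_at(rows[keep], cols[keep]).reset_index(drop=True)
    cells = np.column_stack([rows[keep], cols[keep]])
    return values, cells, report


def sample_background(
    stack: EnvStack,
    n: int,
    seed: int,
    exclude: Optional[Iterable[Tuple[int, int]]] = None,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Draw ``n`` distinct data cells uniformly without replacement.

    ``exclude`` removes specific (row, col) cells from the candidate pool.
    Requesting more cells than are available is an error, never a silent
    truncation.
    """
    rows, cols = stack.data_cells()
    if exclude is not None:
        excl = set(map(tuple, exclude))
        keep = np.array([(r, c) not in excl for r, c in zip(rows, cols)], dtype=bool)
        rows, cols = rows[keep], cols[keep]
    avail = len(rows)
    if n > avail:
        raise ValueError(f"requested {n} background cells but only {avail} data cells available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(avail, size=n, replace=False)
    idx.sort()
    values = stack.values_at(rows[idx], cols[idx]).reset_index(drop=True)
    cells = np.column_stack([rows[idx], cols[idx]])
    return values, cells


def make_sample_matrix(
    stack: EnvStack,
    occurrences,
    n_background: int = 10_000,
    seed: int = 0,
    variables: Optional[Sequence[str]] = None,
) -> Tuple[SampleMatrix, dict]:
    """Assemble presence + background rows on the stack's grid.

    Background size defaults to 10,000 but is capped at the number of data
    cells.  Presence cells are not excluded from the background (standard
    presence-background convention).
    """
    pres_vals, pres_cells, report = extract(stack, occurrences)
    if len(pres_vals) < 1:
        raise ValueError("no usable presence records on the stack grid")
    n_avail = len(stack.data_cells()[0])
    n_bg = min(n_background, n_avail)
    bg_vals, bg_cells = sample_background(stack, n_bg, seed)
    data = pd.concat([pres_vals, bg_vals], ignore_index=True)
    is_presence = np.r_[np.ones(len(pres_vals), bool), np.zeros(len(bg_vals), bool)]
    cells = np.vstack([pres_cells, bg_cells])
    sm = SampleMatrix(data, is_presence, cells)
    if variables is not None:
        sm = sm.subset_variables(variables)
    report = dict(report, n_background=n_bg, background_requested=n_background)
    return sm, report
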