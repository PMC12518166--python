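"""Occurrence record ingestion, cleaning, and spatial thinning.

Thinning enforces at most one presence record per grid cell of the
environmental grid, the standard guard against pseudo-replication in
presence-background modeling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .grids import GridSpec

REQUIRED_COLUMNS = ("species", "longitude", "latitude")
OPTIONAL_COLUMNS = ("elevation", "year")


@dataclass
class OccurrenceSet:
    """Ordered presence records for a single species.

    ``records`` columns: species, longitude, latitude and, when available,
    elevation (m) and year.  Invalid-row diagnostics from parsing live in
    ``issues`` (one dict per rejected row, with the 1-based data row number).
    """

    records: pd.DataFrame
    species: str
    issues: List[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.records.columns:
                raise ValueError(f"records missing column {col!r}")
        if len(self.records) and not (self.records["species"] == self.species).all():
            raise ValueError("all records must share the set's species label")

    def __len__(self) -> int:
        return len(self.records)


def read_occurrences(path, species: str) -> OccurrenceSet:
    """Read one species' records from CSV with row-level validation.

    Required columns: species, longitude, latitude; elevation and year are
    optional.  Rows with unparseable or out-of-range coordinates (or a year
    outside [1800, 2100]) are excluded and reported in ``issues`` with their
    row numbers — never silently dropped.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str).rename(columns=str.lower)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    raw = raw[raw["species"] == species].copy()
    issues: List[dict] = []
    rows = []
    for idx, row in raw.iterrows():
        rownum = int(idx) + 2  # 1-based with header line
        rec = {"species": species}
        problem = None
        for col, lo, hi in (("longitude", -180.0, 180.0), ("latitude", -90.0, 90.0)):
            txt = row.get(col)
            try:
                val = float(txt)
            except (TypeError, ValueError):
                problem = f"unparseable {col}: {txt!r}"
                break
            if not (lo <= val <= hi) or np.isnan(val):
                problem = f"{col} {val} outside [{lo}, {hi}]"
                break
            rec[col] = val
        if problem is None:
            for col in OPTIONAL_COLUMNS:
                txt = row.get(col)
                if txt is None or (isinstance(txt, float) and np.isnan(txt)) or str(txt).strip() == "":
                    rec[col] = np.nan
                    continue
                try:
                    rec[col] = float(txt)
                except ValueError:
                    rec[col] = np.nan
                    issues.append({"row": rownum, "problem": f"unparseable {col}: {txt!r} (set missing)"})
            year = rec.get("year")
            if year is not None and not np.isnan(year) and not (1800 <= year <= 2100):
                problem = f"year {year} outside [1800, 2100]"
        if problem is not None:
            issues.append({"row": rownum, "problem": problem})
            continue
        rows.append(rec)

    cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    records = pd.DataFrame(rows, columns=cols)
    return OccurrenceSet(records, species, issues)


def clean(occ: OccurrenceSet) -> OccurrenceSet:
    """Drop records missing coordinates; collapse exact coordinate duplicates.

    The first record at each (longitude, latitude) pair is kept; order is
    otherwise preserved.  Idempotent.
    """
    df = occ.records
    has_coords = df["longitude"].notna() & df["latitude"].notna()
    df = df[has_coords]
    df = df.drop_duplicates(subset=["longitude", "latitude"], keep="first")
    return OccurrenceSet(df.reset_index(drop=True), occ.species, list(occ.issues))


@dataclass
class ThinningReport:
    species: str
    n_input: int
    n_retained: int
    n_dropped: int
    n_cells_occupied: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def thin(occ: OccurrenceSet, grid: GridSpec, seed: int = 0) -> tuple[OccurrenceSet, ThinningReport]:
    """Keep at most one record per grid cell, chosen uniformly under seed.

    Records outside the grid extent raise an error listing them.  The number
    retained equals the number of distinct occupied cells, so re-thinning is
    a no-op.  Within-cell retention is random-under-seed rather than
    first-record, to avoid ordering artifacts from source databases.
    """
    df = occ.records
    if len(df) == 0:
        return occ, ThinningReport(occ.species, 0, 0, 0, 0, seed)
    rows, cols = grid.cell_index(
        df["longitude"].to_numpy(dtype=float), df["latitude"].to_numpy(dtype=float)
    )
    cell_id = np.atleast_1d(rows) * grid.n_cols + np.atleast_1d(cols)
    rng = np.random.default_rng(seed)
    keep_idx = []
    for cid in np.unique(cell_id):
        members = np.nonzero(cell_id == cid)[0]
        keep_idx.append(int(rng.choice(members)))
    keep_idx.sort()
    thinned = OccurrenceSet(df.iloc[keep_idx].reset_index(drop=True), occ.species, list(occ.issues))
    report = ThinningReport(
        species=occ.species,
        n_input=len(df),
        n_retained=len(keep_idx),
        n_dropped=len(df) - len(keep_idx),
        n_cells_occupied=int(np.unique(cell_id).size),
        seed=seed,
    )
    return thinned, report


def aggregate_reports(reports: List[ThinningReport]) -> dict:
    """Total retained/dropped counts across species (study-level bookkeeping)."""
    return {
        "per_species": {r.species: r.n_retained for r in reports},
        "total_retained": int(sum(r.n_retained for r in reports)),
        "total_input": int(sum(r.n_input for r in reports)),
        "total_dropped": int(sum(r.n_dropped for r in reports)),
    }


def write_occurrences(occ: OccurrenceSet, path) -> None:
    occ.records.to_csv(path, index=False)
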