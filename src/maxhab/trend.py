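"""Elevation-over-time trend analysis of occurrence records.

Per species, ordinary least squares of record elevation on collection
year, split into pre- and post-2000 periods.  The direction calls follow
the usual significance convention: "up"/"down" only when the slope's
two-sided p-value is below 0.05, otherwise "none".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .occurrences import OccurrenceSet


@dataclass
class TrendResult:
    species: str
    period: str                 # "pre2000" | "post2000" (by the split year)
    n: int
    slope: Optional[float]      # m / year
    intercept: Optional[float]  # m
    r_squared: Optional[float]
    p_value: Optional[float]
    direction: str              # "up" | "down" | "none"
    note: str = ""

    def to_row(self) -> dict:
        return {
            "species": self.species,
            "period": self.period,
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "direction": self.direction,
            "note": self.note,
        }


def _fit_period(df: pd.DataFrame, species: str, period: str, alpha: float) -> TrendResult:
    n = len(df)
    if n < 3:
        return TrendResult(species, period, n, None, None, None, None, "none", "insufficient data")
    years = df["year"].to_numpy(dtype=float)
    elev = df["elevation"].to_numpy(dtype=float)
    if np.ptp(years) == 0:
        return TrendResult(
            species, period, n, None, None, None, None, "none", "all years identical"
        )
    res = stats.linregress(years, elev)
    if np.isfinite(res.rvalue):
        r2 = float(res.rvalue**2)
        p = float(res.pvalue)
    else:  # constant elevation: no variance to explain, slope is exactly 0
        r2, p = 0.0, 1.0
    if p < alpha and res.slope > 0:
        direction = "up"
    elif p < alpha and res.slope < 0:
        direction = "down"
    else:
        direction = "none"
    return TrendResult(
        species, period, n, float(res.slope), float(res.intercept), r2, p, direction
    )


def fit_trend(
    occurrences: OccurrenceSet,
    split_year: int = 2000,
    alpha: float = 0.05,
    split_year_to_post: bool = True,
) -> Tuple[TrendResult, TrendResult]:
    """OLS elevation ~ year for the pre- and post-split periods.

    Records missing year or elevation are excluded per-analysis (counts in
    the result notes stay implicit via n).  Records at exactly the split
    year go to the post period by default.
    """
    df = occurrences.records
    usable = df[df["year"].notna() & df["elevation"].notna()]
    if split_year_to_post:
        pre = usable[usable["year"] < split_year]
        post = usable[usable["year"] >= split_year]
    else:
        pre = usable[usable["year"] <= split_year]
        post = usable[usable["year"] > split_year]
    return (
        _fit_period(pre, occurrences.species, f"pre{split_year}", alpha),
        _fit_period(post, occurrences.species, f"post{split_year}", alpha),
    )


def trend_table(results) -> pd.DataFrame:
    """Flatten TrendResults (any iterable, possibly nested pairs) to a table."""
    rows = []
    for item in results:
        if isinstance(item, TrendResult):
            rows.append(item.to_row())
        else:
            rows.extend(r.to_row() for r in item)
    return pd.DataFrame(rows)
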