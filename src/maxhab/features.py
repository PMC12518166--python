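"""Maxent feature expansion and the default regularization schedule.

Feature classes follow the canonical ENMeval letter sets
L / LQ / H / LQH / LQHP / LQHPT with L = linear, Q = quadratic, H = hinge,
P = product, T = threshold.  Every feature maps inputs to [0, 1]: variables
are min/max-scaled on the training data and clamped outside the training
range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("L", "LQ", "H", "LQH", "LQHP", "LQHPT")

#: Default regularization multiplier grid, 0.5 .. 4.0 step 0.5.
DEFAULT_RM_GRID = tuple(np.arange(0.5, 4.01, 0.5))


@dataclass(frozen=True)
class FeatureDef:
    """One expanded feature.

    kind
        linear | quadratic | product | hinge | threshold.
    variables
        One layer name (two for product).
    knot
        Position in *scaled* [0, 1] units (hinge/threshold only).
    direction
        "forward" (ramps up above the knot) or "reverse" (hinge only).
    bounds
        Training (min, max) per variable, used for scaling and clamping.
    """

    kind: str
    variables: Tuple[str, ...]
    bounds: Tuple[Tuple[float, float], ...]
    knot: Optional[float] = None
    direction: str = "forward"

    def label(self) -> str:
        v = "*".join(self.variables)
        if self.kind in ("hinge", "threshold"):
            return f"{self.kind}({v};{self.direction[0]}@{self.knot:.4g})"
        return f"{self.kind}({v})"


def _scale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Min/max scale to [0,1], clamped; constant variables map to 0."""
    if hi <= lo:
        return np.zeros_like(np.asarray(x, dtype=float))
    return np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def evaluate_feature(f: FeatureDef, data: pd.DataFrame) -> np.ndarray:
    z = _scale(data[f.variables[0]].to_numpy(), *f.bounds[0])
    if f.kind == "linear":
        return z
    if f.kind == "quadratic":
        return z**2
    if f.kind == "product":
        z2 = _scale(data[f.variables[1]].to_numpy(), *f.bounds[1])
        return z * z2
    if f.kind == "hinge":
        t = f.knot
        if f.direction == "forward":
            return np.clip((z - t) / (1.0 - t), 0.0, 1.0) if t < 1.0 else np.zeros_like(z)
        return np.clip((t - z) / t, 0.0, 1.0) if t > 0.0 else np.zeros_like(z)
    if f.kind == "threshold":
        return (z > f.knot).astype(float)
    raise ValueError(f"unknown feature kind {f.kind!r}")


def feature_matrix(defs: Sequence[FeatureDef], data: pd.DataFrame) -> np.ndarray:
    if not defs:
        return np.zeros((len(data), 0))
    return np.column_stack([evaluate_feature(f, data) for f in defs])


def expand_features(
    data: pd.DataFrame,
    fc: str,
    hinge_knots: int = 50,
    threshold_knots: int = 20,
) -> List[FeatureDef]:
    """Expand training data columns into the feature set for one FC.

    Knots are placed at training quantiles of each scaled variable (interior
    quantiles, never 0 or 1).  With d variables: L gives d features, Q
    another d, P all d(d-1)/2 pairwise products, H 2*hinge_knots per
    variable (forward + reverse) and T threshold_knots per variable.
    """
    if fc not in FEATURE_CLASSES:
        raise ValueError(f"fc must be one of {FEATURE_CLASSES}, got {fc!r}")
    variables = list(data.columns)
    bounds: Dict[str, Tuple[float, float]] = {
        v: (float(data[v].min()), float(data[v].max())) for v in variables
    }

    def b(*vs: str) -> Tuple[Tuple[float, float], ...]:
        return tuple(bounds[v] for v in vs)

    defs: List[FeatureDef] = []
    letters = set(fc)  # e.g. "LQHPT" -> {"L","Q","H","P","T"}
    if "L" in letters:
        defs += [FeatureDef("linear", (v,), b(v)) for v in variables]
    if "Q" in letters:
        defs += [FeatureDef("quadratic", (v,), b(v)) for v in variables]
    if "H" in letters:
        for v in variables:
            z = _scale(data[v].to_numpy(), *bounds[v])
            qs = np.quantile(z, np.linspace(0, 1, hinge_knots + 2)[1:-1])
            for t in np.unique(qs):
                if 0.0 < t < 1.0:
                    defs.append(FeatureDef("hinge", (v,), b(v), knot=float(t), direction="forward"))
                    defs.append(FeatureDef("hinge", (v,), b(v), knot=float(t), direction="reverse"))
    if "P" in letters:
        for i, v1 in enumerate(variables):
            for v2 in variables[i + 1 :]:
                defs.append(FeatureDef("product", (v1, v2), b(v1, v2)))
    if "T" in letters:
        for v in variables:
            z = _scale(data[v].to_numpy(), *bounds[v])
            qs = np.quantile(z, np.linspace(0, 1, threshold_knots + 2)[1:-1])
            for t in np.unique(qs):
                if 0.0 < t < 1.0:
                    defs.append(FeatureDef("threshold", (v,), b(v), knot=float(t)))
    return defs


# Base regularization anchors: (n_presence, beta) pairs per feature kind,
# piecewise-linear in between, constant beyond the end anchors.  This is the
# standard Maxent schedule; the study-level regularization multiplier scales
# the resulting betas.
_BETA_ANCHORS = {
    "linear": [(0, 1.0), (10, 1.0), (30, 0.2), (100, 0.05)],
    "quadratic": [(0, 1.0), (10, 1.0), (30, 0.2), (100, 0.05)],
    "product": [(0, 1.0), (10, 1.0), (30, 0.2), (100, 0.05)],
    "hinge": [(0, 0.5), (1, 0.5)],
    "threshold": [(0, 2.0), (100, 1.0)],
}


def default_beta(feature_kind: str, n_presence: int) -> float:
    """Base L1 penalty beta for a feature kind at a given presence count."""
    if n_presence < 1:
        raise ValueError("n_presence must be >= 1")
    anchors = _BETA_ANCHORS.get(feature_kind)
    if anchors is None:
        raise ValueError(f"unknown feature kind {feature_kind!r}")
    ns = np.array([a[0] for a in anchors], dtype=float)
    bs = np.array([a[1] for a in anchors], dtype=float)
    return float(np.interp(n_presence, ns, bs))
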