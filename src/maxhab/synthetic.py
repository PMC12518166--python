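"""Seeded synthetic landscapes with known ground truth.

The generator emulates the data regime of a regional species-distribution
study: spatially autocorrelated environmental layers on a lon/lat grid, an
elevation field that drives climate covariance (e.g. cold-quarter
temperature decreasing with elevation), a known logistic true-suitability
surface, presence sampling proportional to suitability, and future-scenario
stacks built by additive shifts to the climate layers while static layers
(elevation, soil, human footprint) stay bit-identical.

Spatial autocorrelation comes from Gaussian-smoothed white noise — enough
statistical structure for testing at desk scale, not a full geostatistical
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .grids import GridSpec
from .occurrences import OccurrenceSet
from .stack import EnvStack


@dataclass(frozen=True)
class LayerRecipe:
    """How to synthesize one environmental layer.

    mean, sd
        Target marginal mean and standard deviation in layer units.
    trend_ns, trend_ew
        Deterministic gradient amplitude added south->north / west->east
        (full-extent swing, layer units) before noise.
    smooth_sigma
        Gaussian smoothing radius (cells) applied to the white-noise field.
    corr_with
        Optional (layer_name, rho): build the stochastic part so its
        empirical correlation with the named already-generated layer equals
        rho exactly (residualized construction).
    """

    name: str
    mean: float = 0.0
    sd: float = 1.0
    trend_ns: float = 0.0
    trend_ew: float = 0.0
    smooth_sigma: float = 3.0
    corr_with: Optional[Tuple[str, float]] = None


@dataclass(frozen=True)
class TrueModel:
    """Known generating suitability surface: inverse-logit of a
    linear + quadratic form in the stack's layers.

    ``coefficients`` are per-standardized-unit linear weights; ``optimum``
    and ``curvature`` define concave quadratic terms
    -curvature * ((x - optimum) / sd_layer)^2 peaking at the optimum.
    """

    intercept: float = 0.0
    coefficients: Mapping[str, float] = field(default_factory=dict)
    optimum: Mapping[str, float] = field(default_factory=dict)
    curvature: Mapping[str, float] = field(default_factory=dict)


def _smooth_standard_field(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothed white noise, standardized to mean 0 / sd 1 over the grid."""
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma, mode="nearest")
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)


def make_stack(spec: GridSpec, recipes: Sequence[LayerRecipe], seed: int) -> EnvStack:
    """Generate one layer per recipe on the given grid, deterministically.

    Recipes are processed in order; a ``corr_with`` recipe may only
    reference a layer generated earlier.  Correlated layers are built by
    mixing the reference field with a residualized noise field so the
    empirical Pearson correlation equals the requested value.
    """
    names = [r.name for r in recipes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate layer names in recipe")
    if not recipes:
        raise ValueError("empty recipe")
    rng = np.random.default_rng(seed)
    nr, nc = spec.shape
    # south->north in [0,1]: array row 0 is the north edge
    ns = np.linspace(1.0, 0.0, nr)[:, None] * np.ones((1, nc))
    ew = np.ones((nr, 1)) * np.linspace(0.0, 1.0, nc)[None, :]

    layers: Dict[str, np.ndarray] = {}
    for r in recipes:
        trend = r.trend_ns * ns + r.trend_ew * ew
        if r.corr_with is not None:
            ref_name, rho = r.corr_with
            if ref_name not in layers:
                raise ValueError(f"recipe {r.name!r} references ungenerated layer {ref_name!r}")
            if not (-1.0 <= rho <= 1.0):
                raise ValueError("correlation must be in [-1, 1]")
            z_ref = _standardize(layers[ref_name])
            noise = _smooth_standard_field((nr, nc), r.smooth_sigma, rng)
            resid = noise - (noise * z_ref).mean() / max((z_ref * z_ref).mean(), 1e-30) * z_ref
            resid = _standardize(resid)
            z = rho * z_ref + np.sqrt(max(0.0, 1 - rho**2)) * resid
            field_vals = r.mean + r.sd * _standardize(z)
        else:
            noise = _smooth_standard_field((nr, nc), r.smooth_sigma, rng) if r.sd > 0 else 0.0
            field_vals = r.mean + trend + r.sd * noise
        layers[r.name] = field_vals
    return EnvStack(spec, layers)


def true_suitability(stack: EnvStack, model: TrueModel) -> np.ndarray:
    """Evaluate the generating suitability surface on the stack's grid.

    Returns values in (0, 1); nodata cells propagate as NaN.
    """
    for name in list(model.coefficients) + list(model.optimum):
        if name not in stack.layers:
            raise KeyError(f"model references layer {name!r} not in stack")
    eta = np.full(stack.grid.shape, float(model.intercept))
    for name, coef in model.coefficients.items():
        eta = eta + coef * _standardize_nan(stack.layers[name])
    for name, opt in model.optimum.items():
        x = stack.layers[name]
        sd = np.nanstd(x)
        sd = sd if sd > 0 else 1.0
        curv = model.curvature.get(name, 1.0)
        eta = eta - curv * ((x - opt) / sd) ** 2
    suit = special.expit(eta)
    suit[stack.nodata_mask()] = np.nan
    return suit


def _standardize_nan(a: np.ndarray) -> np.ndarray:
    sd = np.nanstd(a)
    return (a - np.nanmean(a)) / sd if sd > 0 else np.zeros_like(a)


def sample_occurrences(
    stack: EnvStack,
    suitability: np.ndarray,
    n: int,
    seed: int,
    species: str = "synthetic",
    bias: Optional[np.ndarray] = None,
    year_range: Tuple[int, int] = (1950, 2020),
    year_elevation_link: float = 0.0,
) -> OccurrenceSet:
    """Draw ``n`` presence records with cell probability ∝ suitability × bias.

    Records sit at cell centers and carry the cell's "elev" value when the
    stack has one.  Years are uniform over ``year_range``; with
    ``year_elevation_link`` = r in (0, 1], years are instead assigned so the
    rank correlation between year and elevation approaches r, giving the
    elevation-trend analysis a known signal.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = np.array(suitability, dtype=float)
    if bias is not None:
        p = p * np.asarray(bias, dtype=float)
    flat = np.where(np.isnan(p.ravel()), 0.0, p.ravel())
    total = flat.sum()
    if total <= 0:
        raise ValueError("suitability (x bias) has no positive data cells")
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=True, p=flat / total)
    rows, cols = np.unravel_index(idx, p.shape)
    lon, lat = stack.grid.cell_center(rows, cols)
    elev = stack.layers["elev"][rows, cols] if "elev" in stack.layers else np.full(n, np.nan)

    lo, hi = year_range
    if year_elevation_link > 0 and "elev" in stack.layers:
        r = min(year_elevation_link, 1.0)
        z_elev = _standardize(np.asarray(elev, dtype=float)) if n > 1 else np.zeros(n)
        latent = r * z_elev + np.sqrt(1 - r**2) * rng.standard_normal(n)
        ranks = np.argsort(np.argsort(latent))
        years = lo + np.round(ranks / max(n - 1, 1) * (hi - lo)).astype(int)
    else:
        years = rng.integers(lo, hi + 1, size=n)

    records = pd.DataFrame(
        {
            "species": species,
            "longitude": lon,
            "latitude": lat,
            "elevation": elev,
            "year": years.astype(float),
        }
    )
    return OccurrenceSet(records, species)


def make_future(stack: EnvStack, scenario: str, deltas: Mapping[str, float]) -> EnvStack:
    """Additively shifted scenario stack; unnamed layers stay bit-identical.

    This mirrors the static-layer assumption of scenario projection:
    elevation, soil, and human-footprint layers do not change, only climate
    layers move.
    """
    unknown = [k for k in deltas if k not in stack.layers]
    if unknown:
        raise KeyError(f"deltas name layers not in stack: {unknown}")
    layers = {}
    for name, arr in stack.layers.items():
        layers[name] = arr + deltas[name] if name in deltas else arr
    return EnvStack(stack.grid, layers, dict(stack.units))


def default_world(
    seed: int,
    n_rows: int = 60,
    n_cols: int = 60,
) -> Tuple[EnvStack, TrueModel, np.ndarray]:
    """A compact ready-made study system: mountainous landscape, four
    climate/terrain layers plus a human-footprint layer, and a true model
    with a quadratic elevation optimum at 3500 m.

    Returns (stack, true_model, true_suitability).
    """
    spec = GridSpec(n_rows=n_rows, n_cols=n_cols, x_min=98.0, y_min=28.0, cell_size=2.5 / 60.0)
    recipes = [
        LayerRecipe("elev", mean=3200, sd=700, trend_ns=800, smooth_sigma=4),
        LayerRecipe("bio11", mean=-2.0, sd=3.0, corr_with=("elev", -0.85), smooth_sigma=4),
        LayerRecipe("bio12", mean=700, sd=180, trend_ew=-150, smooth_sigma=4),
        LayerRecipe("bio4", mean=750, sd=60, smooth_sigma=4),
        LayerRecipe("hfp", mean=8, sd=5, corr_with=("elev", -0.4), smooth_sigma=2),
    ]
    stack = make_stack(spec, recipes, seed=seed)
    # A montane, cold-adapted niche: quadratic optima in both elevation and
    # cold-quarter temperature (the two are strongly anti-correlated), plus
    # a precipitation benefit and human-footprint avoidance.  Making the
    # temperature layer causal is what lets warming scenarios move the
    # suitable range uphill, as in a real climate-projection study.
    model = TrueModel(
        intercept=1.5,
        coefficients={"bio12": 0.8, "hfp": -0.5},
        optimum={"elev": 3500.0, "bio11": -2.0},
        curvature={"elev": 2.5, "bio11": 2.5},
    )
    suit = true_suitability(stack, model)
    return stack, model, suit
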