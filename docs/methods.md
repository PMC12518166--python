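# Methods

This note records the models, conventions, and numerical choices behind
`maxhab`, including the places where the design was genuinely open and a
decision had to be made.

## The maximum-entropy presence–background model

The core estimator is the classic presence–background maximum-entropy
(Maxent) model: among all distributions over landscape cells whose feature
expectations match the presence sample, take the one of maximum entropy —
equivalently, the Gibbs distribution `q_λ(x) ∝ exp(λ·f(x))` that maximizes
the L1-regularized log-likelihood ("gain") of the presences. The gain is
reported relative to the uniform distribution, so an all-zero model has
gain 0 and a fitted gain of `g` means the average presence is `e^g` times
more concentrated than uniform.

**Landscape.** The normalizer `Z` and the entropy `H` are computed over the
deduplicated union of presence and background cells. Presence cells are
not excluded from the background (standard presence–background practice;
the background represents available environment, not absences).

**Features.** Variables are min/max-scaled to [0, 1] on the full training
sample (presence ∪ background) and clamped outside that range; a constant
variable maps to the zero feature. Feature classes follow the canonical
ENMeval letter sets — L linear, Q quadratic, P pairwise products, H hinge
(forward + reverse pairs), T thresholds — with hinge/threshold knots at
interior training quantiles. Defaults are 50 hinge knots and 20 threshold
knots per variable, both configurable; desk-scale analyses in the test
suite and acceptance script use 5–8 knots, which preserves every
qualitative behavior at a fraction of the cost.

**Regularization.** The effective L1 penalty on feature `j` is
`RM · β_kind(m) · sd_j / √m`, with `sd_j` the feature's standard deviation
over the background sample and `β_kind(m)` the standard piecewise-linear
Maxent schedule in the presence count `m`: linear/quadratic/product
anchors (0, 1.0), (10, 1.0), (30, 0.2), (100, 0.05); hinge constant 0.5;
threshold (0, 2.0) to (100, 1.0); constant beyond end anchors.

**Optimizer.** Cyclic coordinate ascent. Each coordinate takes a proximal
Newton step (soft-threshold on the local quadratic model of the smooth
part) followed by exact backtracking on the true regularized gain, so an
accepted update can never decrease the objective. This was chosen over a
generic convex solver because percent contribution requires attributing
each accepted update's gain increment to the updated feature's variable
(split equally for products). Iteration stops when a full cycle improves
the gain by less than `tol` (default 1e-5) or at `max_iterations` cycles
(default 1000). The fitted optimum is verified in the test suite against
dense 1-D grid search and a Nelder-Mead solve of the same objective on
small problems (agreement to 1e-3).

**Outputs.** Raw output is the normalized Gibbs probability. Logistic
output is `e^H·q/(1 + e^H·q)` (prevalence fixed at 0.5, the Maxent
default, exposed in configuration); cloglog is `1 − exp(−e^H·q)`. When a
model is projected onto a raster stack, cells are evaluated pointwise
under the *training* normalizer, the same convention as response curves.
Renormalizing over the projection grid instead would couple the logistic
scale to the number of projection cells (a grid with more cells than the
training landscape would systematically deflate suitability), which is why
the renormalized form is reserved for the raw output, where sum-to-one
over the evaluation set is the defining property.

## Model selection and evaluation

Tuning fits every feature-class × regularization-multiplier candidate
(defaults: 6 FCs × 8 RMs = 48) on the full presence set and ranks by AICc
computed from raw scores standardized over the training landscape, with
`k` = number of nonzero coefficients and `n` = number of presences.
Candidates with `k ≥ n − 1` are flagged invalid and excluded from ranking.
Ties at the minimum AICc are broken toward higher RM, then simpler FC —
the tie-break is unavoidable (AICc ties happen on small grids) and is
deliberately biased toward parsimony.

Replicate evaluation repeats a random 75/25 presence split 10 times,
refits on the training portion against the full background, and scores the
held-out presences against the background by rank-sum AUC (midranks on
ties; verified exactly against brute-force pair counting). The reported
map is the cellwise mean of the replicate logistic maps. AUC grade bands:
≥ 0.9 excellent, ≥ 0.8 good, ≥ 0.7 average, ≥ 0.5 poor.

Variable screening runs a pre-model on all candidates (LQHPT, RM = 1 —
the conventional "default parameters" run), takes percent contributions,
and greedily accepts variables in descending contribution order unless
|Spearman r| ≥ 0.8 against an already-accepted variable; accepted
variables under 1% contribution are then dropped. Both thresholds are
configurable; every exclusion is recorded with its cause and partner.
Correlations are computed on presence rows by default (the species'
occupied environment is what matters for its niche description); a
presence+background mode exists.

Response curves support two modes: *marginal* (vary one variable across
its presence range, others fixed at presence means) and *single-variable*
(refit on that variable alone). Optimum reporting uses the
single-variable mode by default in the acceptance pipeline: with strongly
inter-correlated predictors (e.g. elevation vs. cold-quarter temperature)
the marginal curve is confounded by the frozen correlates, and the
single-variable refit recovers the generating optimum markedly more
reliably in the synthetic benchmark. The suitable interval is the
abscissa range where logistic suitability exceeds 0.5 (reported as empty
when nothing does). The jackknife fits with-only and without models per
variable and reports their regularized gains; `gain_without ≤ gain_full`
holds because the reduced feature set is feasible for the full problem.

## Suitability classes, areas, centroids

Class bounds are 0.2 / 0.4 / 0.6. The lower bound belongs to unsuitable
(the class is "≤ 0.2"); 0.4 and 0.6 are assigned upward ([0.4, 0.6) is
moderate, [0.6, 1] high) — the boundary policy is configurable and logged
because interval notation at the two upper cuts is ambiguous in common
usage. "Suitable" for change and centroid analysis means any class above
unsuitable. Cell areas are spherical: `R²·Δλ·(sin φ_N − sin φ_S)` with
R = 6371.0088 km, so area depends on the row latitude only; totals are
reported in 10⁴ km². Range centroids are area-weighted means of suitable
cell centers in lon/lat (a suitability-weighted mode exists; binary is
default), adequate at regional extents; centroid displacement uses the
haversine distance and initial bearing, labeled by compass octant
(±22.5°). Per-scenario tables report both distance-from-current and
distance-from-previous-period; for the first future period the two
coincide by construction.

## Occurrence handling

Cleaning drops records without coordinates and collapses exact coordinate
duplicates (first kept). Thinning keeps at most one record per grid cell
of the environmental grid — the guard against pseudo-replication — with
the retained record chosen uniformly at random under the stage seed rather
than first-in-file, to avoid inheriting source-database ordering
artifacts. Thinning is idempotent and the retained count equals the
number of occupied cells. Cell membership uses corner registration,
half-open cells [edge, edge + size), row 0 northernmost — one convention
shared by every module and cross-checked by a nearest-cell-center oracle
test. Thinning on the environmental grid itself (2.5 arc-minute cells,
≈ 5 km at these latitudes) is the interpretation adopted for "one record
per ~5 km cell"; a metric 5 km grid would differ with latitude, and
per-modeling-cell uniqueness is the property that actually matters.

## Elevation–time trends

Per species, OLS of record elevation on collection year, split into
pre-/post-2000 periods (records at exactly 2000 go to the post period;
configurable). Slope significance is the standard two-sided t-test;
direction is called only at p < 0.05. Periods with fewer than 3 usable
records, or with no year variance, return explicit "insufficient data" /
"all years identical" results rather than numbers.

## The synthetic world

The generator emulates the data regime of a regional montane SDM study:

- **Layers**: Gaussian-smoothed white noise plus optional deterministic
  gradients on a lon/lat grid — spatially autocorrelated structure at desk
  scale, not a geostatistical model. Climate layers can be constructed to
  an exact empirical correlation with the elevation field (residualized
  mixing), e.g. cold-quarter temperature at r = −0.85.
- **Truth**: suitability is the inverse-logit of a linear + concave
  quadratic form. The default world is a specialist montane niche —
  quadratic optima at 3500 m elevation and −2 °C cold-quarter temperature
  (curvature 2.5 per standardized unit), a precipitation benefit, and
  human-footprint avoidance. Making the temperature layer causal (not
  merely correlated with elevation) is what gives warming scenarios a
  mechanism to move the suitable range uphill, as in the real studies this
  design emulates.
- **Sampling**: presences are multinomial draws proportional to
  suitability (optionally × a bias layer), at cell centers, carrying the
  cell's elevation. Years are uniform over 1950–2020 by default; an
  optional rank-coupling parameter links year to elevation so the trend
  module has a known signal.
- **Scenarios**: additive shifts to named climate layers; all other layers
  (elevation, soil, human footprint) stay bit-identical — the static-layer
  assumption of scenario projection.

What the synthetic world does **not** emulate: sampling bias fields beyond
a user-supplied layer, non-stationary spatial covariance, landscape-scale
anisotropy, land-use dynamics, or GCM-specific change patterns. Passing
the recovery tests therefore demonstrates the pipeline's statistical
machinery is sound, not that any particular real dataset would yield the
same conclusions.

Benchmarks in the test suite and acceptance script use a 50 × 50 grid
(2.5-arc-minute cells), 200 presences, 800 background cells, 5–8 knots and
150–300 optimizer cycles; these sizes were chosen so the complete suite
exercises every stage, including the 48-candidate tuning grid and 10-seed
recovery studies, in well under a minute each while leaving all stochastic
margins comfortable.

## Known limitations

- No categorical feature type (class-coded soil variables are treated as
  numeric).
- No clamping diagnostics or extrapolation maps beyond [0, 1] feature
  clamping.
- No spatial cross-validation (random presence splits only) and no
  omission/Boyce metrics; evaluation is AUC-based.
- Percent contribution is path-dependent (as in Maxent itself): it
  depends on the optimizer's update order, so for strongly correlated
  variables it should be read together with the jackknife gains.
- Centroids are computed in lon/lat with area weights, not on an
  equal-area projection; fine regionally, biased for near-global extents.
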