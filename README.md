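# maxhab

Presence–background habitat suitability modeling for species distribution
studies: occurrence thinning, a from-scratch regularized maximum-entropy
model, feature-class/regularization tuning by AICc, jackknife variable
importance and response curves, four-class suitability mapping, and
area/centroid change analysis across climate scenarios — plus an
elevation-over-time trend analysis of collection records.

The package targets the common montane-plant study design: georeferenced
herbarium/occurrence records for a handful of species, a stack of
bioclimatic/terrain/soil/human-footprint rasters at 2.5 arc-minutes, and
future climate stacks under SSP scenarios. Everything is exercisable
end-to-end on seeded synthetic landscapes with known ground truth, so the
whole pipeline is testable without external data downloads.

## The model

Given presence cells $x_1..x_m$ and a background sample over the landscape,
the model is the Gibbs distribution over cells

$$q_\lambda(x) = \frac{e^{\lambda \cdot f(x)}}{Z(\lambda)}$$

with features $f$ (linear, quadratic, product, hinge, threshold expansions
of the environmental variables, each scaled to $[0,1]$), fitted by
maximizing the L1-regularized training gain

$$G(\lambda) = \frac{1}{m}\sum_i \lambda \cdot f(x_i) - \ln Z(\lambda)
              - \sum_j \beta_j^{\mathrm{eff}} |\lambda_j|,
\qquad \beta_j^{\mathrm{eff}} = \mathrm{RM} \cdot \beta_{\mathrm{kind}}(m)
 \cdot \mathrm{sd}_j/\sqrt{m}.$$

The optimizer is cyclic coordinate ascent with a proximal Newton step and
exact backtracking; the gain never decreases on an accepted update, and
per-update gain increments are attributed to variables to produce percent
contributions. Outputs: raw (normalized Gibbs probabilities), logistic
$e^H q/(1+e^H q)$ and cloglog $1-\exp(-e^H q)$, where $H$ is the entropy of
the fitted raw distribution (prevalence 0.5).

Candidate models over the six feature-class sets (L, LQ, H, LQH, LQHP,
LQHPT) and eight regularization multipliers (0.5–4.0, step 0.5) — 48
combinations — are ranked by the small-sample AIC,
$\mathrm{AICc} = 2k - 2\ln L + 2k(k+1)/(n-k-1)$ with $k$ the number of
nonzero coefficients, and the candidate with $\Delta\mathrm{AICc}=0$ is
selected. Discrimination is summarized by the rank-sum AUC with the usual
grade bands (≥0.9 excellent, ≥0.8 good, ≥0.7 average, ≥0.5 poor).

Continuous suitability is reclassified as unsuitable [0, 0.2], general
(0.2, 0.4), moderate [0.4, 0.6) and high [0.6, 1]; per-class areas use
spherical cell areas (reported in 10⁴ km²), range gain/loss/net is computed
between periods, and range centroids (area-weighted) are compared by
haversine distance and compass octant.

## Worked example

```python
import maxhab as mh
from maxhab.evaluation import tune, replicate_evaluation, response_curve
from maxhab.model import fit

# synthetic mountain landscape with a known niche (optimum at 3500 m)
stack, truth, suit = mh.default_world(seed=1, n_rows=50, n_cols=50)
occ = mh.sample_occurrences(stack, suit, 200, seed=2)
thinned, report = mh.thin(occ, stack.grid, seed=3)
matrix, _ = mh.make_sample_matrix(stack, thinned, n_background=800, seed=4)

result = tune(matrix, hinge_knots=6, threshold_knots=6, max_iterations=150)
print(report.n_retained, result.selected_fc, result.selected_rm)

model = fit(matrix, "LQ", 1.0)
curve = response_curve(model, matrix, "elev", mode="single")
print(round(curve.optimum), curve.suitable_interval)
```

prints

```
191 LQHP 2.0
3563 (3196.7626081694866, 3928.7897311725733)
```

— 191 of 200 sampled records survive one-per-cell thinning, the tuner
selects the LQHP feature class at a moderate regularization multiplier,
and the single-variable response curve recovers the generating elevation
optimum (3500 m) to within a few percent of the presence range, with a
suitable interval (> 0.5) of roughly 3200–3930 m.

The same stages run from the shell: `maxhab simulate`, `maxhab thin`,
`maxhab tune`, `maxhab run --config cfg.yaml` (see `maxhab --help`).

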