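"""Model tuning, screening, and interrogation.

Covers the study's evaluation toolchain: Spearman-based variable screening
against a pre-modeling contribution run, AICc model selection over the
feature-class × regularization-multiplier grid, replicate train/test AUC
evaluation, jackknife variable importance, percent contribution, and
response curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .features import DEFAULT_RM_GRID, FEATURE_CLASSES
from .model import MaxentModel, fit
from .stack import EnvStack, SampleMatrix

# ---------------------------------------------------------------------------
# AUC


def auc(presence_scores, background_scores) -> float:
    """Area under the ROC curve for presence vs background scores.

    Equals the Mann-Whitney statistic P(s_pres > s_bg) + 0.5 P(tie),
    computed via midranks so ties are handled exactly.
    """
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if len(pres) == 0 or len(bg) == 0:
        raise ValueError("need at least one score on each side")
    ranks = stats.rankdata(np.concatenate([pres, bg]))
    r1 = ranks[: len(pres)].sum()
    return float((r1 - len(pres) * (len(pres) + 1) / 2) / (len(pres) * len(bg)))


def auc_grade(value: float) -> str:
    """Accuracy band: excellent / good / average / poor."""
    if value >= 0.9:
        return "excellent"
    if value >= 0.8:
        return "good"
    if value >= 0.7:
        return "average"
    if value >= 0.5:
        return "poor"
    return "worse than random"


# ---------------------------------------------------------------------------
# AICc tuning


def compute_aicc(model: MaxentModel, matrix: SampleMatrix) -> Tuple[float, int, float]:
    """(lnL, k, AICc) of a fitted model on its presences.

    Raw scores are standardized to sum to one over the training landscape;
    lnL is the summed log raw score of the presences; k counts nonzero
    coefficients.  AICc = 2k − 2 lnL + 2k(k+1)/(n−k−1) is undefined (NaN,
    excluded from ranking) when k ≥ n − 1.
    """
    eta = model.linear_score(matrix.presence())
    lnl = float(np.sum(eta - model.log_z))
    k = model.k
    n = matrix.n_presence
    if k >= n - 1:
        return lnl, k, float("nan")
    aicc = 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)
    return lnl, k, float(aicc)


@dataclass
class TuningResult:
    table: pd.DataFrame          # fc, rm, lnl, k, aicc, delta_aicc, auc_train, valid
    selected_fc: str
    selected_rm: float
    models: Dict[Tuple[str, float], MaxentModel]

    @property
    def selected_model(self) -> MaxentModel:
        return self.models[(self.selected_fc, self.selected_rm)]


def tune(
    matrix: SampleMatrix,
    fcs: Sequence[str] = FEATURE_CLASSES,
    rms: Sequence[float] = DEFAULT_RM_GRID,
    seed: int = 0,
    **fit_kwargs,
) -> TuningResult:
    """Fit every FC × RM candidate and select the minimum-AICc model.

    The default grids give 48 candidates.  Ties at the minimum AICc are
    broken toward stronger regularization (higher RM), then simpler feature
    classes, biasing the selection toward parsimony.  The selected row has
    delta_aicc = 0 by construction.
    """
    if not fcs or not len(rms):
        raise ValueError("empty tuning grid")
    rows = []
    models: Dict[Tuple[str, float], MaxentModel] = {}
    for fc in fcs:
        for rm in rms:
            m = fit(matrix, fc, rm, seed=seed, **fit_kwargs)
            lnl, k, aicc = compute_aicc(m, matrix)
            a_train = auc(
                m.linear_score(matrix.presence()), m.linear_score(matrix.background())
            )
            models[(fc, float(rm))] = m
            rows.append(
                {
                    "fc": fc,
                    "rm": float(rm),
                    "lnl": lnl,
                    "k": k,
                    "aicc": aicc,
                    "auc_train": a_train,
                    "valid": np.isfinite(aicc),
                }
            )
    table = pd.DataFrame(rows)
    valid = table[table["valid"]]
    if valid.empty:
        raise ValueError("no valid AICc candidates (k >= n-1 everywhere)")
    best_aicc = valid["aicc"].min()
    table["delta_aicc"] = table["aicc"] - best_aicc
    ties = valid[np.isclose(valid["aicc"], best_aicc)]
    fc_rank = {fc: i for i, fc in enumerate(FEATURE_CLASSES)}
    ties = ties.sort_values(
        by=["rm", "fc"],
        key=lambda s: -s if s.name == "rm" else s.map(fc_rank),
        ascending=[True, True],
    )
    sel = ties.iloc[0]
    return TuningResult(table, str(sel["fc"]), float(sel["rm"]), models)


# ---------------------------------------------------------------------------
# Variable screening


def fit_model_for_screening(matrix: SampleMatrix, config=None, **fit_kwargs) -> MaxentModel:
    """Pre-modeling contribution run: all candidate variables, LQHPT, RM = 1.

    This is the conventional "default parameters" model whose percent
    contributions feed the correlation screen, before any tuning.
    """
    if config is not None:
        fit_kwargs = config.fit_kwargs()
    return fit(matrix, "LQHPT", 1.0, **fit_kwargs)


def spearman_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations (average ranks on ties)."""
    if len(data) < 3:
        raise ValueError("need at least 3 rows for rank correlation")
    cols = list(data.columns)
    rho = stats.spearmanr(data.to_numpy(), axis=0).statistic
    rho = np.atleast_2d(rho)
    if rho.shape != (len(cols), len(cols)):  # 2-variable case returns a scalar
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
    return pd.DataFrame(rho, index=cols, columns=cols)


def select_variables(
    contributions: pd.DataFrame,
    corr: pd.DataFrame,
    r_threshold: float = 0.8,
    min_contribution: float = 1.0,
) -> Tuple[List[str], List[dict]]:
    """Greedy correlation/contribution screen.

    ``contributions`` needs columns variable, percent_contribution.
    Variables are taken in descending contribution order; one is accepted
    iff its |Spearman r| with every already-accepted variable is below the
    threshold.  Accepted variables with contribution under
    ``min_contribution`` percent are then dropped.  The audit trail records
    every exclusion with its cause and, for correlation exclusions, the
    partner variable.
    """
    order = contributions.sort_values("percent_contribution", ascending=False)
    missing = [v for v in order["variable"] if v not in corr.columns]
    if missing:
        raise ValueError(f"correlation matrix missing variables: {missing}")
    kept: List[str] = []
    audit: List[dict] = []
    for _, row in order.iterrows():
        v, c = row["variable"], row["percent_contribution"]
        partner = next((u for u in kept if abs(corr.loc[v, u]) >= r_threshold), None)
        if partner is not None:
            audit.append(
                {
                    "variable": v,
                    "action": "excluded",
                    "cause": "correlation",
                    "partner": partner,
                    "r": float(corr.loc[v, partner]),
                }
            )
            continue
        kept.append(v)
    final = []
    for v in kept:
        c = float(order.set_index("variable").loc[v, "percent_contribution"])
        if c < min_contribution:
            audit.append(
                {"variable": v, "action": "excluded", "cause": "low_contribution", "percent": c}
            )
        else:
            final.append(v)
            audit.append({"variable": v, "action": "kept"})
    return final, audit


# ---------------------------------------------------------------------------
# Contribution and jackknife


def percent_contribution(model: MaxentModel) -> pd.DataFrame:
    """Percent of accrued regularized-gain increments per variable.

    Each accepted optimizer update's gain increment is credited to the
    updated feature's variable (split equally for products); shares are
    normalized to sum to 100.  A model that accrued no gain is flagged.
    """
    gains = model.gain_per_variable
    total = sum(gains.values())
    if not gains or total <= 0:
        return pd.DataFrame(
            {"variable": [], "percent_contribution": []}
        ).assign(no_gain=True)
    rows = [
        {"variable": v, "percent_contribution": 100.0 * g / total}
        for v, g in sorted(gains.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows)


def jackknife(
    matrix: SampleMatrix, fc: str, rm: float, seed: int = 0, **fit_kwargs
) -> pd.DataFrame:
    """Per-variable with-only / without training gains (Maxent jackknife).

    Returns one row per variable with gain_with_only, gain_without and the
    full-model gain; for a single-variable matrix the without-model cannot
    be fitted and its gain is NaN with a note.
    """
    variables = matrix.variables
    full = fit(matrix, fc, rm, seed=seed, **fit_kwargs)
    rows = []
    for v in variables:
        only = fit(matrix.subset_variables([v]), fc, rm, seed=seed, **fit_kwargs)
        rest = [u for u in variables if u != v]
        if rest:
            without = fit(matrix.subset_variables(rest), fc, rm, seed=seed, **fit_kwargs)
            g_without, note = without.gain, ""
        else:
            g_without, note = float("nan"), "no remaining variables"
        rows.append(
            {
                "variable": v,
                "gain_with_only": only.gain,
                "gain_without": g_without,
                "gain_full": full.gain,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Replicate evaluation


@dataclass
class ReplicateResult:
    aucs: List[float]
    mean_auc: float
    mean_map: Optional[np.ndarray]   # cellwise mean logistic suitability
    grade: str


def project(model: MaxentModel, stack: EnvStack, output: str = "logistic") -> np.ndarray:
    """Project a fitted model onto a stack: per-cell suitability raster.

    Logistic/cloglog cells are evaluated pointwise under the training
    normalizer (the same convention as response curves), so suitability
    values keep the training scale regardless of the projection grid's
    size.  The raw output is renormalized to sum to one over the stack's
    data cells.
    """
    rows, cols = stack.data_cells()
    data = stack.values_at(rows, cols, names=_model_variables(model))
    if output == "raw":
        vals = model.predict_raw(data)
    elif output == "logistic":
        vals = model.predict_logistic(data, renormalize=False)
    elif output == "cloglog":
        vals = model.predict_cloglog(data, renormalize=False)
    else:
        raise ValueError(f"unknown output {output!r}")
    out = np.full(stack.grid.shape, np.nan)
    out[rows, cols] = vals
    return out


def _model_variables(model: MaxentModel) -> List[str]:
    seen: List[str] = []
    for f in model.features:
        for v in f.variables:
            if v not in seen:
                seen.append(v)
    return seen


def replicate_evaluation(
    matrix: SampleMatrix,
    fc: str,
    rm: float,
    n_replicates: int = 10,
    test_fraction: float = 0.25,
    seed: int = 0,
    stack: Optional[EnvStack] = None,
    **fit_kwargs,
) -> ReplicateResult:
    """Repeated random train/test presence splits with refitting.

    Each replicate holds out ``test_fraction`` of the presences, refits on
    the rest (against the full background), and scores test-presence vs
    background AUC.  When a stack is given the final map is the cellwise
    mean of the per-replicate logistic projections.
    """
    rng = np.random.default_rng(seed)
    pres_idx = np.nonzero(matrix.is_presence)[0]
    bg_idx = np.nonzero(~matrix.is_presence)[0]
    n_test = max(1, int(round(test_fraction * len(pres_idx))))
    aucs: List[float] = []
    maps: List[np.ndarray] = []
    for _ in range(n_replicates):
        perm = rng.permutation(len(pres_idx))
        test = pres_idx[perm[:n_test]]
        train = pres_idx[perm[n_test:]]
        sub = matrix.subset_rows(np.concatenate([train, bg_idx]))
        m = fit(sub, fc, rm, seed=seed, **fit_kwargs)
        test_scores = m.linear_score(matrix.data.iloc[test])
        bg_scores = m.linear_score(matrix.data.iloc[bg_idx])
        aucs.append(auc(test_scores, bg_scores))
        if stack is not None:
            maps.append(project(m, stack, output="logistic"))
    mean_auc = float(np.mean(aucs))
    mean_map = np.mean(maps, axis=0) if maps else None
    return ReplicateResult(aucs, mean_auc, mean_map, auc_grade(mean_auc))


# ---------------------------------------------------------------------------
# Response curves


@dataclass
class ResponseCurve:
    variable: str
    abscissa: np.ndarray
    ordinate: np.ndarray
    optimum: float
    suitable_interval: Optional[Tuple[float, float]]   # ordinate > 0.5, None if empty


def response_curve(
    model: MaxentModel,
    matrix: SampleMatrix,
    variable: str,
    n_points: int = 100,
    mode: str = "marginal",
    fit_kwargs: Optional[dict] = None,
) -> ResponseCurve:
    """Suitability as a function of one variable.

    "marginal" varies the variable over its training range with the others
    held at presence means; "single" refits a one-variable model (the
    model's fc/rm) and evaluates it.  The ordinate is the logistic output
    under the training normalizer; the suitable interval is where it
    exceeds 0.5 (reported as None when empty).
    """
    pres = matrix.presence()
    if variable not in pres.columns:
        raise KeyError(f"variable {variable!r} not in matrix")
    lo, hi = float(pres[variable].min()), float(pres[variable].max())
    xs = np.linspace(lo, hi, n_points)
    if mode == "marginal":
        base = {v: float(pres[v].mean()) for v in _model_variables(model)}
        frame = pd.DataFrame({v: np.full(n_points, base[v]) for v in base})
        frame[variable] = xs
        ys = model.predict_logistic(frame, renormalize=False)
    elif mode == "single":
        single = fit(
            matrix.subset_variables([variable]), model.fc, model.rm, **(fit_kwargs or {})
        )
        frame = pd.DataFrame({variable: xs})
        ys = single.predict_logistic(frame, renormalize=False)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ys = np.asarray(ys, dtype=float)
    optimum = float(xs[int(np.argmax(ys))])
    above = xs[ys > 0.5]
    interval = (float(above.min()), float(above.max())) if above.size else None
    return ResponseCurve(variable, xs, ys, optimum, interval)
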