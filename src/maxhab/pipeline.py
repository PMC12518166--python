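"""End-to-end study orchestration from a single YAML config.

Stages per species: read → clean → thin → pre-modeling contribution run →
Spearman screening → FC×RM tuning by AICc → replicate fitting and AUC →
mean suitability maps per scenario → four-class classification → area and
gain/loss bookkeeping → centroid shifts → elevation-time trends.  Every
stochastic stage derives its seed from the config seed, and the bundle
records enough provenance (config hash, seeds) to reproduce outputs
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import change as ch
from . import evaluation as ev
from . import occurrences as occ
from .features import DEFAULT_RM_GRID, FEATURE_CLASSES
from .grids import write_ascii_grid
from .stack import EnvStack, build_stack, make_sample_matrix

log = logging.getLogger("maxhab")


@dataclass
class ScenarioRef:
    scenario: str
    period: str
    layers: Dict[str, str]

    @property
    def label(self) -> str:
        return f"{self.scenario}_{self.period}"


@dataclass
class RunConfig:
    species: List[Dict[str, str]]          # [{name, occurrences}]
    current_stack: Dict[str, str]          # layer name -> .asc path
    scenarios: List[ScenarioRef] = field(default_factory=list)
    out_dir: str = "maxhab_out"
    seed: int = 0
    background_size: int = 10_000
    hinge_knots: int = 50
    threshold_knots: int = 20
    max_iterations: int = 1000
    tol: float = 1e-5
    n_replicates: int = 10
    test_fraction: float = 0.25
    r_threshold: float = 0.8
    min_contribution: float = 1.0
    class_bounds: Tuple[float, float, float] = (0.2, 0.4, 0.6)
    fcs: Sequence[str] = FEATURE_CLASSES
    rms: Sequence[float] = DEFAULT_RM_GRID
    min_presences: int = 10
    trend_split_year: int = 2000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        scenarios = [
            ScenarioRef(s["scenario"], str(s["period"]), dict(s["layers"]))
            for s in raw.get("scenarios", [])
        ]
        kwargs = {k: v for k, v in raw.items() if k not in ("scenarios", "class_bounds")}
        if "class_bounds" in raw:
            kwargs["class_bounds"] = tuple(raw["class_bounds"])
        return cls(scenarios=scenarios, **kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def fit_kwargs(self) -> dict:
        return {
            "hinge_knots": self.hinge_knots,
            "threshold_knots": self.threshold_knots,
            "max_iterations": self.max_iterations,
            "tol": self.tol,
        }


def validate(config: RunConfig) -> List[str]:
    """Fail-fast config check; returns a list of problems (empty = valid)."""
    problems: List[str] = []
    for sp in config.species:
        if not Path(sp["occurrences"]).exists():
            problems.append(f"occurrence file missing: {sp['occurrences']}")
    ref_grid = None
    for name, path in config.current_stack.items():
        if not Path(path).exists():
            problems.append(f"current layer {name!r} missing: {path}")
    for sc in config.scenarios:
        for name, path in sc.layers.items():
            if not Path(path).exists():
                problems.append(f"{sc.label} layer {name!r} missing: {path}")
    b1, b2, b3 = config.class_bounds
    if not (0.0 < b1 < b2 < b3 < 1.0):
        problems.append(f"class bounds not ascending in (0,1): {config.class_bounds}")
    if not problems:
        try:
            current = build_stack(config.current_stack)
            ref_grid = current.grid
            for sc in config.scenarios:
                st = build_stack(sc.layers)
                if not st.grid.approx_equal(ref_grid):
                    problems.append(f"{sc.label}: grid mismatch vs current stack")
        except ValueError as exc:
            problems.append(str(exc))
    return problems


@dataclass
class SpeciesResult:
    species: str
    n_thinned: int
    kept_variables: List[str]
    selected_fc: str
    selected_rm: float
    tuning_table: pd.DataFrame
    contribution: pd.DataFrame
    jackknife: pd.DataFrame
    mean_auc: float
    auc_grade: str
    areas: Dict[str, Dict[str, float]]             # label -> class areas
    changes: List[ch.ChangeSummary]
    centroid_rows: List[dict]
    trends: Tuple
    error: Optional[str] = None


@dataclass
class RunBundle:
    config_hash: str
    results: Dict[str, SpeciesResult]
    log_records: List[dict]


def _species_seed(base: int, index: int) -> int:
    return (base * 1_000_003 + 7919 * (index + 1)) % (2**31 - 1)


def run(config: RunConfig) -> RunBundle:
    """Execute the full pipeline for every species and scenario.

    A failing species is recorded with a structured error and does not stop
    the others.  Outputs (tables, classified rasters, summaries, log) are
    written under ``config.out_dir``.
    """
    problems = validate(config)
    if problems:
        raise ValueError("config invalid: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records: List[dict] = []
    chash = config.config_hash()

    def note(stage: str, name: str, /, **kw):
        kw.pop("species", None)
        rec = {"stage": stage, "species": name, "config": chash, **kw}
        records.append(rec)
        log.info("%s %s %s", stage, name, kw)

    current = build_stack(config.current_stack)
    scenario_stacks = {sc.label: build_stack(sc.layers) for sc in config.scenarios}

    results: Dict[str, SpeciesResult] = {}
    for i, sp in enumerate(config.species):
        name = sp["name"]
        seed = _species_seed(config.seed, i)
        t0 = time.time()
        try:
            results[name] = _run_species(
                name, sp["occurrences"], config, current, scenario_stacks, seed, out, note
            )
        except Exception as exc:  # noqa: BLE001 - per-species isolation is the contract
            note("error", name, message=str(exc))
            results[name] = SpeciesResult(
                name, 0, [], "", float("nan"), pd.DataFrame(), pd.DataFrame(),
                pd.DataFrame(), float("nan"), "", {}, [], [], (), error=str(exc),
            )
        note("done", name, seconds=round(time.time() - t0, 2))

    with open(out / "run_log.json", "w") as fh:
        json.dump(records, fh, indent=1)
    _write_summaries(results, out)
    return RunBundle(chash, results, records)


def _run_species(name, occ_path, config, current, scenario_stacks, seed, out, note):
    from .trend import fit_trend

    raw = occ.read_occurrences(occ_path, name)
    cleaned = occ.clean(raw)
    thinned, report = occ.thin(cleaned, current.grid, seed=seed)
    note("thin", name, **report.__dict__)
    if report.n_retained < config.min_presences:
        raise ValueError(
            f"only {report.n_retained} thinned presences; "
            f"modeling below {config.min_presences} is refused as unreliable"
        )

    matrix, mreport = make_sample_matrix(
        current, thinned, n_background=config.background_size, seed=seed
    )
    note("sample", name, **{k: v for k, v in mreport.items() if k != "dropped_indices"})

    # Pre-modeling contribution run on all candidates ("default parameters"),
    # then Spearman screening on presence rows.
    pre_model = ev.fit_model_for_screening(matrix, config)
    contrib = ev.percent_contribution(pre_model)
    corr = ev.spearman_matrix(matrix.presence())
    missing = [v for v in matrix.variables if v not in set(contrib.get("variable", []))]
    if missing:  # variables with zero accrued gain still enter the screen at 0%
        contrib = pd.concat(
            [contrib, pd.DataFrame({"variable": missing, "percent_contribution": 0.0})],
            ignore_index=True,
        )
    kept, audit = ev.select_variables(
        contrib, corr, r_threshold=config.r_threshold, min_contribution=config.min_contribution
    )
    note("screen", name, kept=kept, excluded=[a for a in audit if a["action"] == "excluded"])
    if not kept:
        raise ValueError("variable screening excluded every candidate")
    matrix = matrix.subset_variables(kept)

    tuning = ev.tune(matrix, fcs=config.fcs, rms=config.rms, seed=seed, **config.fit_kwargs())
    note("tune", name, fc=tuning.selected_fc, rm=tuning.selected_rm)
    fc, rm = tuning.selected_fc, tuning.selected_rm

    jack = ev.jackknife(matrix, fc, rm, seed=seed, **config.fit_kwargs())
    final_contrib = ev.percent_contribution(tuning.selected_model)

    rep_current = ev.replicate_evaluation(
        matrix, fc, rm,
        n_replicates=config.n_replicates, test_fraction=config.test_fraction,
        seed=seed, stack=current.subset(kept), **config.fit_kwargs(),
    )
    note("evaluate", name, mean_auc=round(rep_current.mean_auc, 4), grade=rep_current.grade)

    sp_dir = out / name
    sp_dir.mkdir(exist_ok=True)
    cls_current = ch.classify(current.grid, rep_current.mean_map, config.class_bounds)
    write_ascii_grid(current.grid, rep_current.mean_map, sp_dir / "suitability_current.asc")
    write_ascii_grid(
        current.grid, np.where(cls_current.codes < 0, np.nan, cls_current.codes),
        sp_dir / "classes_current.asc", fmt="%d",
    )
    areas = {"current": ch.class_areas(cls_current)}
    cen_current = ch.centroid(cls_current)
    centroid_rows: List[dict] = []
    changes: List[ch.ChangeSummary] = []
    prev_centroid: Dict[str, Optional[Tuple[float, float]]] = {}
    for sc_label, sstack in scenario_stacks.items():
        scn, period = sc_label.split("_", 1)
        rep = ev.replicate_evaluation(
            matrix, fc, rm,
            n_replicates=config.n_replicates, test_fraction=config.test_fraction,
            seed=seed, stack=sstack.subset(kept), **config.fit_kwargs(),
        )
        cls_fut = ch.classify(current.grid, rep.mean_map, config.class_bounds)
        write_ascii_grid(current.grid, rep.mean_map, sp_dir / f"suitability_{sc_label}.asc")
        areas[sc_label] = ch.class_areas(cls_fut)
        _, _, _, summary = ch.change_map(cls_current, cls_fut, scn, period)
        changes.append(summary)
        cen_fut = ch.centroid(cls_fut)
        if cen_current is not None and cen_fut is not None:
            d1 = ch.centroid_shift(cen_current, cen_fut)
            prev = prev_centroid.get(scn)
            d2 = ch.centroid_shift(prev, cen_fut) if prev is not None else d1
            centroid_rows.append(
                {
                    "scenario": scn, "period": period,
                    "lon": cen_fut[0], "lat": cen_fut[1],
                    "distance1_km": d1.distance_km, "distance2_km": d2.distance_km,
                    "octant": d2.octant,
                }
            )
        prev_centroid[scn] = cen_fut
        note("scenario", name, label=sc_label, gained=summary.gained, lost=summary.lost)

    trends = fit_trend(thinned, split_year=config.trend_split_year)

    tuning.table.to_csv(sp_dir / "tuning.csv", index=False)
    final_contrib.to_csv(sp_dir / "contribution.csv", index=False)
    jack.to_csv(sp_dir / "jackknife.csv", index=False)
    return SpeciesResult(
        species=name,
        n_thinned=report.n_retained,
        kept_variables=kept,
        selected_fc=fc,
        selected_rm=rm,
        tuning_table=tuning.table,
        contribution=final_contrib,
        jackknife=jack,
        mean_auc=rep_current.mean_auc,
        auc_grade=rep_current.grade,
        areas=areas,
        changes=changes,
        centroid_rows=centroid_rows,
        trends=trends,
    )


def _write_summaries(results: Dict[str, SpeciesResult], out: Path) -> None:
    from .trend import trend_table

    area_rows, change_rows, cen_rows, trend_results = [], [], [], []
    for name, r in results.items():
        if r.error:
            continue
        for label, areas in r.areas.items():
            area_rows.append({"species": name, "stack": label, **areas})
        for c in r.changes:
            change_rows.append(
                {
                    "species": name, "scenario": c.scenario, "period": c.period,
                    "gained": round(c.gained, 2), "lost": round(c.lost, 2),
                    "net": round(c.net, 2),
                }
            )
        for row in r.centroid_rows:
            cen_rows.append({"species": name, **row})
        trend_results.extend(r.trends)
    pd.DataFrame(area_rows).to_csv(out / "class_areas.csv", index=False)
    pd.DataFrame(change_rows).to_csv(out / "range_changes.csv", index=False)
    pd.DataFrame(cen_rows).to_csv(out / "centroid_shifts.csv", index=False)
    if trend_results:
        trend_table(trend_results).to_csv(out / "elevation_trends.csv", index=False)
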