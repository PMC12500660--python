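"""Configuration, CSV I/O, and the end-to-end pipeline.

``run_pipeline`` wires the stages in dependency order — cohort (load or
generate), shift-log demand metrics, univariate statistics, candidate GLM
comparison, nonlinear screening + breakpoint, trajectory simulation — and
writes every artifact with a provenance sidecar carrying the full config and
seeds, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import glm as glm_mod
from . import nonlinear, preprocess, simulate, synthetic, workload

log = logging.getLogger("circashift")

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline",
           "load_cohort_csv", "write_cohort_csv", "COHORT_COLUMNS"]

#: Cohort column dictionary (name -> (description, valid range or None)).
COHORT_COLUMNS: dict[str, tuple[str, tuple[float, float] | None]] = {
    "nurse_id": ("unique nurse identifier", None),
    "gender": ("1 = female, 0 = male", (0, 1)),
    "age": ("age in years", (18, 70)),
    "bmi": ("body mass index, kg/m^2", (10, 60)),
    "fr": ("CTI flexible-rigid score", (5, 25)),
    "lv": ("CTI languid-vigorous score", (6, 30)),
    "psqi": ("PSQI total score", (0, 21)),
    "phq9": ("PHQ-9 total score", (0, 27)),
    "night_count": ("4-week total night shift count", (0, 28)),
    "shift_work_hours": ("4-week shift work hours", (0, 400)),
    "shift_workload_exposure": ("4-week shift workload x hours", (0, 10000)),
    "day_workload_exposure": ("4-week day workload x hours", (0, 10000)),
}

CONTINUOUS_VARS = ("age", "bmi", "fr", "lv", "psqi", "phq9", "night_count",
                   "shift_work_hours", "shift_workload_exposure",
                   "day_workload_exposure")


class SchemaError(ValueError):
    """Cohort CSV violates the documented schema."""


def load_cohort_csv(path) -> pd.DataFrame:
    """Schema-validated cohort read (UTF-8 CSV, one row per nurse)."""
    table = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    problems = []
    for name, (_, rng) in COHORT_COLUMNS.items():
        if name == "nurse_id":
            continue
        coerced = pd.to_numeric(table[name], errors="coerce")
        bad = table.index[coerced.isna() & table[name].notna()]
        for i in bad:
            problems.append(f"line {i + 2}: column {name!r} value "
                            f"{table.loc[i, name]!r} is not numeric")
        if rng is not None:
            out = table.index[(coerced < rng[0]) | (coerced > rng[1])]
            for i in out:
                problems.append(f"line {i + 2}: column {name!r} value "
                                f"{coerced[i]} outside {rng}")
        table[name] = coerced
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems[:10]))
    return table


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, encoding="utf-8")


def load_shift_log_csv(path) -> pd.DataFrame:
    events = pd.read_csv(path, encoding="utf-8",
                         parse_dates=["start", "end"])
    required = {"nurse_id", "start", "end", "nap_hours", "unit_id"}
    missing = required - set(events.columns)
    if missing:
        raise SchemaError(f"{path}: missing shift-log columns {sorted(missing)}")
    return events


@dataclass
class PipelineConfig:
    """One YAML-loadable configuration for the whole pipeline.

    Either input CSV paths (``cohort_csv`` etc.) or generator settings are
    used; all thresholds carry their published defaults (PSQI > 7,
    PHQ-9 >= 10, VIF < 5, EDoF flag 1.2, two-tailed 0.05).
    """

    seed: int = 0
    n: int = 288
    outdir: str = "results"
    cohort_csv: str | None = None
    shift_log_csv: str | None = None
    census_csv: str | None = None
    family: str = "poisson"
    use_shift_log_demand: bool = False
    simulate_n_individuals: int = 1000
    simulate_horizon: int = 100
    simulate_alpha: float = 0.2
    demand_multipliers: tuple[float, ...] = (0.25, 1.0, 1.5, 2.0)
    stages: tuple[str, ...] = ("cohort", "demand", "univariate", "glm",
                               "nonlinear", "simulate")
    write_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        for key in ("demand_multipliers", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ResultBundle:
    """In-memory artifacts of one pipeline run."""

    cohort: pd.DataFrame = None
    demand: pd.DataFrame = None
    correlation: preprocess.CorrelationMatrix = None
    recipe: preprocess.TransformRecipe = None
    group_tests: pd.DataFrame = None
    comparisons: dict = field(default_factory=dict)
    selected: dict = field(default_factory=dict)
    gam: dict = field(default_factory=dict)
    breakpoint: nonlinear.BreakpointFit = None
    population: simulate.TrajectorySet = None
    scenarios: dict = field(default_factory=dict)
    scenario_summary: pd.DataFrame = None
    provenance: dict = field(default_factory=dict)


def _stage_seed(base: int, stage: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(base, spawn_key=(stage,))


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the configured stages in dependency order and write artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle()
    bundle.provenance = {"config": dataclasses.asdict(config),
                         "package": "circashift"}

    # ---- cohort ---------------------------------------------------------
    if config.cohort_csv:
        bundle.cohort = load_cohort_csv(config.cohort_csv)
        bundle.provenance["cohort"] = {"source": str(config.cohort_csv)}
        log.info("loaded cohort with %d nurses from %s",
                 len(bundle.cohort), config.cohort_csv)
    else:
        bundle.cohort, prov = synthetic.generate_descriptive(
            n=config.n, seed=config.seed)
        bundle.provenance["cohort"] = prov
        log.info("generated descriptive cohort, n=%d seed=%d", config.n, config.seed)
    write_cohort_csv(bundle.cohort, outdir / "cohort.csv")

    # ---- demand (workload metrics from shift log + census) --------------
    if "demand" in config.stages:
        if config.shift_log_csv:
            events_df = load_shift_log_csv(config.shift_log_csv)
            census = (pd.read_csv(config.census_csv, encoding="utf-8")
                      if config.census_csv else None)
            prov = {"source": str(config.shift_log_csv)}
        else:
            events_df, census, prov = synthetic.generate_shift_log(
                n=len(bundle.cohort), seed=config.seed)
            events_out = events_df.copy()
            events_out["start"] = events_out["start"].map(lambda t: t.isoformat())
            events_out["end"] = events_out["end"].map(lambda t: t.isoformat())
            events_out.to_csv(outdir / "shift_log.csv", index=False, encoding="utf-8")
            census.to_csv(outdir / "census.csv", index=False, encoding="utf-8")
        bundle.provenance["shift_log"] = prov
        curve = workload.fit_npr_curve()
        events = synthetic.events_from_frame(events_df)
        window_start = min(e.start for e in events).replace(
            hour=0, minute=0, second=0, microsecond=0)
        bundle.demand = workload.demand_table(
            events, window_start, census=census, curve=curve)
        excluded = bundle.demand[bundle.demand["shift_workload"].isna()]
        if len(excluded):
            log.warning("%d nurse(s) excluded from work-intensity analysis "
                        "(no census coverage)", len(excluded))
            bundle.provenance["intensity_exclusions"] = list(excluded["nurse_id"])
        bundle.demand.to_csv(outdir / "demand_summary.csv", index=False,
                             encoding="utf-8")
        if config.use_shift_log_demand:
            merged = bundle.cohort.merge(
                bundle.demand[["nurse_id", "night_count", "shift_work_hours",
                               "shift_workload_exposure", "day_workload_exposure"]],
                on="nurse_id", how="left", suffixes=("_gen", ""))
            bundle.cohort = merged.drop(
                columns=[c for c in merged.columns if c.endswith("_gen")])

    # ---- univariate -----------------------------------------------------
    if "univariate" in config.stages:
        bundle.correlation = preprocess.spearman_matrix(
            bundle.cohort, list(CONTINUOUS_VARS))
        bundle.correlation.to_frame().to_csv(
            outdir / "correlation_matrix.csv", index=False, encoding="utf-8")
        tests = []
        for score in ("psqi", "phq9", "fr", "lv"):
            gt = preprocess.group_compare(bundle.cohort[score],
                                          bundle.cohort["gender"])
            tests.append({"score": score, "grouping": "gender",
                          "test": gt.test, "statistic": gt.statistic, "p": gt.p})
        bundle.group_tests = pd.DataFrame(tests)
        bundle.group_tests.to_csv(outdir / "group_tests.csv", index=False,
                                  encoding="utf-8")
        bundle.recipe = preprocess.TransformRecipe.fit(
            bundle.cohort, CONTINUOUS_VARS)
        bundle.recipe.to_json(outdir / "transform_recipe.json")

    # ---- candidate GLMs -------------------------------------------------
    if "glm" in config.stages:
        if bundle.recipe is None:
            bundle.recipe = preprocess.TransformRecipe.fit(
                bundle.cohort, CONTINUOUS_VARS)
        for outcome in ("psqi", "phq9"):
            fits = {}
            for mod_name, spec in glm_mod.candidate_specs(
                    outcome, family=config.family).items():
                X, y = glm_mod.build_design(bundle.cohort, spec, bundle.recipe)
                fits[mod_name] = glm_mod.fit_glm(
                    X, y, family=config.family, spec=spec, recipe=bundle.recipe)
            table, winner = glm_mod.compare_candidates(fits)
            bundle.comparisons[outcome] = table
            bundle.selected[outcome] = fits[winner]
            table.to_csv(outdir / f"glm_comparison_{outcome}.csv",
                         index=False, encoding="utf-8")
            fits[winner].coefficient_table().to_csv(
                outdir / f"glm_coefficients_{outcome}.csv", index=False,
                encoding="utf-8")
            diag = glm_mod.residual_diagnostics(fits[winner])
            diag["residual_vs_fitted"].to_csv(
                outdir / f"glm_residuals_{outcome}.csv", index=False,
                encoding="utf-8")
            diag["qq"].to_csv(outdir / f"glm_qq_{outcome}.csv", index=False,
                              encoding="utf-8")
            log.info("selected %s model for %s (AIC %.2f)", winner, outcome,
                     fits[winner].aic)

    # ---- nonlinear ------------------------------------------------------
    if "nonlinear" in config.stages:
        gam_rows = []
        for outcome in ("psqi", "phq9"):
            smooth = [v for v in ("night_count", "shift_work_hours",
                                  "shift_workload_exposure", "fr", "lv",
                                  "age", "bmi", "day_workload_exposure",
                                  "phq9" if outcome == "psqi" else "psqi")]
            fit = nonlinear.fit_gam(bundle.cohort, outcome, smooth_terms=smooth,
                                    factor_terms=("gender",))
            bundle.gam[outcome] = fit
            sf = fit.summary_frame()
            sf.insert(0, "outcome", outcome)
            gam_rows.append(sf)
        pd.concat(gam_rows).to_csv(outdir / "gam_terms.csv", index=False,
                                   encoding="utf-8")
        bundle.breakpoint = nonlinear.fit_piecewise(
            bundle.cohort["shift_work_hours"], bundle.cohort["psqi"])
        bp = bundle.breakpoint
        pd.DataFrame([{
            "x_var": "shift_work_hours", "outcome": "psqi",
            "breakpoint": bp.breakpoint, "slope_below": bp.slope_below,
            "p_below": bp.p_below, "slope_above": bp.slope_above,
            "p_above": bp.p_above, "sse": bp.sse,
        }]).to_csv(outdir / "breakpoint.csv", index=False, encoding="utf-8")
        grid = np.linspace(bundle.cohort["shift_work_hours"].min(),
                           bundle.cohort["shift_work_hours"].max(), 101)
        pd.DataFrame({"shift_work_hours": grid,
                      "fitted_psqi": bp.predict(grid)}).to_csv(
            outdir / "breakpoint_fitted.csv", index=False, encoding="utf-8")

    # ---- simulation -----------------------------------------------------
    if "simulate" in config.stages:
        if not bundle.selected:
            raise SchemaError("simulate stage requires the glm stage")
        cfg = simulate.SimulationConfig(
            alpha=config.simulate_alpha,
            horizon=config.simulate_horizon,
            n_individuals=config.simulate_n_individuals,
            seed=config.seed,
        )
        bundle.population = simulate.simulate_population(
            bundle.cohort, bundle.selected["psqi"], bundle.selected["phq9"], cfg)
        frames = [bundle.population.to_frame(group="population")]
        bundle.scenarios, bundle.scenario_summary = simulate.scenario_run(
            bundle.cohort, bundle.selected["psqi"], bundle.selected["phq9"],
            cfg, multipliers=config.demand_multipliers)
        for (group, mult), ts in bundle.scenarios.items():
            frames.append(ts.to_frame(group=group, multiplier=mult))
        pd.concat(frames).to_csv(outdir / "trajectories.csv", index=False,
                                 encoding="utf-8")
        bundle.scenario_summary.to_csv(outdir / "scenario_summary.csv",
                                       index=False, encoding="utf-8")
        if config.write_plots:
            simulate.plot_trajectories(
                {"population": bundle.population}, str(outdir / "population.png"))
            simulate.plot_trajectories(
                bundle.scenarios, str(outdir / "scenarios.png"))

    with open(outdir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.provenance, fh, indent=2, default=str)
    return bundle
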