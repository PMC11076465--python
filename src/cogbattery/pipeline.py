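"""End-to-end driver: adjusted scores -> contrasts -> factors -> selection ->
benchmark -> sensitivity, with every table written to the output directory
and a deterministic JSON summary."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import benchmark as bench
from . import sensitivity as sens
from .adjust import AdjustedScoreMatrix, adjust_all
from .catalog import TaskCatalog, default_catalog, load_catalog
from .cohort import CohortTable, load_cohort, validate_cohort
from .config import PipelineConfig
from .contrasts import age_decade_contrast, contrast_table, two_way_anova
from .factors import (
    CompositeScores,
    FactorSolution,
    fit_efa_kaiser,
    global_composite,
    label_factors,
)
from .selection import (
    SelectionReport,
    SelectionRules,
    compute_task_metrics,
    select_battery,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class ReportBundle:
    """In-memory results of a full pipeline run."""

    adjusted: AdjustedScoreMatrix
    contrasts: pd.DataFrame
    anova: object
    age_contrasts: pd.DataFrame
    solution: FactorSolution
    composites: dict
    selection: SelectionReport
    benchmarks: dict
    sensitivity: dict
    summary: dict = field(default_factory=dict)


def _composite_sets(catalog: TaskCatalog, available: list[str]) -> dict:
    acc = [m for m in available if catalog.measure_kind(m) == "accuracy"]
    lat = [m for m in available if catalog.measure_kind(m) == "latency"]
    battery = [
        f"{t}.primary"
        for t in catalog.final_battery_rows.index
        if f"{t}.primary" in available
    ]
    return {"accuracy": acc, "latency": lat, "battery": battery}


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage on the configured cohort + normative CSVs."""
    catalog = (
        load_catalog(config.catalog_csv) if config.catalog_csv else default_catalog()
    )

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:  # noqa: BLE001 - stage name must be attached
            raise PipelineError(name, err) from err

    cohort = stage("load_cohort", load_cohort, config.cohort_csv, catalog)
    normative = stage("load_normative", load_cohort, config.normative_csv, catalog)
    issues = validate_cohort(cohort, catalog)
    logger.info("cohort validation: %d issue records", len(issues))
    bundle = _run_on_tables(cohort, normative, catalog, config, stage)
    outdir = Path(config.output_dir)
    write_bundle(bundle, outdir, config)
    return bundle


def _run_on_tables(cohort: CohortTable, normative: CohortTable,
                   catalog: TaskCatalog, config: PipelineConfig, stage) -> ReportBundle:
    measure_ids = cohort.task_columns(catalog)
    primaries = [m for m in measure_ids if m.endswith(".primary")]

    adjusted = stage(
        "adjust", adjust_all, cohort, catalog,
        measure_ids=measure_ids,
        covariate_columns=config.adjustment.covariates,
        offset=config.adjustment.rank_offset,
        fit_population=config.adjustment.fit_population,
    )
    norm_adjusted = stage(
        "adjust_normative", adjust_all, normative, catalog,
        covariate_columns=config.adjustment.covariates,
        offset=config.adjustment.rank_offset,
    )
    # for decade contrasts age must stay out of the confound set
    norm_noage = stage(
        "adjust_normative_noage", adjust_all, normative, catalog,
        covariate_columns=("sex", "education_band"),
        offset=config.adjustment.rank_offset,
    )

    contrasts = stage(
        "contrasts", contrast_table, adjusted, measure_ids,
        reference=config.contrasts.reference_group,
    )
    long_scores = (
        adjusted.values[primaries]
        .assign(group=adjusted.covariates["group"].astype(str))
        .melt(id_vars="group", var_name="task", value_name="value")
    )
    anova = stage("anova", two_way_anova, long_scores)
    age_rows = []
    for m in primaries:
        for c in stage("age_contrasts", age_decade_contrast, norm_noage, m):
            age_rows.append(vars(c))
    age_contrasts = pd.DataFrame(age_rows)

    solution = stage("factors", fit_efa_kaiser, adjusted, primaries)
    label_factors(solution, catalog)
    sets = _composite_sets(catalog, measure_ids)
    composites: dict[str, CompositeScores] = {}
    for name in ("accuracy", "latency", "battery"):
        acc_ref = [m for m in sets[name] if catalog.measure_kind(m) == "accuracy"]
        composites[name] = stage(
            f"composite_{name}", global_composite, adjusted, sets[name],
            accuracy_measure_ids=acc_ref or None,
        )

    rules = SelectionRules(
        disc_min=config.selection.disc_min,
        dev_max=config.selection.dev_max,
        discreteness_min=config.selection.discreteness_min,
    )
    metrics = stage(
        "task_metrics", compute_task_metrics, catalog, contrasts, norm_adjusted, solution
    )
    selection = stage("selection", select_battery, metrics, catalog, rules)

    battery_scores = adjusted.values[sets["battery"]]
    benchmarks = {}
    for scale in config.benchmark_scales:
        if scale == "mmse" and "mmse_total_baseline" not in cohort.df.columns:
            continue
        if scale == "moca" and "moca_total_assessment" not in cohort.df.columns:
            continue
        benchmarks[scale] = stage(
            f"benchmark_{scale}", bench.benchmark_scale,
            cohort, battery_scores, composites["battery"].scores, scale,
        )

    sensitivity: dict = {}
    cv = {}
    for name in ("accuracy", "latency"):
        cv[name] = {
            "loo": stage(
                "cv", sens.crossvalidate_composite_model,
                composites[name].scores, cohort.df["group"], "loo",
                seed=config.cv.seed,
            ),
            "kfold": stage(
                "cv", sens.crossvalidate_composite_model,
                composites[name].scores, cohort.df["group"], "kfold",
                n_folds=config.cv.folds, seed=config.cv.seed,
            ),
        }
    sensitivity["cv"] = cv
    variants = {}
    for variant in ("one_model", "continuous_age_cubic"):
        table = stage(
            f"variant_{variant}", sens.model_variant_contrasts,
            cohort, catalog, variant, measure_ids,
            reference=config.contrasts.reference_group,
        )
        variants[variant] = {
            "contrasts": table,
            "agreement": sens.variant_agreement(contrasts, table),
        }
    sensitivity["variants"] = variants
    sensitivity["subgroups"] = stage(
        "subgroups", sens.subgroup_contrasts, cohort,
        {k: composites[k].scores for k in ("accuracy", "latency")},
    )
    sensitivity["motor"] = stage(
        "motor", sens.motor_confound_correlation,
        {
            "accuracy_composite": composites["accuracy"].scores,
            "latency_composite": composites["latency"].scores,
            "battery_composite": composites["battery"].scores,
        },
        cohort,
    )

    summary = _summarize(config, cohort, adjusted, contrasts, solution,
                         composites, selection, benchmarks, sensitivity)
    return ReportBundle(
        adjusted=adjusted,
        contrasts=contrasts,
        anova=anova,
        age_contrasts=age_contrasts,
        solution=solution,
        composites=composites,
        selection=selection,
        benchmarks=benchmarks,
        sensitivity=sensitivity,
        summary=summary,
    )


def run_on_cohorts(cohort: CohortTable, normative: CohortTable,
                   config: PipelineConfig | None = None,
                   catalog: TaskCatalog | None = None) -> ReportBundle:
    """Run the full pipeline on in-memory tables (no file I/O)."""
    config = config or PipelineConfig(cohort_csv="-", normative_csv="-")
    catalog = catalog or default_catalog()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:  # noqa: BLE001
            raise PipelineError(name, err) from err

    return _run_on_tables(cohort, normative, catalog, config, stage)


def _composite_gaps(composites: dict, groups: pd.Series) -> dict:
    out = {}
    for name, comp in composites.items():
        joined = pd.concat([comp.scores.rename("c"), groups.rename("g")], axis=1).dropna()
        means = joined.groupby("g", observed=True)["c"].mean()
        for g in ("PD", "RBD"):
            if g in means.index and "control" in means.index:
                out[f"{name}_deficit_{g}"] = float(means["control"] - means[g])
    return out


def _summarize(config, cohort, adjusted, contrasts, solution, composites,
               selection, benchmarks, sensitivity) -> dict:
    groups = cohort.df["group"].astype(str)
    summary = {
        "seed": config.seed,
        "n_participants": int(len(cohort)),
        "n_by_group": {g: int((groups == g).sum()) for g in sorted(groups.unique())},
        "n_measures": len(adjusted.measure_ids),
        "mean_adjustment_r2": float(adjusted.r_squared_table().mean()),
        "max_adjustment_r2": float(adjusted.r_squared_table().max()),
        "n_factors_retained": int(solution.n_factors),
        "factor_labels": list(solution.factor_labels or []),
        "composite_gaps": _composite_gaps(composites, groups),
        "battery": selection.battery,
        "battery_size": len(selection.battery),
        "battery_duration_minutes": selection.battery_duration_minutes,
    }
    for scale, rep in benchmarks.items():
        pd_contrast = next(
            (c for c in rep.scale_group_contrasts if c.contrast == "PD-control"), None
        )
        summary[f"{scale}_r2_from_tasks"] = rep.scale_fit_from_tasks.r_squared
        summary[f"{scale}_composite_r"] = rep.composite_scale_r
        if pd_contrast is not None:
            summary[f"{scale}_pd_smd"] = pd_contrast.smd
    cv = sensitivity.get("cv", {})
    if "accuracy" in cv:
        summary["cv_accuracy_r"] = cv["accuracy"]["kfold"].correlation
        summary["cv_accuracy_mse"] = cv["accuracy"]["kfold"].mse
    return summary


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _dump_json(payload, path) -> None:
    def clean(x):
        if isinstance(x, float):
            return round(x, 10)
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        return x

    with open(path, "w") as fh:
        json.dump(clean(payload), fh, indent=1, sort_keys=True, default=_json_default)


def write_bundle(bundle: ReportBundle, outdir: Path, config: PipelineConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.adjusted.values.round(10).to_csv(outdir / "adjusted.csv")
    models = {
        m: {
            "coefficients": mod.coefficients.round(10).to_dict(),
            "r_squared": round(mod.r_squared, 10),
            "n_fit": mod.n_fit,
            "fit_population": mod.fit_population,
        }
        for m, mod in bundle.adjusted.models.items()
    }
    _dump_json(models, outdir / "adjustment_models.json")
    bundle.contrasts.round(10).to_csv(outdir / "contrasts.csv", index=False)
    bundle.age_contrasts.round(10).to_csv(outdir / "age_contrasts.csv", index=False)
    _dump_json(
        {
            "table": bundle.anova.table.round(10).to_dict(orient="index"),
            "tukey": bundle.anova.tukey.round(10).to_dict(orient="records"),
            "zero_variance": bundle.anova.zero_variance,
        },
        outdir / "anova.json",
    )
    bundle.solution.loadings_frame().round(10).to_csv(outdir / "loadings.csv")
    pd.Series(bundle.solution.eigenvalues, name="eigenvalue").round(10).to_csv(
        outdir / "eigenvalues.csv", index_label="rank"
    )
    if bundle.solution.scores is not None:
        bundle.solution.scores.round(10).to_csv(outdir / "scores.csv")
    comp = pd.DataFrame(
        {name: c.scores for name, c in bundle.composites.items()}
    )
    comp.round(10).to_csv(outdir / "composites.csv")
    bundle.selection.decisions.round(10).to_csv(outdir / "selection_report.csv")
    bundle.selection.to_json(outdir / "selection_report.json")
    _dump_json(
        {scale: rep.to_dict() for scale, rep in bundle.benchmarks.items()},
        outdir / "benchmark_report.json",
    )
    sens_payload = {
        "cv": {
            name: {
                scheme: {
                    "scheme": res.scheme,
                    "n_folds": res.n_folds,
                    "correlation": res.correlation,
                    "mse": res.mse,
                    "seed": res.seed,
                }
                for scheme, res in inner.items()
            }
            for name, inner in bundle.sensitivity["cv"].items()
        },
        "variant_agreement": {
            v: d["agreement"] for v, d in bundle.sensitivity["variants"].items()
        },
        "subgroups": [vars(s) for s in bundle.sensitivity["subgroups"]],
        "motor": bundle.sensitivity["motor"].round(10).to_dict(orient="index"),
    }
    _dump_json(sens_payload, outdir / "sensitivity_report.json")
    _dump_json(bundle.summary, outdir / "summary.json")
    logger.info("wrote pipeline outputs to %s", outdir)
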