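"""Benchmarking the battery against supervised screening scales (MoCA/MMSE).

Convergence: how much scale variance the selected tasks explain (multiple
regression), per-task Pearson correlations with the adjusted scale, and the
battery composite predicted from the scale's categorical subscales.
Divergence: the scale's own group discriminability (typically attenuated by
its ceiling and coarse integer scoring) next to the battery composite's,
and the scale's insensitivity to change over time (paired t-tests).

The scale is adjusted to the same sociodemographic confounds as the task
scores (linear model on age decade, sex, education band; residuals
rank-transformed to normality) before any comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .adjust import (
    DEFAULT_COVARIATES,
    fit_confound_model,
    rank_inverse_normal,
    residualize,
)
from .cohort import CohortTable
from .contrasts import ContrastResult, group_contrast_series

logger = logging.getLogger(__name__)


class BenchmarkError(ValueError):
    pass


@dataclass
class FitRecord:
    r_squared: float
    p_value: float  # overall F-test, two-sided
    coefficients: pd.Series = field(repr=False, default=None)
    n: int = 0


@dataclass
class BenchmarkReport:
    scale: str
    scale_fit_from_tasks: FitRecord
    task_scale_correlations: pd.DataFrame
    composite_fit_from_subscales: FitRecord | None
    scale_group_contrasts: list[ContrastResult]
    composite_group_contrasts: list[ContrastResult]
    composite_scale_r: float
    composite_scale_r_raw: float
    paired_change: pd.DataFrame | None

    def to_dict(self) -> dict:
        out = {
            "scale": self.scale,
            "scale_fit_from_tasks": {
                "r_squared": self.scale_fit_from_tasks.r_squared,
                "p_value": self.scale_fit_from_tasks.p_value,
                "n": self.scale_fit_from_tasks.n,
            },
            "task_scale_correlations": self.task_scale_correlations.round(10).to_dict(
                orient="index"
            ),
            "scale_group_contrasts": [vars(c) for c in self.scale_group_contrasts],
            "composite_group_contrasts": [vars(c) for c in self.composite_group_contrasts],
            "composite_scale_r": self.composite_scale_r,
            "composite_scale_r_raw": self.composite_scale_r_raw,
        }
        if self.composite_fit_from_subscales is not None:
            out["composite_fit_from_subscales"] = {
                "r_squared": self.composite_fit_from_subscales.r_squared,
                "p_value": self.composite_fit_from_subscales.p_value,
                "n": self.composite_fit_from_subscales.n,
            }
        if self.paired_change is not None:
            out["paired_change"] = self.paired_change.round(10).to_dict(orient="index")
        return out


def adjust_scale(cohort: CohortTable, column: str,
                 covariate_columns=DEFAULT_COVARIATES) -> pd.Series:
    """Confound-adjust and rank-normalize a scale column (high = good)."""
    values = pd.to_numeric(cohort.df[column], errors="coerce")
    model = fit_confound_model(values, cohort.df, measure_id=column,
                               columns=covariate_columns)
    return rank_inverse_normal(residualize(model, values, cohort.df))


def predict_scale_from_tasks(
    task_scores: pd.DataFrame,
    scale: pd.Series,
    condition_cap: float = 1e6,
) -> FitRecord:
    """Multiple OLS of the adjusted scale on the selected task scores."""
    joined = task_scores.join(scale.rename("_scale")).dropna()
    n, k = len(joined), task_scores.shape[1]
    if n < k + 2:
        raise BenchmarkError(f"{n} complete cases for {k} predictors; need >= {k + 2}")
    X = sm.add_constant(joined[task_scores.columns])
    cond = np.linalg.cond(X.to_numpy())
    if cond > condition_cap:
        warnings.warn(
            f"predictor condition number {cond:.3g} exceeds cap; "
            "coefficients may be unstable (ridge fallback is off by default)"
        )
    fit = sm.OLS(joined["_scale"], X).fit()
    return FitRecord(
        r_squared=float(fit.rsquared),
        p_value=float(fit.f_pvalue),
        coefficients=fit.params,
        n=n,
    )


def task_scale_correlations(task_scores: pd.DataFrame, scale: pd.Series) -> pd.DataFrame:
    """Pairwise-complete Pearson r (and p) of each measure with the scale."""
    rows = {}
    for m in task_scores.columns:
        pair = pd.concat([task_scores[m], scale], axis=1).dropna()
        if len(pair) < 3:
            warnings.warn(f"measure {m!r} skipped: fewer than 3 paired observations")
            continue
        r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows[m] = {"r": float(r), "p_value": float(p), "n": len(pair)}
    return pd.DataFrame(rows).T


def predict_composite_from_subscales(
    composite: pd.Series,
    subscales: pd.DataFrame,
    min_level_count: int = 2,
) -> FitRecord:
    """OLS of the battery composite on categorical subscale dummies.

    Each subscale's integer scores are treated as categorical levels;
    singleton levels are merged into the nearest observed level (warning).
    """
    joined = subscales.join(composite.rename("_comp")).dropna()
    parts = []
    for col in subscales.columns:
        lev = joined[col].astype(float)
        counts = lev.value_counts()
        rare = counts[counts < min_level_count].index
        if len(rare):
            warnings.warn(f"subscale {col!r}: merging sparse level(s) {sorted(rare)}")
            keep = np.array(sorted(counts[counts >= min_level_count].index))
            if keep.size == 0:
                continue
            lev = lev.map(lambda v: keep[np.argmin(np.abs(keep - v))])
        dummies = pd.get_dummies(lev.astype("category"), prefix=col, drop_first=True)
        parts.append(dummies.astype(float))
    if not parts:
        raise BenchmarkError("no usable subscale levels")
    X = sm.add_constant(pd.concat(parts, axis=1))
    if len(joined) < X.shape[1] + 2:
        raise BenchmarkError("too few complete cases for the subscale design")
    fit = sm.OLS(joined["_comp"], X).fit()
    return FitRecord(
        r_squared=float(fit.rsquared),
        p_value=float(fit.f_pvalue),
        coefficients=fit.params,
        n=len(joined),
    )


def scale_group_discriminability(
    adjusted_scale: pd.Series,
    group_labels: pd.Series,
    scale_name: str = "scale",
    reference: str = "control",
) -> list[ContrastResult]:
    """Group contrasts on the adjusted scale column (SMD in SD units)."""
    return group_contrast_series(
        adjusted_scale, group_labels, measure_id=scale_name, reference=reference
    )


def paired_change_test(
    baseline: pd.Series,
    followup: pd.Series,
    group_labels: pd.Series,
    interval_years: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-group paired t-test of scale change between timepoints."""
    rows = {}
    paired = pd.concat([baseline.rename("b"), followup.rename("f")], axis=1)
    n_dropped = int(paired.isna().any(axis=1).sum())
    if n_dropped:
        logger.info("paired_change_test: dropped %d unpaired rows", n_dropped)
    paired = paired.dropna()
    if len(paired) < 2:
        raise BenchmarkError("fewer than 2 complete pairs")
    for g in group_labels.loc[paired.index].astype(str).unique():
        idx = paired.index[group_labels.loc[paired.index].astype(str) == g]
        if len(idx) < 2:
            continue
        diff = paired.loc[idx, "f"] - paired.loc[idx, "b"]
        if float(diff.std(ddof=1)) == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(paired.loc[idx, "f"], paired.loc[idx, "b"])
        row = {"t": float(t), "p_value": float(p), "n_pairs": int(len(idx)),
               "mean_change": float(diff.mean())}
        if interval_years is not None:
            iv = interval_years.loc[idx].dropna()
            row["mean_interval_years"] = float(iv.mean()) if len(iv) else np.nan
            row["sd_interval_years"] = float(iv.std(ddof=1)) if len(iv) > 1 else np.nan
        rows[g] = row
    return pd.DataFrame(rows).T


def benchmark_scale(
    cohort: CohortTable,
    task_scores: pd.DataFrame,
    composite: pd.Series,
    scale: str = "moca",
    subscale_columns: list[str] | None = None,
) -> BenchmarkReport:
    """Full convergence/divergence report for one scale.

    ``task_scores`` are the adjusted scores of the recommended battery;
    ``composite`` the battery composite (complete cases).  For the MoCA the
    assessment-timepoint total and sections are used, with the baseline
    total providing the change test; the MMSE (baseline only) reuses the
    identical path without a change test.
    """
    if scale == "moca":
        total_col, baseline_col = "moca_total_assessment", "moca_total_baseline"
        if subscale_columns is None:
            subscale_columns = [
                c for c in cohort.df.columns
                if c.startswith("moca_") and c.endswith("_assessment")
                and c != total_col
            ]
    elif scale == "mmse":
        total_col, baseline_col = "mmse_total_baseline", None
        subscale_columns = subscale_columns or []
    else:
        raise BenchmarkError(f"unknown scale {scale!r}")

    adjusted = adjust_scale(cohort, total_col)
    fit_tasks = predict_scale_from_tasks(task_scores, adjusted)
    corr_table = task_scale_correlations(task_scores, adjusted)
    fit_sub = None
    if subscale_columns:
        fit_sub = predict_composite_from_subscales(
            composite, cohort.df[subscale_columns]
        )
    groups = cohort.df["group"]
    scale_contrasts = scale_group_discriminability(adjusted, groups, scale_name=total_col)
    composite_contrasts = group_contrast_series(
        composite, groups.loc[composite.index.intersection(groups.index)],
        measure_id="battery_composite",
    )
    pair = pd.concat([composite.rename("c"), adjusted.rename("s")], axis=1).dropna()
    r_adj = float(np.corrcoef(pair["c"], pair["s"])[0, 1])
    raw = pd.to_numeric(cohort.df[total_col], errors="coerce")
    pair_raw = pd.concat([composite.rename("c"), raw.rename("s")], axis=1).dropna()
    r_raw = float(np.corrcoef(pair_raw["c"], pair_raw["s"])[0, 1])
    change = None
    if baseline_col is not None and baseline_col in cohort.df.columns:
        change = paired_change_test(
            pd.to_numeric(cohort.df[baseline_col], errors="coerce"),
            raw,
            groups,
        )
    return BenchmarkReport(
        scale=scale,
        scale_fit_from_tasks=fit_tasks,
        task_scale_correlations=corr_table,
        composite_fit_from_subscales=fit_sub,
        scale_group_contrasts=scale_contrasts,
        composite_group_contrasts=composite_contrasts,
        composite_scale_r=r_adj,
        composite_scale_r_raw=r_raw,
        paired_change=change,
    )
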