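"""Confound adjustment and normalization of task scores.

Per measure, the pipeline (i) fits an ordinary least squares model of the raw
score on sociodemographic confounds (age decade as categories to allow
non-linear age effects, sex, and education band), (ii) carries the residuals
forward, (iii) rank-transforms them to normality (rank-based inverse normal
transform, Blom offset by default), and (iv) orients every measure so that
high = good.  The resulting participant x measure matrix of unit-variance
normal scores is what every downstream stage (contrasts, factor analysis,
selection, benchmarking) consumes; because the columns are normal scores,
group-mean differences on them read directly as standardized effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import TaskCatalog
from .cohort import AGE_DECADES, EDUCATION_BANDS, SEXES, CohortTable

#: Blom's rank offset, the conventional default for rank-INT
BLOM_OFFSET = 3.0 / 8.0

#: default confound set; age is dropped for the age-decade contrast analysis
DEFAULT_COVARIATES = ("age_decade", "sex", "education_band")

_LEVELS = {
    "age_decade": AGE_DECADES,
    "sex": SEXES,
    "education_band": EDUCATION_BANDS,
}


class AdjustmentError(ValueError):
    pass


def build_design(covariates: pd.DataFrame, columns=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Intercept + treatment-coded dummies with fixed level order.

    The first level of each covariate is the reference.  Raises if a level has
    no observations (the design would be rank deficient), naming the level.
    """
    parts = {"intercept": np.ones(len(covariates))}
    for col in columns:
        levels = _LEVELS[col]
        values = covariates[col].astype(str)
        counts = values.value_counts()
        for lev in levels:
            if counts.get(lev, 0) == 0:
                raise AdjustmentError(
                    f"covariate {col!r} level {lev!r} has no observations; "
                    "design would be rank deficient"
                )
        for lev in levels[1:]:
            parts[f"{col}[{lev}]"] = (values == lev).astype(float).to_numpy()
    return pd.DataFrame(parts, index=covariates.index)


@dataclass
class AdjustmentModel:
    """Fitted per-measure confound model."""

    measure_id: str
    covariate_columns: tuple
    coefficients: pd.Series
    r_squared: float
    n_fit: int
    fit_population: str = "pooled"

    def predict(self, covariates: pd.DataFrame) -> pd.Series:
        X = build_design_for_predict(covariates, self.covariate_columns, self.coefficients.index)
        return pd.Series(X.to_numpy() @ self.coefficients.to_numpy(), index=covariates.index)


def build_design_for_predict(covariates, columns, expected_cols) -> pd.DataFrame:
    """Design matrix for prediction; unseen levels raise by construction.

    Prediction rows must use levels the fixed level sets know about; anything
    else was already rejected when the cohort was typed.
    """
    X = build_design_no_check(covariates, columns)
    X = X.reindex(columns=list(expected_cols))
    if X.isna().any().any():
        raise AdjustmentError("design mismatch between fit and prediction")
    return X


def build_design_no_check(covariates: pd.DataFrame, columns) -> pd.DataFrame:
    parts = {"intercept": np.ones(len(covariates))}
    for col in columns:
        levels = _LEVELS[col]
        values = covariates[col].astype(str)
        unseen = set(values.dropna()) - set(levels)
        if unseen:
            raise AdjustmentError(f"unseen covariate level(s) {sorted(unseen)} in {col!r}")
        for lev in levels[1:]:
            parts[f"{col}[{lev}]"] = (values == lev).astype(float).to_numpy()
    return pd.DataFrame(parts, index=covariates.index)


def fit_confound_model(
    values: pd.Series,
    covariates: pd.DataFrame,
    measure_id: str = "",
    columns=DEFAULT_COVARIATES,
    fit_population: str = "pooled",
) -> AdjustmentModel:
    """OLS of a score on the confound design, fitted on non-missing rows."""
    mask = values.notna()
    if mask.sum() < 2:
        raise AdjustmentError(f"{measure_id}: need >= 2 non-missing values")
    y = values[mask].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise AdjustmentError(f"{measure_id}: all values constant")
    X = build_design(covariates.loc[mask], columns)
    beta, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    fitted = X.to_numpy() @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return AdjustmentModel(
        measure_id=measure_id,
        covariate_columns=tuple(columns),
        coefficients=pd.Series(beta, index=X.columns),
        r_squared=max(0.0, min(1.0, r2)),
        n_fit=int(mask.sum()),
        fit_population=fit_population,
    )


def residualize(model: AdjustmentModel, values: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """Observed minus predicted; missing in -> missing out."""
    pred = model.predict(covariates)
    return values - pred


def rank_inverse_normal(values, offset: float = BLOM_OFFSET):
    """Rank-based inverse normal transform.

    value_i -> Phi^-1((r_i - c) / (n - 2c + 1)) with 1-based ranks r_i, ties
    receiving average ranks, and c the rank offset (Blom's 3/8 by default).
    Missing values are preserved in place.
    """
    arr = pd.Series(values, dtype=float)
    mask = arr.notna()
    n = int(mask.sum())
    if n < 2:
        raise AdjustmentError("rank-INT needs >= 2 non-missing values")
    ranks = stats.rankdata(arr[mask].to_numpy(), method="average")
    quantiles = (ranks - offset) / (n - 2 * offset + 1)
    out = arr.copy()
    out[mask] = stats.norm.ppf(quantiles)
    return out


def orient_scores(values, direction: str):
    """Flip lower_better measures so that high = good everywhere."""
    if direction == "higher_better":
        return values
    if direction == "lower_better":
        return -values
    raise AdjustmentError(f"unknown direction {direction!r}")


@dataclass
class AdjustedScoreMatrix:
    """Participant x measure matrix of oriented, rank-normalized residuals."""

    values: pd.DataFrame = field(repr=False)
    models: dict = field(repr=False)
    covariates: pd.DataFrame = field(repr=False)
    orientation: str = "high_good"

    @property
    def measure_ids(self) -> list[str]:
        return list(self.values.columns)

    def r_squared_table(self) -> pd.Series:
        return pd.Series({m: mod.r_squared for m, mod in self.models.items()}, name="r_squared")

    def complete_cases(self, measure_ids=None) -> pd.Series:
        cols = measure_ids if measure_ids is not None else self.values.columns
        return self.values[cols].notna().all(axis=1)


def adjust_all(
    cohort: CohortTable,
    catalog: TaskCatalog,
    measure_ids: list[str] | None = None,
    covariate_columns=DEFAULT_COVARIATES,
    offset: float = BLOM_OFFSET,
    fit_population: str = "pooled",
) -> AdjustedScoreMatrix:
    """Run fit -> residualize -> rank-INT -> orient for every measure column.

    ``fit_population`` is ``"pooled"`` (default: the whole analysed sample) or
    ``"controls"`` (normative-style fitting on controls only); residuals are
    computed for everyone either way.
    """
    df = cohort.df
    if measure_ids is None:
        measure_ids = cohort.task_columns(catalog)
    fit_mask = (
        (df["group"].astype(str) == "control")
        if fit_population == "controls"
        else pd.Series(True, index=df.index)
    )
    # one shared design for the whole table; per-measure fits subset its rows
    full_design = build_design(df.loc[fit_mask], covariate_columns)
    full_X = full_design.to_numpy()
    level_indicators = {
        (col, lev): (df.loc[fit_mask, col].astype(str) == lev).to_numpy()
        for col in covariate_columns
        for lev in _LEVELS[col]
    }
    predict_X = (
        full_X
        if fit_mask.all()
        else build_design_no_check(df, covariate_columns).to_numpy()
    )
    adjusted = {}
    models = {}
    for m in measure_ids:
        try:
            values = df.loc[fit_mask, m]
            mask = values.notna().to_numpy()
            if mask.sum() < 2:
                raise AdjustmentError("need >= 2 non-missing values")
            y = values.to_numpy(dtype=float)[mask]
            if np.ptp(y) == 0:
                raise AdjustmentError("all values constant")
            if not mask.all():
                for (col, lev), ind in level_indicators.items():
                    if not ind[mask].any():
                        raise AdjustmentError(
                            f"covariate {col!r} level {lev!r} has no observations; "
                            "design would be rank deficient"
                        )
            X = full_X[mask]
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            fitted = X @ beta
            ss_res = float(np.sum((y - fitted) ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            model = AdjustmentModel(
                measure_id=m,
                covariate_columns=tuple(covariate_columns),
                coefficients=pd.Series(beta, index=full_design.columns),
                r_squared=max(0.0, min(1.0, 1.0 - ss_res / ss_tot)),
                n_fit=int(mask.sum()),
                fit_population=fit_population,
            )
            resid = df[m] - predict_X @ beta
            normed = rank_inverse_normal(resid, offset=offset)
            adjusted[m] = orient_scores(normed, catalog.direction(m))
            models[m] = model
        except AdjustmentError as err:
            raise AdjustmentError(f"measure {m!r}: {err}") from err
    out = pd.DataFrame(adjusted, index=df.index)
    covar_cols = ["group", "age_decade", "sex", "education_band"]
    if "device" in df.columns:
        covar_cols.append("device")
    if "probable_rbd" in df.columns:
        covar_cols.append("probable_rbd")
    return AdjustedScoreMatrix(values=out, models=models, covariates=df[covar_cols].copy())
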