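"""Robustness analyses for the group-composite results.

Covers (i) out-of-sample generalization of the group-contrast linear model
via leave-one-out and stratified k-fold cross-validation, (ii) modelling
variants (single-model adjustment, continuous cubic age), (iii) PD
sub-typing by probable RBD (RBDSQ > 6), and (iv) correlations between
cognitive composites and clinically assessed motor severity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .adjust import (
    DEFAULT_COVARIATES,
    AdjustmentError,
    build_design,
    orient_scores,
    rank_inverse_normal,
)
from .catalog import TaskCatalog
from .cohort import CohortTable
from .contrasts import ContrastResult, contrast_table, group_contrast_series

logger = logging.getLogger(__name__)


class SensitivityError(ValueError):
    pass


@dataclass
class CvResult:
    scheme: str  # "loo" or "kfold"
    n_folds: int
    correlation: float  # r(predicted, observed), out of fold
    mse: float
    fold_sizes: list[int]
    seed: int
    predictions: pd.Series = field(repr=False, default=None)


@dataclass
class SubgroupContrast:
    comparison: str
    composite: str  # "accuracy" or "latency"
    smd: float
    se: float
    p_value: float
    n_reference: int
    n_comparison: int


def _group_design(labels: np.ndarray, levels: list[str]) -> np.ndarray:
    X = np.ones((len(labels), len(levels)))
    for j, g in enumerate(levels[1:], start=1):
        X[:, j] = labels == g
    return X


def crossvalidate_composite_model(
    composite: pd.Series,
    group_labels: pd.Series,
    scheme: str = "kfold",
    n_folds: int = 25,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
    max_refolds: int = 5,
) -> CvResult:
    """Out-of-fold prediction of the composite from group (+ covariates).

    The model is the group-contrast linear model (group dummies, optionally
    plus the sociodemographic design).  k-fold folds are stratified by group
    with a recorded seed; leave-one-out is the n-fold special case and needs
    no stratification.  A fold whose training half misses a group level is
    retried with a fresh seed (logged).
    """
    data = pd.concat([composite.rename("y"), group_labels.rename("g")], axis=1).dropna()
    y = data["y"].to_numpy(dtype=float)
    lab = data["g"].astype(str).to_numpy()
    levels = sorted(set(lab))
    X = _group_design(lab, levels)
    if covariates is not None:
        C = build_design(covariates.loc[data.index]).to_numpy()[:, 1:]
        X = np.hstack([X, C])
    n = len(y)
    if scheme == "loo":
        splits = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    elif scheme == "kfold":
        if n < n_folds:
            raise SensitivityError(f"n={n} smaller than n_folds={n_folds}")
        if n_folds == n:
            splits = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
        else:
            for attempt in range(max_refolds):
                kf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                     random_state=seed + attempt)
                splits = list(kf.split(X, lab))
                ok = all(set(lab[tr]) == set(levels) for tr, _ in splits)
                if ok:
                    if attempt:
                        logger.info("refolded %d time(s) to cover all groups", attempt)
                    break
            else:
                raise SensitivityError("could not build folds covering every group")
    else:
        raise SensitivityError(f"unknown scheme {scheme!r}")

    pred = np.empty(n)
    fold_sizes = []
    for train, test in splits:
        beta, *_ = np.linalg.lstsq(X[train], y[train], rcond=None)
        pred[test] = X[test] @ beta
        fold_sizes.append(len(test))
    if np.std(pred) == 0 or np.std(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(pred, y)[0, 1])
    mse = float(np.mean((pred - y) ** 2))
    return CvResult(
        scheme=scheme,
        n_folds=len(splits),
        correlation=r,
        mse=mse,
        fold_sizes=fold_sizes,
        seed=seed,
        predictions=pd.Series(pred, index=data.index, name="predicted"),
    )


def _orthogonal_age_design(df: pd.DataFrame, degree: int = 3) -> pd.DataFrame:
    """Centered, QR-orthogonalized polynomial age design + sex/education."""
    age = df["age_years"].to_numpy(dtype=float)
    centred = age - age.mean()
    raw = np.column_stack([centred**d for d in range(1, degree + 1)])
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    base = build_design(df, columns=("sex", "education_band"))
    out = base.copy()
    for d in range(degree):
        out[f"age_poly{d + 1}"] = q[:, d]
    return out


def _adjust_one_measure(values: pd.Series, design: pd.DataFrame, direction: str) -> pd.Series:
    mask = values.notna()
    if mask.sum() < 2:
        raise AdjustmentError("need >= 2 non-missing values")
    X = design.loc[mask].to_numpy(dtype=float)
    y = values[mask].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = values.copy()
    resid[mask] = y - X @ beta
    return orient_scores(rank_inverse_normal(resid), direction)


def model_variant_contrasts(
    cohort: CohortTable,
    catalog: TaskCatalog,
    variant: str,
    measure_ids: list[str] | None = None,
    reference: str = "control",
) -> pd.DataFrame:
    """Group contrasts under a modelling variant.

    ``two_step``: the primary pipeline (confound OLS -> rank-INT -> group
    model).  ``one_model``: rank-INT of the raw score, then one OLS with
    group and sociodemographic terms together; the group coefficients are
    the contrasts.  ``continuous_age_cubic``: two-step, with age entered as
    a centered orthogonalized cubic instead of decade categories.
    """
    from .adjust import adjust_all  # deferred: avoids import-order clutter

    df = cohort.df
    if measure_ids is None:
        measure_ids = cohort.task_columns(catalog)
    if variant == "two_step":
        adjusted = adjust_all(cohort, catalog, measure_ids=measure_ids)
        return contrast_table(adjusted, measure_ids, reference=reference)
    if variant == "continuous_age_cubic":
        design = _orthogonal_age_design(df)
        rows = []
        for m in measure_ids:
            adj = _adjust_one_measure(df[m], design, catalog.direction(m))
            for c in group_contrast_series(adj, df["group"], measure_id=m,
                                           reference=reference):
                rows.append(vars(c))
        return pd.DataFrame(rows)
    if variant == "one_model":
        design = build_design(df, columns=DEFAULT_COVARIATES)
        rows = []
        groups = sorted(df["group"].astype(str).unique())
        others = [g for g in groups if g != reference]
        for m in measure_ids:
            normed = orient_scores(rank_inverse_normal(df[m]), catalog.direction(m))
            mask = normed.notna()
            y = normed[mask].to_numpy(dtype=float)
            lab = df.loc[mask, "group"].astype(str).to_numpy()
            G = np.column_stack([(lab == g).astype(float) for g in others])
            X = np.hstack([design.loc[mask].to_numpy(dtype=float), G])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dof = len(y) - X.shape[1]
            sigma2 = float(resid @ resid) / dof
            xtx_inv = np.linalg.pinv(X.T @ X)
            for j, g in enumerate(others):
                col = X.shape[1] - len(others) + j
                se = float(np.sqrt(sigma2 * xtx_inv[col, col]))
                coef = float(beta[col])
                p = 2.0 * stats.t.sf(abs(coef / se), dof) if se > 0 else 1.0
                rows.append(
                    {
                        "measure_id": m,
                        "contrast": f"{g}-{reference}",
                        "smd": coef,
                        "se": se,
                        "p_value": float(p),
                        "n_reference": int(np.sum(lab == reference)),
                        "n_comparison": int(np.sum(lab == g)),
                    }
                )
        return pd.DataFrame(rows)
    raise SensitivityError(f"unknown variant {variant!r}")


def variant_agreement(primary: pd.DataFrame, variant: pd.DataFrame) -> dict:
    """Max |delta SMD| and sign-agreement rate between two contrast tables."""
    merged = primary.merge(
        variant, on=["measure_id", "contrast"], suffixes=("_a", "_b")
    )
    if merged.empty:
        raise SensitivityError("no overlapping contrasts to compare")
    delta = (merged["smd_a"] - merged["smd_b"]).abs()
    signs = np.sign(merged["smd_a"]) == np.sign(merged["smd_b"])
    return {
        "max_abs_delta_smd": float(delta.max()),
        "mean_abs_delta_smd": float(delta.mean()),
        "sign_agreement": float(signs.mean()),
        "n_contrasts": int(len(merged)),
    }


def subgroup_contrasts(
    cohort: CohortTable,
    composites: dict,
) -> list[SubgroupContrast]:
    """PD split by probable RBD (RBDSQ > 6): the three comparison families.

    ``composites`` maps "accuracy"/"latency" to complete-case composite
    series.  Comparisons: PD+RBD vs PD-RBD, PD+RBD vs idiopathic RBD, and
    each patient subgroup vs controls.  Empty subgroups are skipped with a
    warning.
    """
    df = cohort.df
    if "probable_rbd" not in df.columns:
        raise SensitivityError("cohort lacks probable_rbd (no RBDSQ column?)")
    group = df["group"].astype(str)
    sub = pd.Series("control", index=df.index)
    sub[group == "RBD"] = "iRBD"
    sub[(group == "PD") & df["probable_rbd"]] = "PD+RBD"
    sub[(group == "PD") & ~df["probable_rbd"].astype(bool)] = "PD-RBD"

    comparisons = [
        ("PD+RBD vs PD-RBD", "PD-RBD", "PD+RBD"),
        ("PD+RBD vs iRBD", "iRBD", "PD+RBD"),
        ("PD+RBD vs control", "control", "PD+RBD"),
        ("PD-RBD vs control", "control", "PD-RBD"),
        ("iRBD vs control", "control", "iRBD"),
    ]
    out = []
    for name, comp in composites.items():
        lab = sub.loc[comp.index.intersection(sub.index)]
        for label, ref, other in comparisons:
            n_ref = int((lab == ref).sum())
            n_oth = int((lab == other).sum())
            if n_ref < 2 or n_oth < 2:
                warnings.warn(f"{label}: subgroup empty or too small; skipped")
                continue
            res = group_contrast_series(
                comp.loc[lab.index[lab.isin([ref, other])]],
                lab[lab.isin([ref, other])],
                measure_id=name,
                reference=ref,
                groups=(ref, other),
            )[0]
            out.append(
                SubgroupContrast(
                    comparison=label,
                    composite=name,
                    smd=res.smd,
                    se=res.se,
                    p_value=res.p_value,
                    n_reference=res.n_reference,
                    n_comparison=res.n_comparison,
                )
            )
    return out


def fingertap_hand_composite(cohort: CohortTable,
                             items=("updrs3_fingertap", "updrs3_handmovement")) -> pd.Series:
    """Standardized mean of the finger-tapping / hand-movement sub-items."""
    z = []
    for item in items:
        v = pd.to_numeric(cohort.df[item], errors="coerce")
        z.append((v - v.mean()) / v.std(ddof=1))
    return pd.concat(z, axis=1).mean(axis=1)


def motor_confound_correlation(
    composites: dict,
    cohort: CohortTable,
    group: str = "PD",
) -> pd.DataFrame:
    """Pearson r of each composite with UPDRS-III and the tapping composite.

    Computed on the rows of one clinical group (PD by default), where motor
    severity varies meaningfully.
    """
    mask = cohort.df["group"].astype(str) == group
    motor = {
        "updrs3": pd.to_numeric(cohort.df.loc[mask, "updrs3"], errors="coerce"),
        "fingertap_hand": fingertap_hand_composite(cohort).loc[mask],
    }
    rows = {}
    for cname, comp in composites.items():
        for mname, mval in motor.items():
            pair = pd.concat([comp, mval], axis=1, join="inner").dropna()
            if len(pair) < 3:
                raise SensitivityError(
                    f"fewer than 3 paired observations for {cname} vs {mname}"
                )
            r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows[f"{cname}~{mname}"] = {"r": float(r), "p_value": float(p), "n": len(pair)}
    return pd.DataFrame(rows).T
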