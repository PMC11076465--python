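"""Group and age-decade contrasts, omnibus ANOVA, and effect-size labelling.

Contrasts are OLS coefficients of group (or age-decade) dummies fitted to
adjusted scores.  Because adjusted scores are unit-variance normal scores,
those coefficients are standardized mean differences (SMDs) in SD units,
with the sign convention that negative = worse than the reference group
(scores are oriented high = good upstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .adjust import AdjustedScoreMatrix

#: Sawilowsky's extension of Cohen's effect-size bins (threshold -> label)
SAWILOWSKY_BINS = (
    (2.0, "huge"),
    (1.2, "very large"),
    (0.8, "large"),
    (0.5, "medium"),
    (0.2, "small"),
    (0.1, "very small"),
)


class ContrastError(ValueError):
    pass


@dataclass
class ContrastResult:
    measure_id: str
    contrast: str  # e.g. "PD-control", "60s-50s"
    smd: float
    se: float
    p_value: float
    n_reference: int
    n_comparison: int


@dataclass
class AnovaResult:
    """Two-way (group x task) ANOVA with Type-II sums of squares."""

    table: pd.DataFrame  # index: group, task, group:task, residual
    tukey: pd.DataFrame  # pairwise group comparisons on marginal means
    zero_variance: bool = False


@dataclass
class EffectSizeLabel:
    smd: float
    label: str


def _dummy_ols_contrasts(y: np.ndarray, labels: np.ndarray, levels: list[str], reference: str):
    """OLS of y on treatment dummies; returns per-level (coef, se, p, n)."""
    others = [g for g in levels if g != reference]
    X = np.ones((len(y), 1 + len(others)))
    for j, g in enumerate(others):
        X[:, 1 + j] = labels == g
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    if dof <= 0:
        raise ContrastError("not enough observations for the group model")
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    out = {}
    for j, g in enumerate(others):
        coef = float(beta[1 + j])
        se = float(np.sqrt(sigma2 * xtx_inv[1 + j, 1 + j]))
        if se == 0.0:
            p = 1.0 if coef == 0.0 else 0.0
        else:
            t = coef / se
            p = 2.0 * stats.t.sf(abs(t), dof)
        out[g] = (coef, se, float(p))
    return out


def group_contrast_series(
    values: pd.Series,
    group_labels: pd.Series,
    measure_id: str = "",
    reference: str = "control",
    groups: tuple = ("control", "PD", "RBD"),
) -> list[ContrastResult]:
    """Group contrasts for a standalone score column (e.g. an adjusted scale)."""
    mask = values.notna()
    y = values[mask].to_numpy(dtype=float)
    lab = group_labels[mask].astype(str).to_numpy()
    absent = [g for g in groups if g not in set(lab)]
    if absent:
        raise ContrastError(f"group(s) {absent} absent for {measure_id!r}")
    fits = _dummy_ols_contrasts(y, lab, list(groups), reference)
    n_ref = int(np.sum(lab == reference))
    return [
        ContrastResult(
            measure_id=measure_id,
            contrast=f"{g}-{reference}",
            smd=coef,
            se=se,
            p_value=p,
            n_reference=n_ref,
            n_comparison=int(np.sum(lab == g)),
        )
        for g, (coef, se, p) in fits.items()
    ]


def group_contrast(
    adjusted: AdjustedScoreMatrix,
    measure_id: str,
    reference: str = "control",
    groups: tuple = ("control", "PD", "RBD"),
) -> list[ContrastResult]:
    """SMD of each non-reference group vs the reference on one measure."""
    return group_contrast_series(
        adjusted.values[measure_id],
        adjusted.covariates["group"],
        measure_id=measure_id,
        reference=reference,
        groups=groups,
    )


def contrast_table(
    adjusted: AdjustedScoreMatrix,
    measure_ids=None,
    reference: str = "control",
    groups: tuple = ("control", "PD", "RBD"),
) -> pd.DataFrame:
    """All group contrasts for many measures, as a tidy frame."""
    rows = []
    for m in measure_ids if measure_ids is not None else adjusted.measure_ids:
        for c in group_contrast(adjusted, m, reference=reference, groups=groups):
            rows.append(vars(c))
    return pd.DataFrame(rows)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    # normal equations with pinv of the Gram matrix: dummy designs are small
    # in columns but tall in rows, so this beats an SVD of X itself
    g = X.T @ X
    xty = X.T @ y
    beta = np.linalg.pinv(g) @ xty
    return float(y @ y - beta @ xty)


def two_way_anova(long_scores: pd.DataFrame) -> AnovaResult:
    """Type-II two-way ANOVA of value on group, task and their interaction.

    ``long_scores`` needs columns participant, group, task, value (stacked
    adjusted scores).  Unbalanced designs are fine; an empty group x task
    cell is an error.  Tukey HSD is applied to the group marginal means, the
    post-hoc the omnibus effect is interrogated with.
    """
    d = long_scores.dropna(subset=["value"])
    groups = sorted(d["group"].astype(str).unique())
    tasks = sorted(d["task"].astype(str).unique())
    if len(groups) < 2 or len(tasks) < 2:
        raise ContrastError("need >= 2 groups and >= 2 tasks")
    counts = d.groupby(["group", "task"], observed=True).size()
    empty = [
        (g, t) for g in groups for t in tasks if counts.get((g, t), 0) == 0
    ]
    if empty:
        raise ContrastError(f"empty group x task cells: {empty}")

    y = d["value"].to_numpy(dtype=float)
    g_dum = pd.get_dummies(pd.Categorical(d["group"], categories=groups), drop_first=True)
    t_dum = pd.get_dummies(pd.Categorical(d["task"], categories=tasks), drop_first=True)
    G = g_dum.to_numpy(dtype=float)
    T = t_dum.to_numpy(dtype=float)
    inter = np.einsum("ij,ik->ijk", G, T).reshape(len(y), -1)
    ones = np.ones((len(y), 1))

    rss_full = _rss(np.hstack([ones, G, T, inter]), y)
    rss_gt = _rss(np.hstack([ones, G, T]), y)
    rss_g = _rss(np.hstack([ones, G]), y)
    rss_t = _rss(np.hstack([ones, T]), y)

    df_g = len(groups) - 1
    df_t = len(tasks) - 1
    df_i = df_g * df_t
    df_resid = len(y) - (1 + df_g + df_t + df_i)
    # Type II: each main effect adjusted for the other, ignoring the interaction
    ss = {
        "group": max(0.0, rss_t - rss_gt),
        "task": max(0.0, rss_g - rss_gt),
        "group:task": max(0.0, rss_gt - rss_full),
    }
    mse = rss_full / df_resid if df_resid > 0 else np.nan
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    zero_variance = not np.isfinite(mse) or ss_tot <= 1e-12 or mse <= 1e-12 * ss_tot
    rows = []
    for term, dof in (("group", df_g), ("task", df_t), ("group:task", df_i)):
        if zero_variance:
            f, p = 0.0, 1.0
        else:
            f = (ss[term] / dof) / mse
            p = float(stats.f.sf(f, dof, df_resid))
        rows.append({"term": term, "sum_sq": ss[term], "df": dof, "F": f, "p_value": p})
    rows.append(
        {"term": "residual", "sum_sq": rss_full, "df": df_resid, "F": np.nan, "p_value": np.nan}
    )
    table = pd.DataFrame(rows).set_index("term")

    if zero_variance:
        pairs = []
        for i, a in enumerate(groups):
            for b in groups[i + 1 :]:
                pairs.append({"group1": a, "group2": b, "meandiff": 0.0, "p_adj": 1.0})
        tukey = pd.DataFrame(pairs)
    else:
        res = pairwise_tukeyhsd(d["value"].to_numpy(dtype=float), d["group"].astype(str).to_numpy())
        uniq = list(res.groupsunique)
        pairs = [
            (uniq[i], uniq[j]) for i in range(len(uniq)) for j in range(i + 1, len(uniq))
        ]
        tukey = pd.DataFrame(
            {
                "group1": [a for a, _ in pairs],
                "group2": [b for _, b in pairs],
                "meandiff": np.asarray(res.meandiffs, dtype=float),
                "p_adj": np.clip(np.asarray(res.pvalues, dtype=float), 0.0, 1.0),
            }
        )
    return AnovaResult(table=table, tukey=tukey, zero_variance=zero_variance)


def age_decade_contrast(
    adjusted: AdjustedScoreMatrix, measure_id: str, reference: str = "50s"
) -> list[ContrastResult]:
    """Decade contrasts (60s/70s/80s vs 50s) on normative adjusted scores.

    The adjustment feeding this analysis must leave age out of the confound
    set (sex and education only), since age is the predictor of interest.
    """
    values = adjusted.values[measure_id]
    decades = adjusted.covariates["age_decade"].astype(str)
    mask = values.notna()
    present = set(decades[mask])
    missing = [d for d in ("50s", "60s", "70s", "80s") if d not in present]
    if missing:
        raise ContrastError(f"age decade(s) {missing} missing for {measure_id!r}")
    fits = _dummy_ols_contrasts(
        values[mask].to_numpy(dtype=float),
        decades[mask].to_numpy(),
        ["50s", "60s", "70s", "80s"],
        reference,
    )
    n_ref = int(np.sum(decades[mask] == reference))
    return [
        ContrastResult(
            measure_id=measure_id,
            contrast=f"{dec}-{reference}",
            smd=coef,
            se=se,
            p_value=p,
            n_reference=n_ref,
            n_comparison=int(np.sum(decades[mask] == dec)),
        )
        for dec, (coef, se, p) in fits.items()
    ]


def effect_size_label(smd: float) -> EffectSizeLabel:
    """Sawilowsky bin for |SMD|; thresholds are inclusive upward."""
    if not np.isfinite(smd):
        raise ContrastError("SMD must be finite")
    mag = abs(smd)
    for threshold, label in SAWILOWSKY_BINS:
        if mag >= threshold:
            return EffectSizeLabel(smd=smd, label=label)
    return EffectSizeLabel(smd=smd, label="negligible")
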