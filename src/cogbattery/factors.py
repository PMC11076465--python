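"""Exploratory factor analysis: extraction, varimax rotation, composites.

Extraction is principal-axis factoring with iterated communalities (the
common default in the psychometric literature), factor count by the Kaiser
convention (correlation-matrix eigenvalues > 1), rotation by varimax with
Kaiser row normalization, and factor scores by the regression (Thurstone)
method.  Global performance composites are scores on a single unrotated
factor fitted to participants with complete data on the contributing
measures.

Rotation is implemented as Kaiser's planar algorithm: repeated sweeps of
2-column rotations, each maximizing the varimax criterion exactly in its
plane, until no plane can improve it.  That makes the stationarity property
(no single planar rotation can improve the criterion) hold by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjust import AdjustedScoreMatrix


class FactorError(ValueError):
    pass


class HeywoodWarning(UserWarning):
    """A communality exceeded 1 during extraction and was clipped."""


@dataclass
class FactorSolution:
    measure_ids: list[str]
    corr: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray = field(repr=False)
    n_factors: int = 0
    loadings_unrotated: np.ndarray = field(default=None, repr=False)
    loadings: np.ndarray = field(default=None, repr=False)  # rotated (or = unrotated)
    rotation_matrix: np.ndarray = field(default=None, repr=False)
    communalities: np.ndarray = field(default=None, repr=False)
    scores: pd.DataFrame = field(default=None, repr=False)
    rotation: str = "none"
    n_iter: int = 0
    factor_labels: list[str] | None = None

    def loadings_frame(self) -> pd.DataFrame:
        cols = self.factor_labels or [f"F{k + 1}" for k in range(self.n_factors)]
        return pd.DataFrame(self.loadings, index=self.measure_ids, columns=cols)


@dataclass
class CompositeScores:
    """Standardized single-factor scores for complete-case participants."""

    scores: pd.Series = field(repr=False)
    measure_ids: list[str] = field(default_factory=list)
    method: str = "paf_one_factor_regression"
    loadings: pd.Series = field(default=None, repr=False)


def correlation_matrix(adjusted: AdjustedScoreMatrix, measure_ids=None) -> pd.DataFrame:
    """Pearson correlations on complete cases across the measure subset."""
    cols = list(measure_ids) if measure_ids is not None else adjusted.measure_ids
    data = adjusted.values[cols].dropna()
    if len(data) < 3:
        raise FactorError(f"only {len(data)} complete cases; need >= 3")
    corr = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    return pd.DataFrame(corr, index=cols, columns=cols)


def kaiser_n_factors(eigenvalues) -> int:
    """Number of eigenvalues strictly greater than 1."""
    return int(np.sum(np.asarray(eigenvalues, dtype=float) > 1.0))


def _smc(corr: np.ndarray) -> np.ndarray:
    """Squared multiple correlations as starting communalities."""
    try:
        inv = np.linalg.inv(corr)
        smc = 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        smc = np.full(corr.shape[0], 0.5)
    return np.clip(smc, 0.0, 0.995)


def _paf(corr: np.ndarray, n_factors: int, max_iter: int = 1000, tol: float = 1e-3,
         heywood_clip: float = 0.995):
    """Principal-axis factoring with iterated communalities."""
    p = corr.shape[0]
    if n_factors >= p:
        raise FactorError(f"n_factors ({n_factors}) must be < n_measures ({p})")
    h2 = _smc(corr)
    loadings = None
    for it in range(1, max_iter + 1):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h2)
        vals, vecs = np.linalg.eigh(reduced)
        order = np.argsort(vals)[::-1][:n_factors]
        lam = np.clip(vals[order], 0.0, None)
        loadings = vecs[:, order] * np.sqrt(lam)
        new_h2 = np.sum(loadings**2, axis=1)
        if np.any(new_h2 > 1.0):
            warnings.warn(
                "Heywood case: communality > 1 clipped during extraction",
                HeywoodWarning,
                stacklevel=3,
            )
            new_h2 = np.clip(new_h2, 0.0, heywood_clip)
        delta = float(np.max(np.abs(new_h2 - h2)))
        h2 = new_h2
        if delta < tol:
            return loadings, h2, it
    # communalities near the Heywood boundary can oscillate indefinitely;
    # accept the stalled solution when the residual change is already small
    if delta < 1e-2:
        warnings.warn(
            f"principal-axis factoring stopped after {max_iter} iterations "
            f"with communality change {delta:.2e}",
            stacklevel=3,
        )
        return loadings, h2, max_iter
    raise FactorError(f"principal-axis factoring did not converge in {max_iter} iterations")


def varimax_criterion(loadings: np.ndarray) -> float:
    """Sum over factors of the variance of squared loadings."""
    sq = loadings**2
    return float(np.sum(sq.var(axis=0)))


def _varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
             tol: float = 1e-10, max_sweeps: int = 200):
    """Kaiser's pairwise varimax; returns rotated loadings and rotation matrix."""
    L = loadings.copy()
    p, k = L.shape
    if kaiser_normalize:
        norms = np.sqrt(np.sum(L**2, axis=1))
        norms[norms == 0] = 1.0
        L = L / norms[:, None]
    R = np.eye(k)
    for _ in range(max_sweeps):
        max_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                # closed-form optimal planar angle for the varimax criterion
                num = 2.0 * (p * np.dot(u, v) - u.sum() * v.sum())
                den = p * (np.dot(u, u) - np.dot(v, v)) - (u.sum() ** 2 - v.sum() ** 2)
                if num == 0.0 and den == 0.0:
                    continue
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < tol:
                    continue
                max_angle = max(max_angle, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                L[:, [i, j]] = L[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
        if max_angle < tol:
            break
    if kaiser_normalize:
        L = L * norms[:, None]
    return L, R


def _fix_signs(loadings: np.ndarray, rotation_matrix: np.ndarray | None = None):
    """Flip factor signs so each column's largest-|loading| entry is positive."""
    flips = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            flips[j] = -1.0
    L = loadings * flips
    R = rotation_matrix * flips if rotation_matrix is not None else None
    return L, R


def _regression_scores(data: pd.DataFrame, corr: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Thurstone regression factor scores from standardized data."""
    Z = data.to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
    weights, *_ = np.linalg.lstsq(corr, loadings, rcond=None)  # pinv: tolerates
    return Z @ weights  # duplicated / collinear measure sets


def fit_efa(
    corr: pd.DataFrame,
    n_factors: int,
    rotation: str = "varimax",
    data: pd.DataFrame | None = None,
    max_iter: int = 1000,
) -> FactorSolution:
    """Fit an EFA to a correlation matrix (optionally scoring ``data``).

    ``data`` must be the complete-case frame the correlation matrix came
    from, with the same column order; when given, regression factor scores
    are attached to the solution.
    """
    measure_ids = list(corr.columns)
    C = corr.to_numpy(dtype=float)
    if not np.allclose(C, C.T, atol=1e-10):
        raise FactorError("correlation matrix must be symmetric")
    eigenvalues = np.sort(np.linalg.eigvalsh(C))[::-1]
    loadings_unrot, h2, n_iter = _paf(C, n_factors, max_iter=max_iter)
    if rotation == "varimax" and n_factors > 1:
        loadings, R = _varimax(loadings_unrot)
    elif rotation in ("none", "varimax"):
        loadings, R = loadings_unrot.copy(), np.eye(n_factors)
    else:
        raise FactorError(f"unknown rotation {rotation!r}")
    loadings, R = _fix_signs(loadings, R)
    scores = None
    if data is not None:
        raw = _regression_scores(data[measure_ids], C, loadings)
        scores = pd.DataFrame(
            raw, index=data.index, columns=[f"F{k + 1}" for k in range(n_factors)]
        )
    return FactorSolution(
        measure_ids=measure_ids,
        corr=C,
        eigenvalues=eigenvalues,
        n_factors=n_factors,
        loadings_unrotated=loadings_unrot,
        loadings=loadings,
        rotation_matrix=R,
        communalities=np.sum(loadings**2, axis=1),
        scores=scores,
        rotation=rotation if n_factors > 1 else "none",
        n_iter=n_iter,
    )


def fit_efa_kaiser(adjusted: AdjustedScoreMatrix, measure_ids=None,
                   rotation: str = "varimax") -> FactorSolution:
    """Correlation matrix -> Kaiser retention -> EFA, on complete cases."""
    corr = correlation_matrix(adjusted, measure_ids)
    data = adjusted.values[list(corr.columns)].dropna()
    n = kaiser_n_factors(np.linalg.eigvalsh(corr.to_numpy()))
    if n < 1:
        raise FactorError("Kaiser rule retained no factors")
    return fit_efa(corr, n, rotation=rotation, data=data)


def global_composite(
    adjusted: AdjustedScoreMatrix,
    measure_ids: list[str],
    accuracy_measure_ids: list[str] | None = None,
) -> CompositeScores:
    """One-unrotated-factor composite over a measure subset (complete cases).

    Scores are standardized (mean 0, SD 1 on the scored subset) and
    sign-fixed so the mean loading over ``accuracy_measure_ids`` (all
    measures when not given) is positive, keeping high = good.
    """
    data = adjusted.values[list(measure_ids)].dropna()
    if len(data) < len(measure_ids) + 1:
        raise FactorError(
            f"{len(data)} complete cases for {len(measure_ids)} measures; need more"
        )
    corr = pd.DataFrame(
        np.corrcoef(data.to_numpy(dtype=float), rowvar=False),
        index=measure_ids,
        columns=measure_ids,
    )
    sol = fit_efa(corr, 1, rotation="none", data=data)
    loadings = sol.loadings[:, 0]
    ref = accuracy_measure_ids if accuracy_measure_ids else list(measure_ids)
    ref_idx = [list(measure_ids).index(m) for m in ref if m in measure_ids]
    sign = 1.0 if float(np.mean(loadings[ref_idx])) >= 0 else -1.0
    raw = sol.scores.iloc[:, 0] * sign
    standardized = (raw - raw.mean()) / raw.std(ddof=1)
    return CompositeScores(
        scores=standardized,
        measure_ids=list(measure_ids),
        loadings=pd.Series(loadings * sign, index=measure_ids),
    )


def dominant_factor(solution: FactorSolution, measure_id: str) -> tuple[int, float]:
    """(0-based dominant factor index, |top| - |second| loading gap)."""
    i = solution.measure_ids.index(measure_id)
    row = np.abs(solution.loadings[i])
    order = np.argsort(row)[::-1]
    top = int(order[0])
    gap = float(row[order[0]] - row[order[1]]) if len(row) > 1 else float(row[order[0]])
    return top, gap


def label_factors(solution: FactorSolution, catalog) -> list[str]:
    """Assign domain labels post hoc: each factor takes the catalog domain
    of its highest-loading task; duplicated labels get a numeric suffix."""
    labels = []
    for j in range(solution.n_factors):
        col = np.abs(solution.loadings[:, j])
        top_measure = solution.measure_ids[int(np.argmax(col))]
        task = catalog.task_of(top_measure)
        lab = str(catalog.table.loc[task, "domain"])
        if lab in labels:
            lab = f"{lab}_{labels.count(lab) + 1}"
        labels.append(lab)
    solution.factor_labels = labels
    return labels


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient (cosine) between two loading columns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def align_factors(estimated: np.ndarray, target: np.ndarray):
    """Greedily match estimated factor columns to target columns.

    Resolves column permutation and sign indeterminacy by maximal absolute
    congruence.  Returns (aligned estimated matrix, per-target congruences).
    """
    k = target.shape[1]
    if estimated.shape[1] < k:
        raise FactorError("estimated solution has fewer factors than the target")
    cong = np.array(
        [
            [tucker_congruence(estimated[:, i], target[:, j]) for j in range(k)]
            for i in range(estimated.shape[1])
        ]
    )
    aligned = np.zeros_like(target)
    congruences = np.zeros(k)
    used_rows: set[int] = set()
    used_cols: set[int] = set()
    for _ in range(k):
        masked = np.abs(cong).copy()
        if used_rows:
            masked[list(used_rows), :] = -np.inf
        if used_cols:
            masked[:, list(used_cols)] = -np.inf
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        sign = 1.0 if cong[i, j] >= 0 else -1.0
        aligned[:, j] = estimated[:, i] * sign
        congruences[j] = abs(cong[i, j])
        used_rows.add(int(i))
        used_cols.add(int(j))
    return aligned, congruences
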