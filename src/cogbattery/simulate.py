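"""Synthetic cohorts with the latent structure the analysis pipeline assumes.

The generator emulates a three-group observational study (healthy controls,
early-mid Parkinson's disease, isolated REM sleep behaviour disorder) that
completed a 19-task online cognitive battery, plus a large device-diverse
normative sample spanning ages 50-89.

The measurement model is a five-factor model (executive, visuospatial /
attention, short-term memory, word knowledge, motor reaction time) with
simple-structure loadings, positively intercorrelated factors (the positive
manifold of cognitive abilities), and uniqueness chosen so every measure has
unit variance before group, confound and device shifts.  Group deficits are
shifts of latent factor means in SD units: the default is a uniform global
accuracy deficit (PD -0.65, RBD -0.45) and a latency deficit (PD -0.61, RBD
-0.20, sub-threshold).  Sociodemographic confounds enter as additive
per-measure offsets derived from factor-level coefficient tables -- notably
a positive age trend for word knowledge, so vocabulary measures improve
through the decades while fluid measures decline.  Device offsets are
additive per measure; a few tasks (simple reaction time, motor control,
picture completion) are markedly phone-sensitive, mirroring the kind of
tasks a device-robustness screen should reject.

Supervised scales (MoCA, MMSE) are generated as coarse integer instruments:
per-section error counts are Poisson with a rate that decays with the
relevant latent ability, subtracted from the section maximum.  This builds
in the ceiling, discretization and limited reliability that make such scales
insensitive to subtle group deficits even though they correlate with the
battery.

Every generated table is accompanied by a :class:`SyntheticTruth` capturing
the realized parameters and per-participant latent scores, so recovery tests
can compare pipeline estimates against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import TaskCatalog, default_catalog
from .cohort import AGE_DECADES, DEVICES, EDUCATION_BANDS, GROUPS, CohortTable

FACTORS = (
    "executive",
    "visuospatial_attention",
    "short_term_memory",
    "word_knowledge",
    "motor_rt",
)
ACCURACY_FACTORS = FACTORS[:4]

#: within-group correlation between latent factors (positive manifold);
#: chosen so that factor-level deficits and the measured one-factor global
#: composite deficit coincide (see docs/methods.md)
DEFAULT_FACTOR_CORR = 0.10

#: scale <- latent coupling for the Poisson error model of MoCA/MMSE
DEFAULT_SCALE_COUPLING = 0.65

_PRIMARY_LOADINGS = {
    # task_id: {factor: loading}
    "motor_control": {"motor_rt": 0.72},
    "recognition_memory_immediate": {"short_term_memory": 0.75},
    "target_detection": {"visuospatial_attention": 0.62, "executive": 0.18},
    "emotional_discrimination": {"visuospatial_attention": 0.68},
    "manipulations_2d": {"visuospatial_attention": 0.70},
    "digit_span": {"short_term_memory": 0.65},
    "spatial_span": {"short_term_memory": 0.50, "visuospatial_attention": 0.30},
    "blocks": {"executive": 0.55, "visuospatial_attention": 0.28},
    "tower_of_london": {"executive": 0.50},
    "word_definitions": {"word_knowledge": 0.84},
    "recognition_memory_delayed": {"short_term_memory": 0.72},
    "srt": {"motor_rt": 0.78},
    "trail_making": {"executive": 0.30, "motor_rt": 0.58},
    "paired_associate_learning": {"short_term_memory": 0.42, "executive": 0.40},
    "switching_stroop": {"executive": 0.75},
    "picture_completion": {"visuospatial_attention": 0.60},
    "card_pairs": {"short_term_memory": 0.45},
    "scene_rotation_3d": {"visuospatial_attention": 0.72},
    "verbal_analogies": {"word_knowledge": 0.68, "executive": 0.20},
}

#: secondary (response latency) measures: shared motor loading plus a weak
#: echo of the task's dominant accuracy factor
_SECONDARY_MOTOR_LOADING = 0.55
_SECONDARY_TASK_LOADING = 0.25

_AGE_FACTOR_EFFECTS = {
    # factor: offsets for (50s, 60s, 70s, 80s), high = good
    "executive": (0.0, -0.35, -0.80, -1.30),
    "visuospatial_attention": (0.0, -0.30, -0.70, -1.15),
    "short_term_memory": (0.0, -0.40, -0.85, -1.35),
    "word_knowledge": (0.0, 0.15, 0.25, 0.30),
    "motor_rt": (0.0, -0.45, -1.00, -1.70),
}

_SEX_FACTOR_EFFECTS = {  # male minus female, latent SD units
    "executive": 0.0,
    "visuospatial_attention": 0.10,
    "short_term_memory": -0.10,
    "word_knowledge": 0.0,
    "motor_rt": 0.05,
}

_EDUCATION_BAND_OFFSETS = {"none": -0.25, "<5y": -0.10, "5-10y": 0.0, ">10y": 0.12}
_EDUCATION_FACTOR_WEIGHTS = {
    "executive": 0.5,
    "visuospatial_attention": 0.4,
    "short_term_memory": 0.4,
    "word_knowledge": 1.0,
    "motor_rt": 0.2,
}

_PHONE_OFFSETS = {
    # per primary measure, high-good scale; negative = worse on a phone
    "srt.primary": -0.45,
    "motor_control.primary": -0.40,
    "picture_completion.primary": -0.32,
    "trail_making.primary": -0.12,
    "target_detection.primary": -0.08,
    "blocks.primary": -0.06,
}
_PHONE_OFFSET_DEFAULT_PRIMARY = -0.03
_PHONE_OFFSET_DEFAULT_SECONDARY = -0.08
_TABLET_SCALE = 0.4  # tablet offsets are a fraction of phone offsets

_MOCA_SECTIONS = (
    # (name, max score, Poisson error rate, factor mix)
    ("visuospatial_executive", 5, 0.35, {"executive": 0.5, "visuospatial_attention": 0.5}),
    ("naming", 3, 0.30, {"word_knowledge": 1.0}),
    ("attention", 6, 0.30, {"visuospatial_attention": 0.7, "executive": 0.3}),
    ("language", 3, 0.50, {"word_knowledge": 0.8, "executive": 0.2}),
    ("abstraction", 2, 0.20, {"word_knowledge": 0.5, "executive": 0.5}),
    ("delayed_recall", 5, 0.55, {"short_term_memory": 1.0}),
    ("orientation", 6, 0.08, {f: 0.25 for f in ACCURACY_FACTORS}),
)
_MMSE_LAMBDA = 1.3

#: per-measure extra group deficits (high=good scale) beyond the uniform
#: factor-mean shifts: the battery tasks discriminate the patient groups at
#: the task level (medium-plus effects), the remaining candidates only via
#: the shared factor shifts -- mirroring the published per-task profile
#: (memory/vocabulary deficits in both groups; attention/executive deficits
#: mainly in PD).  The composite calibration absorbs these, so the global
#: composite deficits still equal the configured values.
_MEASURE_EXTRA_EFFECTS = {
    # measure: (PD extra, RBD extra)
    "recognition_memory_immediate.primary": (-0.42, -0.33),
    "recognition_memory_delayed.primary": (-0.40, -0.30),
    "word_definitions.primary": (-0.45, -0.35),
    "verbal_analogies.primary": (-0.40, -0.32),
    "switching_stroop.primary": (-0.38, -0.12),
    "target_detection.primary": (-0.40, -0.12),
    "trail_making.primary": (-0.38, -0.15),
    "blocks.primary": (-0.35, -0.10),
    "emotional_discrimination.primary": (-0.36, -0.10),
}

_AGE_DISTRIBUTIONS = {  # mean, SD of age at cognitive assessment
    "control": (72.8, 8.4),
    "PD": (66.0, 8.6),
    "RBD": (68.7, 8.8),
}
_FEMALE_FRACTION = {"control": 0.42, "PD": 0.48, "RBD": 0.11}
_EDUCATION_PROBS = (0.05, 0.30, 0.40, 0.25)


class GeneratorError(ValueError):
    pass


def default_loadings(catalog: TaskCatalog | None = None) -> pd.DataFrame:
    """Measure x factor loading matrix for all primary and secondary scores."""
    catalog = catalog or default_catalog()
    rows = {}
    for task_id in catalog.task_ids:
        load = dict.fromkeys(FACTORS, 0.0)
        load.update(_PRIMARY_LOADINGS[task_id])
        rows[f"{task_id}.primary"] = load
        if catalog.table.loc[task_id, "has_secondary"]:
            spec = _PRIMARY_LOADINGS[task_id]
            dominant = max(
                (f for f in spec if f != "motor_rt"), key=lambda f: spec[f], default=None
            )
            sec = dict.fromkeys(FACTORS, 0.0)
            sec["motor_rt"] = _SECONDARY_MOTOR_LOADING
            if dominant is not None:
                sec[dominant] = _SECONDARY_TASK_LOADING
            rows[f"{task_id}.secondary"] = sec
    return pd.DataFrame(rows).T[list(FACTORS)]


def default_device_offsets(loadings: pd.DataFrame) -> pd.DataFrame:
    phone = {}
    for m in loadings.index:
        if m in _PHONE_OFFSETS:
            phone[m] = _PHONE_OFFSETS[m]
        elif m.endswith(".secondary"):
            phone[m] = _PHONE_OFFSET_DEFAULT_SECONDARY
        else:
            phone[m] = _PHONE_OFFSET_DEFAULT_PRIMARY
    out = pd.DataFrame(index=loadings.index)
    out["computer"] = 0.0
    out["tablet"] = pd.Series(phone) * _TABLET_SCALE
    out["phone"] = pd.Series(phone)
    return out


def default_measure_extra_effects(loadings: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(0.0, index=loadings.index, columns=["PD", "RBD"])
    for m, (pd_x, rbd_x) in _MEASURE_EXTRA_EFFECTS.items():
        if m in out.index:
            out.loc[m, "PD"] = pd_x
            out.loc[m, "RBD"] = rbd_x
    return out


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_control: int = 50
    n_pd: int = 59
    n_rbd: int = 54
    n_per_decade: int = 1250  # normative sample
    factor_corr: float = DEFAULT_FACTOR_CORR
    loadings: pd.DataFrame = field(default=None, repr=False)
    pd_accuracy_effect: float = -0.65
    rbd_accuracy_effect: float = -0.45
    pd_latency_effect: float = -0.61
    rbd_latency_effect: float = -0.20
    prbd_fraction: float = 0.25  # probable-RBD fraction within PD
    prbd_extra_accuracy: float = -0.06
    prbd_extra_latency: float = -0.55
    age_decade_factor_effects: dict = field(default_factory=lambda: dict(_AGE_FACTOR_EFFECTS))
    age_decade_measure_offsets: pd.DataFrame | None = field(default=None, repr=False)
    sex_factor_effects: dict = field(default_factory=lambda: dict(_SEX_FACTOR_EFFECTS))
    education_band_offsets: dict = field(default_factory=lambda: dict(_EDUCATION_BAND_OFFSETS))
    education_factor_weights: dict = field(default_factory=lambda: dict(_EDUCATION_FACTOR_WEIGHTS))
    device_offsets: pd.DataFrame | None = field(default=None, repr=False)
    device_proportions_cohort: tuple = (0.80, 0.15, 0.05)
    device_proportions_normative: tuple = (0.45, 0.20, 0.35)
    missingness: float | dict = 0.004  # per task measure
    scale_coupling: float = DEFAULT_SCALE_COUPLING
    #: "composite": group effects are deficits of the measured one-factor
    #: global composites, and the generator solves for the uniform
    #: factor-mean shifts realizing them; "factor": effects are applied to
    #: factor means as given.
    effect_scale: str = "composite"
    moca_inclusion_cutoff: int | None = None  # e.g. 24 to emulate recruitment
    updrs3_motor_slope: float = 4.0
    updrs3_noise_sd: float = 9.0
    emit_raw_latency_ms: bool = False
    #: per-measure additive group deficits beyond the factor shifts
    #: (DataFrame: measure x {PD, RBD}); None selects the packaged defaults
    measure_extra_effects: pd.DataFrame | None = field(default=None, repr=False)
    catalog: TaskCatalog = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.catalog is None:
            self.catalog = default_catalog()
        if self.loadings is None:
            self.loadings = default_loadings(self.catalog)
        if self.device_offsets is None:
            self.device_offsets = default_device_offsets(self.loadings)
        if self.measure_extra_effects is None:
            self.measure_extra_effects = default_measure_extra_effects(self.loadings)
        else:
            self.measure_extra_effects = self.measure_extra_effects.reindex(
                index=self.loadings.index, columns=["PD", "RBD"]
            ).fillna(0.0)
        for n, name in ((self.n_control, "control"), (self.n_pd, "PD"), (self.n_rbd, "RBD")):
            if n < 2:
                raise GeneratorError(f"need n >= 2 per group; got {n} for {name}")
        if not (0.0 <= self.factor_corr < 1.0):
            raise GeneratorError("factor_corr must be in [0, 1)")
        psi = self.uniquenesses()
        if (psi <= 0).any() or (psi > 1).any():
            bad = psi[(psi <= 0) | (psi > 1)].index.tolist()
            raise GeneratorError(
                f"implied uniqueness outside (0, 1] for {bad}; "
                "measure variance would not be positive definite"
            )

    # -- derived structure -------------------------------------------------

    def factor_cov(self) -> np.ndarray:
        k = len(FACTORS)
        phi = np.full((k, k), self.factor_corr)
        np.fill_diagonal(phi, 1.0)
        return phi

    def uniquenesses(self) -> pd.Series:
        L = self.loadings.to_numpy(dtype=float)
        h2 = np.einsum("ij,jk,ik->i", L, self.factor_cov(), L)
        return pd.Series(1.0 - h2, index=self.loadings.index, name="psi")

    def group_factor_effects(self) -> pd.DataFrame:
        """Per-group factor-mean shifts (SD units), after calibration.

        With ``effect_scale="composite"`` the configured effects are deficits
        of the measured global composites and the returned factor shifts are
        the solution of :func:`calibrate_factor_shifts`; with ``"factor"``
        the configured effects are the factor shifts themselves.
        """
        if self.effect_scale == "composite":
            shifts = calibrate_factor_shifts(self)
        elif self.effect_scale == "factor":
            shifts = {
                ("PD", "accuracy"): self.pd_accuracy_effect,
                ("RBD", "accuracy"): self.rbd_accuracy_effect,
                ("PD", "latency"): self.pd_latency_effect,
                ("RBD", "latency"): self.rbd_latency_effect,
            }
        else:
            raise GeneratorError(f"unknown effect_scale {self.effect_scale!r}")
        eff = pd.DataFrame(0.0, index=list(GROUPS), columns=list(FACTORS))
        eff.loc["PD", list(ACCURACY_FACTORS)] = shifts[("PD", "accuracy")]
        eff.loc["RBD", list(ACCURACY_FACTORS)] = shifts[("RBD", "accuracy")]
        eff.loc["PD", "motor_rt"] = shifts[("PD", "latency")]
        eff.loc["RBD", "motor_rt"] = shifts[("RBD", "latency")]
        return eff

    def measure_confound_offsets(self) -> dict:
        """Per-measure additive offsets for age decade, sex (male) and education."""
        L = self.loadings
        age = pd.DataFrame(
            {
                dec: sum(
                    L[f] * self.age_decade_factor_effects[f][i] for f in FACTORS
                )
                for i, dec in enumerate(AGE_DECADES)
            }
        )
        if self.age_decade_measure_offsets is not None:
            override = self.age_decade_measure_offsets
            age.loc[override.index, override.columns] = override
        sex_male = sum(L[f] * self.sex_factor_effects[f] for f in FACTORS)
        edu = pd.DataFrame(
            {
                band: sum(
                    L[f] * self.education_factor_weights[f] * self.education_band_offsets[band]
                    for f in FACTORS
                )
                for band in EDUCATION_BANDS
            }
        )
        return {"age": age, "sex_male": sex_male, "education": edu}

    def missingness_rates(self) -> pd.Series:
        if isinstance(self.missingness, dict):
            rates = pd.Series(self.missingness).reindex(self.loadings.index).fillna(0.0)
        else:
            rates = pd.Series(float(self.missingness), index=self.loadings.index)
        if ((rates < 0) | (rates > 1)).any():
            raise GeneratorError("missingness rates must be in [0, 1]")
        return rates


def _decade_probs(group: str) -> np.ndarray:
    """P(age decade | group) under the truncated-normal age model."""
    from scipy.stats import norm

    mean, sd = _AGE_DISTRIBUTIONS[group]
    cdf = norm(mean, sd).cdf
    p = np.array([cdf(60), cdf(70) - cdf(60), cdf(80) - cdf(70), 1 - cdf(80)])
    return p / p.sum()


def _population_composite_gap(cfg: GeneratorConfig, measure_ids: list[str],
                              subpop_weights: np.ndarray,
                              subpop_factor_means: np.ndarray,
                              return_weights: bool = False) -> np.ndarray:
    """Asymptotic (population) composite means per subpopulation.

    Mirrors what the pipeline estimates at n -> infinity: pooled confound
    regression (whose covariates correlate with group membership, so part of
    the group separation is absorbed -- the residual-confounding attenuation
    inherent to two-step adjustment), residual correlation, one-factor
    principal-axis extraction, regression scores standardized on the pooled
    sample.  Computed by exact enumeration over subpopulation x age decade x
    sex x education cells; device offsets enter as group-independent
    variance.  The rank-INT step is variance-standardizing and near-linear
    at these separations, so it is absorbed by the correlation
    standardization.
    """
    from .factors import _paf  # local import to keep module layers acyclic

    L = cfg.loadings.loc[measure_ids].to_numpy(dtype=float)
    psi = cfg.uniquenesses().loc[measure_ids].to_numpy()
    phi = cfg.factor_cov()
    sigma_w = L @ phi @ L.T + np.diag(psi)
    delta = subpop_factor_means @ L.T  # subpop x measure group shifts
    subpop_groups = ("control", "PD", "PD", "RBD")
    extras = cfg.measure_extra_effects.loc[measure_ids]
    for s_idx, g in enumerate(subpop_groups):
        if g in extras.columns:
            delta[s_idx] += extras[g].to_numpy()

    # enumerate (subpop, decade, sex, education) cells: probability and the
    # confound design vector (decade dummies 60s/70s/80s, male, edu dummies)
    n_x = 3 + 1 + 3
    probs, xs, sp_idx = [], [], []
    for s, g in enumerate(subpop_groups):
        p_dec = _decade_probs(g)
        p_f = _FEMALE_FRACTION[g]
        for d in range(4):
            for sex_male, p_sex in ((1.0, 1 - p_f), (0.0, p_f)):
                for e in range(4):
                    x = np.zeros(n_x)
                    if d > 0:
                        x[d - 1] = 1.0
                    x[3] = sex_male
                    if e > 0:
                        x[3 + e] = 1.0
                    probs.append(subpop_weights[s] * p_dec[d] * p_sex * _EDUCATION_PROBS[e])
                    xs.append(x)
                    sp_idx.append(s)
    p = np.array(probs)
    X = np.array(xs)
    sp_idx = np.array(sp_idx)
    x_bar = p @ X
    Xc = X - x_bar
    V = (Xc.T * p) @ Xc
    D = delta[sp_idx]  # cell x measure
    d_bar = p @ D
    Dc = D - d_bar
    C = (Xc.T * p) @ Dc  # Cov(x, group shift)
    b = np.linalg.solve(V, C)  # leakage coefficients per measure

    # residual means per subpopulation and residual covariance
    resid_cells = Dc - Xc @ b
    r_means = np.zeros((len(subpop_weights), len(measure_ids)))
    for s in range(len(subpop_weights)):
        m = sp_idx == s
        w_s = p[m].sum()
        r_means[s] = (p[m] @ resid_cells[m]) / w_s if w_s > 0 else 0.0
    between = (resid_cells.T * p) @ resid_cells
    dev = cfg.device_offsets.loc[measure_ids].to_numpy(dtype=float)
    p_dev = np.asarray(cfg.device_proportions_cohort)
    dev_mean = dev @ p_dev
    dev_c = dev - dev_mean[:, None]
    cov_dev = (dev_c * p_dev) @ dev_c.T
    sigma_r = sigma_w + between + cov_dev

    d_sd = np.sqrt(np.diag(sigma_r))
    corr = sigma_r / np.outer(d_sd, d_sd)
    if len(measure_ids) == 1:  # degenerate composite: the measure itself
        v = np.ones(1)
        if return_weights:
            return v / d_sd
        return (r_means / d_sd) @ v
    loadings, _, _ = _paf(corr, 1)
    lam = loadings[:, 0]
    if lam.mean() < 0:
        lam = -lam
    v = np.linalg.solve(corr, lam)
    scale = float(np.sqrt(v @ corr @ v))
    if return_weights:
        return v / d_sd / scale
    return (r_means / d_sd) @ v / scale


def _default_subpops(cfg: GeneratorConfig):
    """(weights, factor means) of the four subpopulations under the config."""
    n_total = cfg.n_control + cfg.n_pd + cfg.n_rbd
    fr = cfg.prbd_fraction
    weights = np.array(
        [cfg.n_control, cfg.n_pd * (1 - fr), cfg.n_pd * fr, cfg.n_rbd], dtype=float
    ) / n_total
    eff = cfg.group_factor_effects()
    mu = np.zeros((4, len(FACTORS)))
    mu[1] = eff.loc["PD"].to_numpy()
    mu[2] = eff.loc["PD"].to_numpy()
    acc_idx = [FACTORS.index(f) for f in ACCURACY_FACTORS]
    mu[2, acc_idx] += cfg.prbd_extra_accuracy
    mu[2, FACTORS.index("motor_rt")] += cfg.prbd_extra_latency
    mu[3] = eff.loc["RBD"].to_numpy()
    return weights, mu


def population_measure_gaps(cfg: GeneratorConfig, measure_ids: list[str]) -> pd.DataFrame:
    """Asymptotic per-measure control-minus-group gaps after adjustment.

    What `group_contrast` estimates at n -> infinity: residual group-mean
    differences in pooled-SD units, including the residual-confounding
    attenuation of the two-step model.  Used as the round-trip oracle.
    """
    weights, mu = _default_subpops(cfg)
    out = {}
    for m in measure_ids:
        cm = _population_composite_gap(cfg, [m], weights, mu)
        pd_mean = (weights[1] * cm[1] + weights[2] * cm[2]) / (weights[1] + weights[2])
        out[m] = {"PD": cm[0] - pd_mean, "RBD": cm[0] - cm[3]}
    return pd.DataFrame(out).T


def latent_global_composite(cfg: GeneratorConfig, measure_ids: list[str],
                            factor_scores: pd.DataFrame,
                            group_labels: pd.Series | None = None) -> pd.Series:
    """Population counterpart of the estimated one-factor composite.

    Projects each participant's systematic measure values (latent factor
    scores through the loadings, plus the group's task-specific deficits
    when ``group_labels`` is given) through the asymptotic composite
    weights -- the quantity the pipeline's composite estimates up to
    measurement noise.  Used by recovery tests.
    """
    weights, mu = _default_subpops(cfg)
    w = _population_composite_gap(cfg, measure_ids, weights, mu, return_weights=True)
    L = cfg.loadings.loc[measure_ids].to_numpy(dtype=float)
    systematic = factor_scores[list(FACTORS)].to_numpy(dtype=float) @ L.T
    if group_labels is not None:
        extras = cfg.measure_extra_effects.loc[measure_ids]
        for g in ("PD", "RBD"):
            rows = (group_labels.astype(str) == g).to_numpy()
            if rows.any():
                systematic[rows] += extras[g].to_numpy()
    values = systematic @ w
    return pd.Series(values, index=factor_scores.index, name="latent_composite")


def null_generator_config(structure: bool = True, confounds: bool = False,
                          devices: bool = False, **overrides) -> GeneratorConfig:
    """A generator with every group-level effect switched off.

    ``structure=False`` additionally removes the factor loadings (pure-noise
    measures); ``confounds``/``devices`` keep the sociodemographic and
    device offsets when True.
    """
    base = GeneratorConfig()
    zero_extras = base.measure_extra_effects * 0.0
    kwargs: dict = dict(
        effect_scale="factor",
        pd_accuracy_effect=0.0, rbd_accuracy_effect=0.0,
        pd_latency_effect=0.0, rbd_latency_effect=0.0,
        prbd_extra_accuracy=0.0, prbd_extra_latency=0.0,
        measure_extra_effects=zero_extras,
    )
    if not structure:
        kwargs["loadings"] = base.loadings * 0.0
    if not confounds:
        kwargs.update(
            age_decade_factor_effects={f: (0, 0, 0, 0) for f in FACTORS},
            sex_factor_effects={f: 0.0 for f in FACTORS},
            education_band_offsets={b: 0.0 for b in EDUCATION_BANDS},
        )
    kwargs.update(overrides)
    cfg = GeneratorConfig(**kwargs)
    if not devices:
        cfg.device_offsets.loc[:, :] = 0.0
    return cfg


def calibrate_factor_shifts(cfg: GeneratorConfig, tol: float = 1e-9,
                            max_iter: int = 60) -> dict:
    """Solve for uniform factor-mean shifts realizing composite-level effects.

    The configured group effects are deficits of the measured global
    accuracy / latency composites.  Because one-factor scores aggregate
    separation across factors, a factor-mean shift of x produces a composite
    gap larger than x; this fixed point inverts that map so that the
    pipeline's composite estimates converge to the configured values.
    """
    cached = getattr(cfg, "_shift_cache", None)
    key = (
        cfg.pd_accuracy_effect, cfg.rbd_accuracy_effect,
        cfg.pd_latency_effect, cfg.rbd_latency_effect,
        cfg.factor_corr, cfg.prbd_fraction,
        cfg.prbd_extra_accuracy, cfg.prbd_extra_latency,
        cfg.n_control, cfg.n_pd, cfg.n_rbd,
        cfg.measure_extra_effects.to_numpy().tobytes(),
        cfg.loadings.to_numpy().tobytes(),
    )
    if cached is not None and cached[0] == key:
        return cached[1]
    cat = cfg.catalog
    acc_measures = [
        m for m in cfg.loadings.index
        if m.endswith(".primary") and cat.measure_kind(m) == "accuracy"
    ]
    lat_measures = [m for m in cfg.loadings.index if cat.measure_kind(m) == "latency"]
    targets = {
        ("PD", "accuracy"): -cfg.pd_accuracy_effect,
        ("RBD", "accuracy"): -cfg.rbd_accuracy_effect,
        ("PD", "latency"): -cfg.pd_latency_effect,
        ("RBD", "latency"): -cfg.rbd_latency_effect,
    }
    if not acc_measures or not lat_measures:
        raise GeneratorError(
            "composite-scale effects need both accuracy and latency measures; "
            'use effect_scale="factor" for custom measure sets'
        )
    n_total = cfg.n_control + cfg.n_pd + cfg.n_rbd
    fr = cfg.prbd_fraction
    weights = np.array(
        [cfg.n_control, cfg.n_pd * (1 - fr), cfg.n_pd * fr, cfg.n_rbd], dtype=float
    ) / n_total
    acc_idx = [FACTORS.index(f) for f in ACCURACY_FACTORS]
    mot_idx = FACTORS.index("motor_rt")

    shifts = {k: -t for k, t in targets.items()}  # start at the targets

    def subpop_means(s):
        mu = np.zeros((4, len(FACTORS)))  # control, PD-, PD+, RBD
        for row in (1, 2):
            mu[row, acc_idx] = s[("PD", "accuracy")]
            mu[row, mot_idx] = s[("PD", "latency")]
        mu[2, acc_idx] += cfg.prbd_extra_accuracy
        mu[2, mot_idx] += cfg.prbd_extra_latency
        mu[3, acc_idx] = s[("RBD", "accuracy")]
        mu[3, mot_idx] = s[("RBD", "latency")]
        return mu

    def gaps(s):
        mu = subpop_means(s)
        out = {}
        for domain, measures in (("accuracy", acc_measures), ("latency", lat_measures)):
            cm = _population_composite_gap(cfg, measures, weights, mu)
            pd_mean = (weights[1] * cm[1] + weights[2] * cm[2]) / (weights[1] + weights[2])
            out[("PD", domain)] = cm[0] - pd_mean
            out[("RBD", domain)] = cm[0] - cm[3]
        return out

    if all(abs(t) < 1e-12 for t in targets.values()) and (
        abs(cfg.prbd_extra_accuracy) < 1e-12
        and abs(cfg.prbd_extra_latency) < 1e-12
        and float(cfg.measure_extra_effects.abs().to_numpy().max()) < 1e-12
    ):
        result = dict.fromkeys(targets, 0.0)
    else:
        for _ in range(max_iter):
            g = gaps(shifts)
            err = 0.0
            for k, t in targets.items():
                if abs(t) < 1e-12:
                    shifts[k] = 0.0
                    continue
                err = max(err, abs(g[k] - t))
                if abs(g[k]) > 1e-12:
                    shifts[k] = shifts[k] * t / g[k]
            if err < tol:
                break
        result = shifts
    cfg._shift_cache = (key, dict(result))
    return dict(result)


@dataclass
class SyntheticTruth:
    """Realized generator parameters plus per-participant latent scores."""

    seed: int
    factor_corr: float
    loadings: pd.DataFrame = field(repr=False)
    uniquenesses: pd.Series = field(repr=False)
    group_factor_effects: pd.DataFrame = field(repr=False)
    confound_offsets: dict = field(repr=False)
    device_offsets: pd.DataFrame = field(repr=False)
    factor_scores: pd.DataFrame = field(repr=False)
    config: GeneratorConfig = field(repr=False, default=None)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "factor_corr": self.factor_corr,
            "loadings": self.loadings.round(10).to_dict(),
            "uniquenesses": self.uniquenesses.round(10).to_dict(),
            "group_factor_effects": self.group_factor_effects.round(10).to_dict(),
            "device_offsets": self.device_offsets.round(10).to_dict(),
            "factor_scores": self.factor_scores.round(10).to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _draw_demographics(rng, group: str, n: int) -> pd.DataFrame:
    mean, sd = _AGE_DISTRIBUTIONS[group]
    age = np.clip(rng.normal(mean, sd, size=n), 50.0, 89.0).round(1)
    sex = np.where(rng.random(n) < _FEMALE_FRACTION[group], "female", "male")
    edu = rng.choice(EDUCATION_BANDS, size=n, p=_EDUCATION_PROBS)
    return pd.DataFrame({"group": group, "age_years": age, "sex": sex, "education_band": edu})


def _decade_index(age_years: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(age_years / 10).astype(int) - 5, 0, 3)


def _measures_from_latents(cfg: GeneratorConfig, rng, demo: pd.DataFrame,
                           f: np.ndarray) -> pd.DataFrame:
    """Measurement model: loadings x latents + confounds + device + noise."""
    L = cfg.loadings.to_numpy(dtype=float)
    psi = cfg.uniquenesses().to_numpy()
    offsets = cfg.measure_confound_offsets()
    n = len(demo)
    y = f @ L.T
    dec_idx = _decade_index(demo["age_years"].to_numpy())
    y += offsets["age"].to_numpy()[:, dec_idx].T.reshape(n, -1)
    y += np.outer((demo["sex"].to_numpy() == "male").astype(float), offsets["sex_male"])
    edu_mat = offsets["education"].to_numpy()
    band_idx = np.array([EDUCATION_BANDS.index(b) for b in demo["education_band"]])
    y += edu_mat[:, band_idx].T.reshape(n, -1)
    dev = cfg.device_offsets
    dev_idx = np.array([list(dev.columns).index(d) for d in demo["device"]])
    y += dev.to_numpy()[:, dev_idx].T.reshape(n, -1)
    extras = cfg.measure_extra_effects
    for g in ("PD", "RBD"):
        rows = (demo["group"].to_numpy() == g)
        if rows.any():
            y[rows] += extras[g].to_numpy()
    y += rng.standard_normal((n, L.shape[0])) * np.sqrt(psi)
    out = pd.DataFrame(y, columns=cfg.loadings.index, index=demo.index)
    # emit latency columns on their natural lower=better scale
    for m in out.columns:
        if cfg.catalog.measure_kind(m) == "latency":
            out[m] = np.exp(6.4 - 0.35 * out[m]) if cfg.emit_raw_latency_ms else -out[m]
    return out


def _scale_scores(cfg: GeneratorConfig, rng, f: np.ndarray) -> pd.DataFrame:
    """MoCA (two timepoints, per-section), MMSE: Poisson error-count model."""
    fac = {name: f[:, i] for i, name in enumerate(FACTORS)}
    c = cfg.scale_coupling
    out = {}
    for tp in ("baseline", "assessment"):
        total = np.zeros(f.shape[0])
        for name, max_score, lam, mix in _MOCA_SECTIONS:
            g = sum(w * fac[factor] for factor, w in mix.items())
            errors = rng.poisson(lam * np.exp(-c * g))
            score = np.maximum(max_score - errors, 0)
            total += score
            if tp == "assessment":
                out[f"moca_{name}_assessment"] = score
        out[f"moca_total_{tp}"] = total
    g_all = sum(fac[x] for x in ACCURACY_FACTORS) / 4.0
    mmse_err = rng.poisson(_MMSE_LAMBDA * np.exp(-c * g_all))
    out["mmse_total_baseline"] = np.maximum(30 - mmse_err, 0)
    return pd.DataFrame(out)


def _clinical_scores(cfg: GeneratorConfig, rng, demo: pd.DataFrame, f: np.ndarray,
                     prbd: np.ndarray) -> pd.DataFrame:
    n = len(demo)
    group = demo["group"].to_numpy()
    motor = f[:, FACTORS.index("motor_rt")]
    out = pd.DataFrame(index=demo.index)

    rbdsq = np.zeros(n)
    is_c = group == "control"
    is_pd = group == "PD"
    is_rbd = group == "RBD"
    rbdsq[is_c] = rng.normal(2.5, 1.8, is_c.sum())
    rbdsq[is_rbd] = rng.normal(9.9, 2.0, is_rbd.sum())
    # PD is a mixture: the probable-RBD subgroup sits strictly above the
    # screening cutoff (>6), the rest strictly below, so the derived flag
    # matches the latent subgroup assignment exactly
    pd_prbd = is_pd & prbd
    pd_no = is_pd & ~prbd
    rbdsq[pd_prbd] = 7.0 + np.abs(rng.normal(1.5, 1.3, pd_prbd.sum()))
    rbdsq[pd_no] = np.minimum(rng.normal(4.0, 1.5, pd_no.sum()), 6.0)
    out["rbdsq"] = np.clip(np.round(rbdsq), 0, 13).astype(int)

    base3 = np.select([is_c, is_pd, is_rbd], [1.4, 30.7, 6.8])
    sd3 = np.select([is_c, is_pd, is_rbd], [1.6, cfg.updrs3_noise_sd, 6.0])
    u3 = base3 - cfg.updrs3_motor_slope * motor + rng.normal(0, 1, n) * sd3
    out["updrs3"] = np.clip(np.round(u3), 0, 132).astype(int)
    for item in ("updrs3_fingertap", "updrs3_handmovement"):
        base_i = np.select([is_c, is_pd, is_rbd], [0.3, 3.5, 0.8])
        u = base_i - 0.8 * motor + rng.normal(0, 1.2, n)
        out[item] = np.clip(np.round(u), 0, 8).astype(int)
    out["updrs1"] = np.clip(
        np.round(np.select([is_c, is_pd, is_rbd], [4.9, 9.8, 7.2]) + rng.normal(0, 4.5, n)), 0, 52
    ).astype(int)
    out["updrs2"] = np.clip(
        np.round(np.select([is_c, is_pd, is_rbd], [0.9, 11.6, 2.7]) + rng.normal(0, 5.0, n)), 0, 52
    ).astype(int)
    u4 = np.clip(np.round(4.1 + rng.normal(0, 3.6, n)), 0, 24).astype(float)
    u4[~is_pd] = np.nan
    out["updrs4"] = u4
    purdue = (
        np.select([is_c, is_pd, is_rbd], [38.6, 29.6, 32.3]) + 2.0 * motor + rng.normal(0, 5.5, n)
    )
    out["purdue"] = np.round(purdue, 1)
    return out


def _assemble(cfg: GeneratorConfig, rng, demo: pd.DataFrame, mu: np.ndarray,
              prbd: np.ndarray, with_scales: bool) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = len(demo)
    chol = np.linalg.cholesky(cfg.factor_cov())
    f = mu + rng.standard_normal((n, len(FACTORS))) @ chol.T
    measures = _measures_from_latents(cfg, rng, demo, f)
    parts = [demo.reset_index(drop=True)]
    if with_scales:
        parts.append(_scale_scores(cfg, rng, f).reset_index(drop=True))
        parts.append(
            _clinical_scores(cfg, rng, demo.reset_index(drop=True), f, prbd).reset_index(drop=True)
        )
    parts.append(measures.reset_index(drop=True))
    df = pd.concat(parts, axis=1)
    scores = pd.DataFrame(f, columns=list(FACTORS))
    return df, scores


def generate_cohort(config: GeneratorConfig, seed: int) -> tuple[CohortTable, SyntheticTruth]:
    """Generate the patient/control cohort plus its ground truth."""
    rng = np.random.default_rng([int(seed), 101])
    sizes = {"control": config.n_control, "PD": config.n_pd, "RBD": config.n_rbd}
    demo = pd.concat(
        [_draw_demographics(rng, g, n) for g, n in sizes.items()], ignore_index=True
    )
    p = config.device_proportions_cohort
    demo["device"] = rng.choice(DEVICES, size=len(demo), p=p)
    prbd = np.zeros(len(demo), dtype=bool)
    is_pd = (demo["group"] == "PD").to_numpy()
    prbd[is_pd] = rng.random(is_pd.sum()) < config.prbd_fraction

    eff = config.group_factor_effects()
    mu = eff.loc[demo["group"]].to_numpy(dtype=float)
    extra = np.zeros_like(mu)
    extra[prbd, : len(ACCURACY_FACTORS)] = config.prbd_extra_accuracy
    extra[prbd, FACTORS.index("motor_rt")] = config.prbd_extra_latency
    mu = mu + extra

    df, scores = _assemble(config, rng, demo, mu, prbd, with_scales=True)
    if config.moca_inclusion_cutoff is not None:
        keep = df["moca_total_baseline"] > config.moca_inclusion_cutoff
        df = df[keep].reset_index(drop=True)
        scores = scores[keep.to_numpy()].reset_index(drop=True)

    rates = config.missingness_rates()
    mask = rng.random((len(df), len(rates))) < rates.to_numpy()
    for j, m in enumerate(rates.index):
        df.loc[mask[:, j], m] = np.nan

    df.insert(0, "participant_id", [f"sub-{i + 1:05d}" for i in range(len(df))])
    cohort = CohortTable(df)
    truth = SyntheticTruth(
        seed=int(seed),
        factor_corr=config.factor_corr,
        loadings=config.loadings.copy(),
        uniquenesses=config.uniquenesses(),
        group_factor_effects=eff,
        confound_offsets=config.measure_confound_offsets(),
        device_offsets=config.device_offsets.copy(),
        factor_scores=scores,
        config=config,
    )
    return cohort, truth


def generate_normative_sample(config: GeneratorConfig, seed: int) -> CohortTable:
    """Large healthy sample, balanced over age decades, mixed devices."""
    if config.n_per_decade < 2:
        raise GeneratorError("need n_per_decade >= 2")
    rng = np.random.default_rng([int(seed), 202])
    n = config.n_per_decade * len(AGE_DECADES)
    age = np.concatenate(
        [rng.uniform(10 * d, 10 * d + 9.9, config.n_per_decade) for d in range(5, 9)]
    ).round(1)
    demo = pd.DataFrame(
        {
            "group": "control",
            "age_years": age,
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "education_band": rng.choice(EDUCATION_BANDS, size=n, p=_EDUCATION_PROBS),
            "device": rng.choice(DEVICES, size=n, p=config.device_proportions_normative),
        }
    )
    mu = np.zeros((n, len(FACTORS)))
    df, _ = _assemble(config, rng, demo, mu, np.zeros(n, dtype=bool), with_scales=False)
    df.insert(0, "participant_id", [f"norm-{i + 1:06d}" for i in range(len(df))])
    return CohortTable(df)


def apply_missingness(cohort: CohortTable, rates, seed: int) -> CohortTable:
    """Independently blank task cells at per-measure rates (demographics kept)."""
    rng = np.random.default_rng([int(seed), 303])
    df = cohort.df.copy()
    rates = pd.Series(rates, dtype=float)
    if ((rates < 0) | (rates > 1)).any():
        raise GeneratorError("missingness rates must be in [0, 1]")
    for m, rate in rates.items():
        if m not in df.columns:
            raise GeneratorError(f"no such measure column {m!r}")
        df.loc[rng.random(len(df)) < rate, m] = np.nan
    return CohortTable(df)


def scaled_config(config: GeneratorConfig, n_per_group: int) -> GeneratorConfig:
    """Same study conditions at a different per-group sample size."""
    return replace(config, n_control=n_per_group, n_pd=n_per_group, n_rbd=n_per_group)
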