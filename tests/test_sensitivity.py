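"""Cross-validation identities, modelling variants, subgroups, motor confound."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cogbattery.adjust import adjust_all
from cogbattery.factors import global_composite
from cogbattery.sensitivity import (
    SensitivityError,
    crossvalidate_composite_model,
    fingertap_hand_composite,
    model_variant_contrasts,
    motor_confound_correlation,
    subgroup_contrasts,
    variant_agreement,
)
from cogbattery.simulate import (
    FACTORS,
    GeneratorConfig,
    generate_cohort,
    scaled_config,
)


def _labels(n_each=("control", "PD", "RBD"), n=60):
    return pd.Series(np.repeat(list(n_each), n))


class TestCrossValidation:
    def test_loo_equals_nfold(self):
        rng = np.random.default_rng(0)
        lab = _labels(n=40)
        y = pd.Series(rng.standard_normal(len(lab)))
        loo = crossvalidate_composite_model(y, lab, scheme="loo")
        nfold = crossvalidate_composite_model(y, lab, scheme="kfold", n_folds=len(y))
        pd.testing.assert_series_equal(loo.predictions, nfold.predictions)
        assert loo.mse == nfold.mse

    def test_noiseless_group_function(self):
        lab = _labels(n=40)
        y = lab.map({"control": 1.0, "PD": -1.0, "RBD": 0.0}).astype(float)
        res = crossvalidate_composite_model(y, lab, scheme="loo")
        assert res.correlation == pytest.approx(1.0, abs=1e-10)
        assert res.mse == pytest.approx(0.0, abs=1e-20)

    def test_pure_noise_near_zero_correlation(self):
        rng = np.random.default_rng(1)
        lab = _labels(n=167)  # ~500 rows
        y = pd.Series(rng.standard_normal(len(lab)))
        res = crossvalidate_composite_model(y, lab, scheme="kfold", n_folds=25, seed=2)
        assert abs(res.correlation) < 0.1

    def test_mse_converges_to_noise_variance(self):
        rng = np.random.default_rng(3)
        lab = _labels(n=334)  # ~1000 rows
        effect = lab.map({"control": 0.0, "PD": -0.65, "RBD": -0.45}).astype(float)
        y = effect + rng.standard_normal(len(lab))
        res = crossvalidate_composite_model(y, lab, scheme="loo")
        assert res.mse == pytest.approx(1.0, rel=0.10)

    def test_heldout_responses_never_used(self):
        """Corrupting a held-out response does not change its prediction."""
        rng = np.random.default_rng(4)
        lab = _labels(n=30)
        y = pd.Series(rng.standard_normal(len(lab)))
        base = crossvalidate_composite_model(y, lab, scheme="loo")
        y2 = y.copy()
        y2.iloc[7] = 1e6
        corrupted = crossvalidate_composite_model(y2, lab, scheme="loo")
        assert corrupted.predictions.iloc[7] == pytest.approx(
            base.predictions.iloc[7], abs=1e-10
        )

    def test_folds_partition_sample(self):
        rng = np.random.default_rng(5)
        lab = _labels(n=50)
        y = pd.Series(rng.standard_normal(len(lab)))
        res = crossvalidate_composite_model(y, lab, scheme="kfold", n_folds=25, seed=1)
        assert sum(res.fold_sizes) == len(y)
        assert res.n_folds == 25

    def test_covariate_augmented_model(self, midsize_cohort):
        _, cohort, _, adjusted = midsize_cohort
        acc = [m for m in adjusted.measure_ids if m.endswith(".primary")][:10]
        comp = global_composite(adjusted, acc, accuracy_measure_ids=acc)
        res = crossvalidate_composite_model(
            comp.scores, cohort.df["group"], scheme="kfold", n_folds=25,
            seed=3, covariates=cohort.df.loc[comp.scores.index],
        )
        assert np.isfinite(res.correlation) and res.mse > 0

    def test_too_many_folds_rejected(self):
        lab = _labels(n=3)
        y = pd.Series(np.arange(9, dtype=float))
        with pytest.raises(SensitivityError):
            crossvalidate_composite_model(y, lab, scheme="kfold", n_folds=25)


class TestModelVariants:
    @pytest.fixture(scope="class")
    def cohort600(self, gen_config):
        cfg = scaled_config(gen_config, 200)
        cohort, _ = generate_cohort(cfg, 80)
        return cfg, cohort

    def test_two_step_and_one_model_agree(self, cohort600):
        cfg, cohort = cohort600
        measures = [f"{t}.primary" for t in list(cfg.catalog.task_ids)[:6]]
        a = model_variant_contrasts(cohort, cfg.catalog, "two_step", measures)
        b = model_variant_contrasts(cohort, cfg.catalog, "one_model", measures)
        agree = variant_agreement(a, b)
        assert agree["max_abs_delta_smd"] < 0.12
        # signs must agree wherever the primary contrast is non-negligible
        merged = a.merge(b, on=["measure_id", "contrast"], suffixes=("_a", "_b"))
        solid = merged[merged["smd_a"].abs() > 0.1]
        assert (np.sign(solid["smd_a"]) == np.sign(solid["smd_b"])).all()

    def test_variants_agree_without_age_effects(self, gen_config):
        cfg = scaled_config(
            replace(
                gen_config,
                age_decade_factor_effects={f: (0, 0, 0, 0) for f in FACTORS},
            ),
            200,
        )
        cohort, _ = generate_cohort(cfg, 81)
        measures = [f"{t}.primary" for t in list(cfg.catalog.task_ids)[:6]]
        tables = {
            v: model_variant_contrasts(cohort, cfg.catalog, v, measures)
            for v in ("two_step", "one_model", "continuous_age_cubic")
        }
        for v in ("one_model", "continuous_age_cubic"):
            agree = variant_agreement(tables["two_step"], tables[v])
            assert agree["max_abs_delta_smd"] < 0.12, v

    def test_cubic_age_effect_handled_by_cubic_variant(self, gen_config):
        """A smooth cubic age effect leaves decade categories with residual
        within-decade confounding; the cubic-age variant absorbs it."""
        cfg = scaled_config(gen_config, 500)
        cohort, _ = generate_cohort(cfg, 82)
        df = cohort.df.copy()
        m = "digit_span.primary"
        age_c = (df["age_years"] - 70.0) / 10.0
        df[m] = df[m] - 0.8 * age_c**3  # decline accelerating with age
        from cogbattery.cohort import CohortTable

        bent = CohortTable(df)
        two = model_variant_contrasts(bent, cfg.catalog, "two_step", [m])
        cub = model_variant_contrasts(bent, cfg.catalog, "continuous_age_cubic", [m])
        agree = variant_agreement(two, cub)
        assert agree["max_abs_delta_smd"] > 0.0
        # the cubic model should land closer to the no-distortion analysis
        clean = model_variant_contrasts(cohort, cfg.catalog, "two_step", [m])
        merged_t = clean.merge(two, on=["measure_id", "contrast"], suffixes=("_c", "_v"))
        merged_q = clean.merge(cub, on=["measure_id", "contrast"], suffixes=("_c", "_v"))
        err_two = (merged_t["smd_c"] - merged_t["smd_v"]).abs().mean()
        err_cub = (merged_q["smd_c"] - merged_q["smd_v"]).abs().mean()
        assert err_cub <= err_two + 0.02

    def test_unknown_variant(self, cohort600):
        cfg, cohort = cohort600
        with pytest.raises(SensitivityError):
            model_variant_contrasts(cohort, cfg.catalog, "bayesian")


class TestSubgroups:
    @pytest.fixture(scope="class")
    def subgroup_setup(self, gen_config):
        # PD large enough for the latency split to reach significance while
        # the accuracy split stays a sub-threshold trend (~75 vs ~225)
        cfg = replace(gen_config, n_control=300, n_pd=300, n_rbd=300)
        cohort, _ = generate_cohort(cfg, 83)
        cat = cfg.catalog
        adjusted = adjust_all(cohort, cat)
        acc = [
            m for m in adjusted.measure_ids
            if m.endswith(".primary") and cat.measure_kind(m) == "accuracy"
        ]
        lat = [m for m in adjusted.measure_ids if cat.measure_kind(m) == "latency"]
        comps = {
            "accuracy": global_composite(adjusted, acc, accuracy_measure_ids=acc).scores,
            "latency": global_composite(adjusted, lat).scores,
        }
        return cfg, cohort, comps

    def test_partition_exact(self, subgroup_setup):
        _, cohort, _ = subgroup_setup
        df = cohort.df
        pd_rows = df[df["group"] == "PD"]
        assert pd_rows["probable_rbd"].sum() + (~pd_rows["probable_rbd"]).sum() == len(pd_rows)

    def test_rbd_subgroup_slower_accuracy_trend(self, subgroup_setup):
        """PD with probable RBD: significantly slower; accuracy shows a
        negative sub-threshold trend."""
        _, cohort, comps = subgroup_setup
        results = {
            (s.comparison, s.composite): s for s in subgroup_contrasts(cohort, comps)
        }
        lat = results[("PD+RBD vs PD-RBD", "latency")]
        acc = results[("PD+RBD vs PD-RBD", "accuracy")]
        assert lat.smd < 0 and lat.p_value < 0.05
        assert acc.smd < 0 and acc.p_value > 0.01  # trend, not a strong effect

    def test_all_family_comparisons_present(self, subgroup_setup):
        _, cohort, comps = subgroup_setup
        labels = {s.comparison for s in subgroup_contrasts(cohort, comps)}
        assert labels == {
            "PD+RBD vs PD-RBD",
            "PD+RBD vs iRBD",
            "PD+RBD vs control",
            "PD-RBD vs control",
            "iRBD vs control",
        }

    def test_zero_prbd_fraction_skips_comparison(self, gen_config):
        cfg = replace(gen_config, prbd_fraction=0.0, n_pd=80)
        cohort, _ = generate_cohort(cfg, 84)
        cat = cfg.catalog
        adjusted = adjust_all(cohort, cat)
        acc = [m for m in adjusted.measure_ids if m.endswith(".primary")][:8]
        comps = {"accuracy": global_composite(adjusted, acc).scores}
        with pytest.warns(UserWarning, match="skipped"):
            results = subgroup_contrasts(cohort, comps)
        assert not any(s.comparison == "PD+RBD vs PD-RBD" for s in results)


class TestMotorConfound:
    def test_antithetic_composite(self, small_study):
        _, cohort, _, _ = small_study
        comp = -pd.to_numeric(cohort.df["updrs3"], errors="coerce")
        table = motor_confound_correlation({"anti": comp}, cohort)
        assert table.loc["anti~updrs3", "r"] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_composite_null(self, gen_config):
        cfg = replace(gen_config, n_pd=1000)
        cohort, _ = generate_cohort(cfg, 85)
        rng = np.random.default_rng(6)
        comp = pd.Series(rng.standard_normal(len(cohort.df)), index=cohort.df.index)
        table = motor_confound_correlation({"noise": comp}, cohort)
        assert abs(table.loc["noise~updrs3", "r"]) < 0.1

    def test_latency_composite_tracks_motor_severity(self, gen_config):
        """Generator couples UPDRS-III to the motor latent at rho ~ 0.4;
        the latency composite recovers a correlation of that size."""
        cfg = replace(gen_config, n_pd=200)
        cohort, truth = generate_cohort(cfg, 86)
        cat = cfg.catalog
        adjusted = adjust_all(cohort, cat)
        lat = [m for m in adjusted.measure_ids if cat.measure_kind(m) == "latency"]
        comp = global_composite(adjusted, lat).scores
        table = motor_confound_correlation({"latency": comp}, cohort)
        assert table.loc["latency~updrs3", "r"] == pytest.approx(-0.4, abs=0.12)

    def test_fingertap_composite_standardized(self, small_study):
        _, cohort, _, _ = small_study
        z = fingertap_hand_composite(cohort)
        assert abs(z.mean()) < 0.05

    def test_too_few_pairs(self, small_study):
        _, cohort, _, _ = small_study
        comp = pd.Series([1.0, 2.0], index=cohort.df.index[:2])
        with pytest.raises(SensitivityError):
            motor_confound_correlation({"tiny": comp}, cohort, group="RBD")
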