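"""Convergence/divergence benchmarking against supervised scales."""

import numpy as np
import pandas as pd
import pytest

from cogbattery.adjust import adjust_all
from cogbattery.benchmark import (
    BenchmarkError,
    adjust_scale,
    benchmark_scale,
    paired_change_test,
    predict_composite_from_subscales,
    predict_scale_from_tasks,
    scale_group_discriminability,
    task_scale_correlations,
)
from cogbattery.cohort import CohortTable
from cogbattery.factors import global_composite
from cogbattery.simulate import GeneratorConfig, generate_cohort, scaled_config


@pytest.fixture(scope="module")
def battery_setup(small_study):
    cfg, cohort, truth, _ = small_study
    cat = cfg.catalog
    adjusted = adjust_all(cohort, cat)
    battery = [f"{t}.primary" for t in cat.final_battery_rows.index]
    acc = [m for m in battery if cat.measure_kind(m) == "accuracy"]
    composite = global_composite(adjusted, battery, accuracy_measure_ids=acc)
    return cfg, cohort, truth, adjusted, battery, composite


class TestPredictScaleFromTasks:
    def test_exact_linear_combination(self, battery_setup):
        _, _, _, adjusted, battery, _ = battery_setup
        X = adjusted.values[battery].dropna()
        scale = X @ np.arange(1, len(battery) + 1)
        fit = predict_scale_from_tasks(X, scale)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_independent_scale_near_zero(self, battery_setup):
        _, _, _, adjusted, battery, _ = battery_setup
        rng = np.random.default_rng(0)
        cfg = scaled_config(GeneratorConfig(missingness=0.0), 334)
        cohort, _ = generate_cohort(cfg, 70)
        adj = adjust_all(cohort, cfg.catalog, measure_ids=battery)
        X = adj.values[battery].dropna()
        noise = pd.Series(rng.standard_normal(len(X)), index=X.index)
        fit = predict_scale_from_tasks(X, noise)
        assert fit.r_squared < 0.05

    def test_calibrated_moca_r2_at_paper_scale(self, gen_config):
        """~25% of adjusted MoCA variance is explained by the selected tasks
        at the study's sample size (mean over replicates)."""
        cat = gen_config.catalog
        battery = [f"{t}.primary" for t in cat.final_battery_rows.index]
        r2s = []
        for seed in range(300, 308):
            cohort, _ = generate_cohort(scaled_config(gen_config, 50), seed)
            adj = adjust_all(cohort, cat, measure_ids=battery)
            scale = adjust_scale(cohort, "moca_total_assessment")
            X = adj.values[battery].dropna()
            r2s.append(predict_scale_from_tasks(X, scale.loc[X.index]).r_squared)
        assert np.mean(r2s) == pytest.approx(0.25, abs=0.07)

    def test_too_few_cases(self, battery_setup):
        _, _, _, adjusted, battery, _ = battery_setup
        X = adjusted.values[battery].dropna().iloc[:5]
        with pytest.raises(BenchmarkError):
            predict_scale_from_tasks(X, X.iloc[:, 0])


class TestTaskScaleCorrelations:
    def test_self_and_antithetic(self, battery_setup):
        _, _, _, adjusted, battery, _ = battery_setup
        X = adjusted.values[battery].dropna()
        scale = X[battery[0]]
        table = task_scale_correlations(X[[battery[0]]], scale)
        assert table.loc[battery[0], "r"] == pytest.approx(1.0, abs=1e-12)
        anti = task_scale_correlations(X[[battery[0]]], -scale)
        assert anti.loc[battery[0], "r"] == pytest.approx(-1.0, abs=1e-12)

    def test_word_definitions_most_scale_correlated(self, gen_config):
        """Vocabulary probes the scale hardest; perceptual tasks weakly."""
        cat = gen_config.catalog
        battery = [f"{t}.primary" for t in cat.final_battery_rows.index]
        acc = [m for m in battery if cat.measure_kind(m) == "accuracy"]
        cohort, _ = generate_cohort(scaled_config(gen_config, 400), 71)
        adj = adjust_all(cohort, cat, measure_ids=battery)
        scale = adjust_scale(cohort, "moca_total_assessment")
        X = adj.values[acc].dropna()
        table = task_scale_correlations(X, scale.loc[X.index])
        word_tasks = {"word_definitions.primary", "verbal_analogies.primary"}
        assert table["r"].idxmax() in word_tasks
        median_r = table["r"].median()
        assert table.loc["word_definitions.primary", "r"] > median_r
        assert table.loc["emotional_discrimination.primary", "r"] <= median_r

    def test_sparse_measure_skipped_with_warning(self, battery_setup):
        _, _, _, adjusted, battery, _ = battery_setup
        X = adjusted.values[battery].dropna().copy()
        X.iloc[2:, 0] = np.nan
        with pytest.warns(UserWarning, match="fewer than 3"):
            table = task_scale_correlations(X, X[battery[1]])
        assert battery[0] not in table.index


class TestSubscaleRegression:
    def test_deterministic_function_of_levels(self, battery_setup):
        _, cohort, _, _, _, composite = battery_setup
        sub = cohort.df[["moca_delayed_recall_assessment"]].loc[composite.scores.index]
        target = sub["moca_delayed_recall_assessment"].map(
            lambda v: {0: -2.0, 1: -1.0, 2: 0.0, 3: 0.5, 4: 1.0, 5: 1.5}[int(v)]
        )
        fit = predict_composite_from_subscales(target, sub, min_level_count=1)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_independent_subscales_null_r2(self):
        rng = np.random.default_rng(4)
        n, k_levels = 1000, 4
        sub = pd.DataFrame(
            {f"s{j}": rng.integers(0, k_levels, n) for j in range(3)}
        )
        comp = pd.Series(rng.standard_normal(n))
        fit = predict_composite_from_subscales(comp, sub)
        k = 3 * (k_levels - 1)
        assert fit.r_squared == pytest.approx(k / (n - 1), abs=0.03)

    def test_significant_fit_on_synthetic_cohort(self, gen_config):
        cat = gen_config.catalog
        battery = [f"{t}.primary" for t in cat.final_battery_rows.index]
        acc = [m for m in battery if cat.measure_kind(m) == "accuracy"]
        cohort, _ = generate_cohort(scaled_config(gen_config, 200), 72)
        adj = adjust_all(cohort, cat, measure_ids=battery)
        comp = global_composite(adj, battery, accuracy_measure_ids=acc)
        subcols = [
            c for c in cohort.df.columns
            if c.startswith("moca_") and c.endswith("_assessment")
            and c != "moca_total_assessment"
        ]
        fit = predict_composite_from_subscales(comp.scores, cohort.df[subcols])
        assert fit.p_value < 0.05
        assert 0.05 < fit.r_squared < 0.6


class TestScaleDiscriminability:
    def test_identical_distributions_zero(self):
        rng = np.random.default_rng(6)
        vals = pd.Series(np.tile(rng.standard_normal(50), 3))
        lab = pd.Series(["control"] * 50 + ["PD"] * 50 + ["RBD"] * 50)
        res = scale_group_discriminability(vals, lab)
        assert all(abs(c.smd) < 1e-10 for c in res)

    def test_ceilinged_scale_attenuated_below_composite(self, battery_setup):
        cfg, cohort, _, adjusted, battery, composite = battery_setup
        cat = cfg.catalog
        acc_all = [
            m for m in adjusted.measure_ids
            if m.endswith(".primary") and cat.measure_kind(m) == "accuracy"
        ]
        comp = global_composite(adjusted, acc_all, accuracy_measure_ids=acc_all)
        groups = cohort.df["group"]
        scale = adjust_scale(cohort, "moca_total_assessment")
        smd_scale = {
            c.contrast: c.smd for c in scale_group_discriminability(scale, groups)
        }
        from cogbattery.contrasts import group_contrast_series

        smd_comp = {
            c.contrast: c.smd
            for c in group_contrast_series(
                comp.scores, groups.loc[comp.scores.index]
            )
        }
        assert abs(smd_scale["PD-control"]) < abs(smd_comp["PD-control"])

    def test_continuous_unceilinged_scale_not_attenuated(self, battery_setup):
        """A continuous probe of the latent global composite shows the full
        group effect, unlike the ceilinged integer scale."""
        from cogbattery.simulate import latent_global_composite

        cfg, cohort, truth, adjusted, battery, _ = battery_setup
        cat = cfg.catalog
        acc = [
            m for m in cfg.loadings.index
            if m.endswith(".primary") and cat.measure_kind(m) == "accuracy"
        ]
        rng = np.random.default_rng(7)
        latent = latent_global_composite(
            cfg, acc, truth.factor_scores, cohort.df["group"].reset_index(drop=True)
        )
        latent.index = cohort.df.index
        probe = latent + rng.normal(0, 0.1, len(latent))
        res = scale_group_discriminability(probe, cohort.df["group"])
        smd = {c.contrast: c.smd for c in res}
        # close to the configured 0.65 SD deficit; far beyond the ~0.3 the
        # ceilinged scale shows
        assert smd["PD-control"] < -0.45


class TestPairedChange:
    def test_no_change(self):
        rng = np.random.default_rng(8)
        base = pd.Series(rng.normal(27, 2, 60).round())
        lab = pd.Series(["PD"] * 30 + ["RBD"] * 30)
        out = paired_change_test(base, base.copy(), lab)
        assert (out["t"] == 0).all()
        assert (out["p_value"] == 1).all()

    def test_constant_shift_closed_form(self):
        rng = np.random.default_rng(9)
        n = 40
        base = pd.Series(rng.normal(27, 2, n))
        diff_noise = rng.normal(0, 1, n)
        follow = base + 1.5 + diff_noise
        lab = pd.Series(["PD"] * n)
        out = paired_change_test(base, follow, lab)
        d = (follow - base).to_numpy()
        t_expected = d.mean() * np.sqrt(n) / d.std(ddof=1)
        assert out.loc["PD", "t"] == pytest.approx(t_expected, abs=1e-10)

    def test_null_type_one_control(self):
        rng = np.random.default_rng(10)
        rejections = 0
        for _ in range(200):
            base = pd.Series(rng.normal(27, 2, 40))
            follow = base + rng.normal(0, 1.5, 40)
            lab = pd.Series(["PD"] * 40)
            out = paired_change_test(base, follow, lab)
            rejections += out.loc["PD", "p_value"] < 0.05
        assert rejections / 200 == pytest.approx(0.05, abs=0.04)

    def test_interval_reported(self, battery_setup):
        _, cohort, _, _, _, _ = battery_setup
        df = cohort.df
        interval = pd.Series(6.5, index=df.index)
        out = paired_change_test(
            df["moca_total_baseline"], df["moca_total_assessment"],
            df["group"], interval_years=interval,
        )
        assert out["mean_interval_years"].notna().all()


class TestBenchmarkReport:
    def test_full_report_and_identities(self, battery_setup):
        cfg, cohort, _, adjusted, battery, composite = battery_setup
        rep = benchmark_scale(
            cohort, adjusted.values[battery], composite.scores, "moca"
        )
        # composite-scale r equals sqrt of the one-predictor regression R2
        scale = adjust_scale(cohort, "moca_total_assessment")
        single = predict_scale_from_tasks(
            composite.scores.to_frame("comp"), scale
        )
        assert rep.composite_scale_r**2 == pytest.approx(
            single.r_squared, abs=1e-10
        )
        assert -1 <= rep.composite_scale_r <= 1
        assert 0 <= rep.scale_fit_from_tasks.r_squared <= 1
        assert rep.paired_change is not None
        payload = rep.to_dict()
        assert payload["scale"] == "moca"

    def test_affine_rescaling_invariance(self, battery_setup):
        """rank-INT adjustment removes the scale's units: benchmarking an
        affinely rescaled raw scale gives identical adjusted statistics."""
        cfg, cohort, _, adjusted, battery, composite = battery_setup
        df2 = cohort.df.copy()
        df2["moca_total_assessment"] = 3.0 * df2["moca_total_assessment"] + 7.0
        rescaled = CohortTable(df2)
        a = benchmark_scale(cohort, adjusted.values[battery], composite.scores, "moca")
        b = benchmark_scale(rescaled, adjusted.values[battery], composite.scores, "moca")
        assert a.scale_fit_from_tasks.r_squared == pytest.approx(
            b.scale_fit_from_tasks.r_squared, abs=1e-10
        )
        assert a.composite_scale_r == pytest.approx(b.composite_scale_r, abs=1e-10)
        for ca, cb in zip(a.scale_group_contrasts, b.scale_group_contrasts):
            assert ca.smd == pytest.approx(cb.smd, abs=1e-10)

    def test_mmse_path(self, battery_setup):
        cfg, cohort, _, adjusted, battery, composite = battery_setup
        rep = benchmark_scale(
            cohort, adjusted.values[battery], composite.scores, "mmse"
        )
        assert rep.paired_change is None
        assert rep.composite_fit_from_subscales is None
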