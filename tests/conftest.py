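"""Shared fixtures: one small synthetic study reused across test modules."""

import warnings

import pytest

from cogbattery.adjust import adjust_all
from cogbattery.catalog import default_catalog
from cogbattery.factors import HeywoodWarning
from cogbattery.simulate import (
    GeneratorConfig,
    generate_cohort,
    generate_normative_sample,
    scaled_config,
)


@pytest.fixture(autouse=True)
def _quiet_heywood():
    # small-sample EFA occasionally clips a communality; irrelevant to most tests
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", HeywoodWarning)
        yield


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def gen_config():
    """Default study conditions, missingness off for deterministic row counts."""
    return GeneratorConfig(missingness=0.0)


@pytest.fixture(scope="session")
def small_study(gen_config):
    """Paper-scale cohort + normative sample (n=59/54/50, 400/decade)."""
    from dataclasses import replace

    cfg = replace(gen_config, n_per_decade=400)
    cohort, truth = generate_cohort(cfg, 20240501)
    normative = generate_normative_sample(cfg, 20240501)
    return cfg, cohort, truth, normative


@pytest.fixture(scope="session")
def midsize_cohort(gen_config):
    """n=300/group cohort with its adjusted matrix (shared heavy fixture)."""
    cfg = scaled_config(gen_config, 300)
    cohort, truth = generate_cohort(cfg, 7777)
    adjusted = adjust_all(cohort, cfg.catalog)
    return cfg, cohort, truth, adjusted


@pytest.fixture(scope="session")
def factor_study(gen_config):
    """n~2000 cohort adjusted on primary measures, for factor-structure tests."""
    cfg = scaled_config(gen_config, 667)
    cohort, truth = generate_cohort(cfg, 11)
    primaries = [m for m in cfg.loadings.index if m.endswith(".primary")]
    adjusted = adjust_all(cohort, cfg.catalog, measure_ids=primaries)
    return cfg, cohort, truth, adjusted, primaries
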