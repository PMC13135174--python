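import numpy as np
import pytest

import stenoscope as st
from stenoscope.classify import (
    GBM_GRID_FAST,
    SVM_GRID_FAST,
    PipelineConfig,
    extract_cohort_features,
    run_pipeline,
)
from stenoscope.synth import SimParams

PAPER_TEST_COUNTS = {"mild": 5, "moderate": 4, "severe": 6}


def fast_config(**kwargs) -> PipelineConfig:
    kwargs.setdefault("svm_grid", dict(SVM_GRID_FAST))
    kwargs.setdefault("gbm_grid", dict(GBM_GRID_FAST))
    kwargs.setdefault("test_counts", dict(PAPER_TEST_COUNTS))
    return PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def bank():
    return st.build_filter_bank()


@pytest.fixture(scope="session")
def cohort():
    """Default 75-participant cohort (seed 7): (manifest, records, truths)."""
    return st.simulate_cohort(seed=7, n_cycles=14)


@pytest.fixture(scope="session")
def cohort_features(cohort):
    manifest, records, truths = cohort
    cfg = PipelineConfig(seed=7)
    return extract_cohort_features(records, cfg, truths)


@pytest.fixture(scope="session")
def cohort30_features():
    """Ten 30 %-stenosis participants through the full feature pipeline."""
    params = SimParams()
    _, records, truths = st.simulate_cohort(((30.0, 30.0, 10),), params, seed=1, n_cycles=14)
    cfg = PipelineConfig(seed=1)
    return extract_cohort_features(records, cfg, truths)


@pytest.fixture(scope="session")
def default_run():
    """End-to-end run on the default cohort with the reduced tuning grids."""
    return run_pipeline(fast_config(seed=11))


@pytest.fixture(scope="session")
def null_run():
    """End-to-end run with the murmur disabled for every participant."""
    params = SimParams(murmur_gain_scale=0.0)
    return run_pipeline(fast_config(seed=12, sim_params=params))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
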