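import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rsnsage import (
    PipelineConfig,
    SyntheticConfig,
    build_graph,
    cohort_mean_correlation,
    run_pipeline,
    simulate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """21 ROIs in 3 planted networks; quick enough for every unit test."""
    cfg = SyntheticConfig(
        n_rois=21, n_networks=3, n_subjects=4, n_timepoints=120, seed=7
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_graph(small_cohort):
    return build_graph(cohort_mean_correlation(small_cohort))


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default planted-network conditions.

    70 ROIs, 7 networks, 10 subjects, 180 time points, rho = 0.6; shared
    across the recovery and invariant tests because training dominates
    the suite's runtime.
    """
    config = PipelineConfig(synthetic=SyntheticConfig(), seed=1)
    return run_pipeline(config)
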