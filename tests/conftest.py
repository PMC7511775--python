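import math

import pytest

from immunotopo import RunConfig, SimParams, generate_cohort, run_pipeline
from immunotopo.simulate import write_cohort


@pytest.fixture(scope="session")
def small_params():
    return SimParams(n_cases=12, cores_per_case=2, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """A small but fully featured synthetic cohort (both panels, benign cores)."""
    return generate_cohort(small_params)


@pytest.fixture(scope="session")
def cohort_paths(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    return write_cohort(small_cohort, out)


@pytest.fixture(scope="session")
def pipeline_result(cohort_paths, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig(rng_seed=5)
    return run_pipeline(
        cfg,
        cohort_paths["cells_p1"], cohort_paths["cells_p2"],
        cohort_paths["geometry"], cohort_paths["clinical"],
        out,
    )


@pytest.fixture(scope="session")
def survival_params():
    """Clinical-only cohort parameters: true HR 0.6, ~60% events by 60 months."""
    return dict(
        n_cases=400, cores_per_case=0, benign_case_fraction=0.0,
        betas={"high_infiltration": math.log(0.6)},
        baseline_weibull_shape=1.0, baseline_weibull_scale=50.0,
        admin_censor_months=60.0,
    )
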