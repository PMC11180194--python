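import numpy as np
import pytest

from stnio import cohort, trajectory


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic cohort shared by the module tests."""
    cfg = cohort.SyntheticStudyConfig(n_patients=4, seed=7)
    sites, clinical, truth = cohort.simulate_study(cfg)
    return cfg, sites, clinical, truth


@pytest.fixture(scope="session")
def pipeline_results(small_study):
    _, sites, _, _ = small_study
    return trajectory.run_pipeline(sites)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
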