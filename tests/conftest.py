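import numpy as np
import pytest

from metpanel.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """A synthetic study-sized cohort (31 met / 49 nonmet, all 13 markers)."""
    return simulate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def study_outcome(study_cohort):
    return (study_cohort["outcome"] == "met").to_numpy(dtype=float)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
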