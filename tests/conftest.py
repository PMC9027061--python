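import numpy as np
import pytest
from hypothesis import settings

from cobbkit import simulate as sim

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_design():
    return sim.StudyDesign(rng_seed=20220412)


@pytest.fixture(scope="session")
def study_table(default_design):
    """One full simulated observer study (1680 rows), fixed seed."""
    rng = np.random.default_rng(default_design.rng_seed)
    truth = sim.sample_true_curves(default_design, rng)
    return sim.simulate_study(truth, sim.default_observers(), default_design, rng)


@pytest.fixture(scope="session")
def true_curves(default_design):
    rng = np.random.default_rng(default_design.rng_seed)
    return sim.sample_true_curves(default_design, rng)
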