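import logging

import numpy as np
import pytest

logging.getLogger("gaitfuse").setLevel(logging.ERROR)

from gaitfuse.fusion import normalize_to_cycle, preset_params, simulate_gait
from gaitfuse.heel_paths import fit_heel_mixture, generate_synthetic_heel_data


@pytest.fixture(scope="session")
def normal_traj():
    """Two normal-preset gait cycles at production tolerances."""
    return simulate_gait(preset_params("normal"), 2)


@pytest.fixture(scope="session")
def normal_cycle(normal_traj):
    return normalize_to_cycle(normal_traj)


@pytest.fixture(scope="session")
def normal_corpus():
    return generate_synthetic_heel_data("normal", seed=3)


@pytest.fixture(scope="session")
def normal_mixture(normal_corpus):
    return fit_heel_mixture(normal_corpus, n_components=12)


@pytest.fixture(scope="session")
def crouch_traj():
    return simulate_gait(preset_params("crouch"), 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
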