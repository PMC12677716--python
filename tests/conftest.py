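import numpy as np
import pytest

from glysaxs.synthetic_data import SyntheticSpec, generate_hairpin_trajectory


@pytest.fixture(scope="session")
def folded_traj():
    return generate_hairpin_trajectory(
        SyntheticSpec(seed=7, n_frames=100, state="folded"))


@pytest.fixture(scope="session")
def unfolded_traj():
    return generate_hairpin_trajectory(
        SyntheticSpec(seed=7, n_frames=100, state="unfolded"))


@pytest.fixture(scope="session")
def q_lin():
    return np.linspace(0.01, 0.5, 40)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
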