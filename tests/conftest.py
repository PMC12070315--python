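import numpy as np
import pytest

from tndyn.config import default_config
from tndyn.synthetic import GeneratorSpec, make_toy_topology, simulate_hinge_trajectory


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_topology(GeneratorSpec(seed=0, n_frames=1))


@pytest.fixture(scope="session")
def small_trajectory(toy_model):
    """200-frame hinge trajectory with global motions, shared across tests."""
    spec = GeneratorSpec(seed=101, n_frames=200)
    traj, truth, model = simulate_hinge_trajectory(spec, toy_model)
    return spec, traj, truth, model


def rigid_motion(rng):
    """A random proper rotation matrix and translation vector."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    from scipy.spatial.transform import Rotation

    return Rotation.from_quat(q).as_matrix(), rng.uniform(-20, 20, 3)
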