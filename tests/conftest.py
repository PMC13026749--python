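import numpy as np
import pytest

from pedscrew import AnalysisConfig
from pedscrew.phantom import PhantomSpec, generate_phantom, plan_trajectories


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def plans(phantom):
    return plan_trajectories(phantom)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rigid_transform(rng):
    """Uniformly random proper rotation + bounded translation."""
    from scipy.spatial.transform import Rotation

    from pedscrew import RigidTransform

    R = Rotation.random(random_state=int(rng.integers(2**31 - 1))).as_matrix()
    return RigidTransform(R, rng.uniform(-50, 50, 3))
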