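import numpy as np
import pytest

from vesica.displacement import SphericalFrame, compute_displacement_field
from vesica.synthetic import VoidingScenario, make_sphere_mesh, make_voiding_pair


@pytest.fixture(scope="session")
def sphere_sub4():
    return make_sphere_mesh(10.0, 4)


@pytest.fixture(scope="session")
def concentric_pair():
    """Concentric spheres 30 -> 20 mm (uniform shrink), subdivision 4."""
    scenario = VoidingScenario(pattern="uniform", r_pre=30.0,
                               shrink_fraction=1.0 / 3.0, mesh_subdivisions=4)
    return make_voiding_pair(scenario)


@pytest.fixture(scope="session")
def concentric_field(concentric_pair):
    pre, post, _ = concentric_pair
    frame = SphericalFrame.from_meshes(pre, post)
    return compute_displacement_field(pre, post, frame), frame, pre, post


@pytest.fixture(scope="session")
def asymmetric_pair():
    scenario = VoidingScenario(pattern="asymmetric", r_pre=30.0,
                               shrink_fraction=1.0 / 3.0, asym_gain=1.5,
                               mesh_subdivisions=4)
    return make_voiding_pair(scenario)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
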