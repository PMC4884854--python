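import numpy as np
import pytest

from nlswei.materials import MaterialParams, tissue
from nlswei.phantom import build_phantom, make_test_fixture


@pytest.fixture(scope="session")
def tumor():
    return tissue("tumor")


@pytest.fixture(scope="session")
def benign():
    return tissue("benign")


@pytest.fixture(scope="session")
def neo_hookean_4kpa():
    """Simple material with mu0 = 4 kPa and no hardening terms."""
    return MaterialParams.from_coefficients(
        c10=1.0, c01=1.0, c11=0.0, c20=0.0, c02=0.0, label="nh4")


@pytest.fixture(scope="session")
def uniform_phantom(neo_hookean_4kpa):
    """Full-geometry phantom with one 4 kPa material everywhere."""
    return build_phantom(background=neo_hookean_4kpa,
                         tumor_material=neo_hookean_4kpa)


@pytest.fixture(scope="session")
def small_box():
    """20 x 10 mm homogeneous fixture with a roller base (uniform-compression
    oracle: full-width frictionless platen gives an exact homogeneous state)."""
    return make_test_fixture("homogeneous", width=20, height=10, mu0=4.0,
                             base_bc="roller")


def random_plane_strain_F(rng, scale=0.15):
    """Random admissible plane-strain deformation gradient near identity."""
    while True:
        F = np.eye(2) + scale * rng.standard_normal((2, 2))
        if np.linalg.det(F) > 0.35:
            return F
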