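import numpy as np
import pytest

from mmtrack import (
    FlowField,
    MagneticSphere,
    PhantomGeometry,
    make_planar_array,
)


@pytest.fixture(scope="session")
def reference_flow():
    """Reference flow: 30 ml/min in a 1.5 mm tube of 2 mm^2/s fluid."""
    return FlowField.from_flow_rate(30e-6 / 60.0, 1.5e-3, 2e-6)


@pytest.fixture(scope="session")
def flow_056():
    """Flow with the centerline velocity pinned to the nominal 0.56 m/s."""
    return FlowField.from_centerline(0.56, 1.5e-3, 2e-6)


@pytest.fixture()
def straight_geometry():
    return PhantomGeometry(reduction=0.0, straight_length=0.30)


@pytest.fixture()
def mm1():
    """Large dense sphere: 34.6 um, 10 nA m^2."""
    return MagneticSphere(diameter=34.6e-6, moment_magnitude=1e-8)


@pytest.fixture()
def mm2():
    """Red-blood-cell-sized sphere: 5.7 um, 80 pA m^2."""
    return MagneticSphere(diameter=5.7e-6, moment_magnitude=80e-12)


@pytest.fixture(scope="session")
def fov_array():
    """147-channel planar triaxial array over the 15 x 20 cm field of view."""
    return make_planar_array(7, 7, 0.15, 0.20, 0.035, triaxial=True,
                             noise_density=3e-15)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
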