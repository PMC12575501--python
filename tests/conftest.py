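import numpy as np
import pytest

from fevarsim import generate_aorta_centerline, generate_patient, generate_renal_branch


@pytest.fixture(scope="session")
def straight_aorta():
    return generate_aorta_centerline(200.0, 10.0, 0.0, 201, 0)


@pytest.fixture(scope="session")
def tortuous_aorta():
    return generate_aorta_centerline(200.0, 10.0, 2.0, 201, 42)


@pytest.fixture(scope="session")
def patient():
    return generate_patient(7)


@pytest.fixture(scope="session")
def straight_branch(straight_aorta):
    """Perpendicular, zero-curvature renal branch: angles are exact."""
    return generate_renal_branch(straight_aorta, "right", 90.0, 40.0, 3.0, 0.0, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """Uniform-ish random proper rotation matrix."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
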