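import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from icediag import SyntheticSpec, UnitCell, generate_clean


@pytest.fixture(scope="session")
def clean_set():
    """One default synthetic dataset, shared across tests."""
    return generate_clean(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def small_cell():
    return UnitCell(10.0, 12.0, 14.0, 90.0, 90.0, 90.0)


def brute_force_reciprocal_d(a, b, c, alpha, beta, gamma, h, k, l):
    """Independent d-spacing oracle: build real basis vectors, invert to
    the reciprocal basis, and measure |h a* + k b* + l c*|."""
    al, be, ga = np.radians([alpha, beta, gamma])
    va = np.array([a, 0.0, 0.0])
    vb = np.array([b * np.cos(ga), b * np.sin(ga), 0.0])
    cx = c * np.cos(be)
    cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
    cz = np.sqrt(max(c * c - cx * cx - cy * cy, 0.0))
    vc = np.array([cx, cy, cz])
    A = np.stack([va, vb, vc])  # rows are basis vectors
    recip = np.linalg.inv(A).T  # rows are a*, b*, c*
    s = h * recip[0] + k * recip[1] + l * recip[2]
    return 1.0 / np.linalg.norm(s)
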