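import numpy as np
import pytest

from condylometry.morphometry import measure_mandible
from condylometry.synthgen import PhantomSpec, generate_mandible_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default mandible phantom: (mesh, landmarks, ground_truth)."""
    return generate_mandible_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_measurement(default_phantom):
    mesh, landmarks, _ = default_phantom
    return measure_mandible(mesh, landmarks)


def random_rotation(seed: int) -> np.ndarray:
    """A uniformly random proper rotation matrix (for invariance tests)."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
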