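import numpy as np
import pytest

from lvemu.constitutive import (
    DEFAULT_ACTIVE,
    DEFAULT_PASSIVE,
    Kinematics,
)


def random_kinematics(rng, scale=0.12):
    """Admissible random deformation state with orthonormal f0, s0."""
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.3:
            break
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    return Kinematics(F=F, f0=q[:, 0], s0=q[:, 1])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def passive():
    return DEFAULT_PASSIVE


@pytest.fixture(scope="session")
def active():
    return DEFAULT_ACTIVE


@pytest.fixture(scope="session")
def small_pv_ensemble():
    """Small deterministic pressure/volume ensemble shared across tests."""
    from lvemu.ensembles import generate_pv_ensemble

    return generate_pv_ensemble(n_models=6, seed=7)


@pytest.fixture(scope="session")
def small_stress_ensemble():
    from lvemu.ensembles import generate_stress_ensemble

    return generate_stress_ensemble(n_models=8, seed=7)
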