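import numpy as np
import pytest

from osteomatch import (
    Assemblage,
    BoneType,
    LandmarkConfiguration,
    Side,
    SimulationParams,
    generate_assemblage,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_config(
    rng,
    specimen_id="SPEC1",
    bone_type=BoneType.ACETABULUM,
    side=Side.RIGHT,
    scale=30.0,
):
    """A random, well-conditioned 11-landmark configuration."""
    coords = rng.normal(0.0, scale, size=(11, 3))
    return LandmarkConfiguration(specimen_id, bone_type, side, coords)


@pytest.fixture
def random_config(rng):
    return make_config(rng)


@pytest.fixture
def zero_noise_assemblage():
    """10 simulated individuals with no digitization noise, with truth."""
    params = SimulationParams(n_individuals=10, digitization_sd=0.0, seed=7)
    return generate_assemblage(params)


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q
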