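import numpy as np
import pytest

from lrpath.toy import (
    ToyTransporterSpec,
    build_double_basin_spec,
    build_reference_states,
)


@pytest.fixture(scope="session")
def toy_spec():
    return ToyTransporterSpec()


@pytest.fixture(scope="session")
def reference_pair(toy_spec):
    return build_reference_states(toy_spec)


@pytest.fixture(scope="session")
def double_basin(reference_pair):
    return build_double_basin_spec(reference_pair)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def numerical_gradient(term, coords, eps=1e-6):
    """Central-difference force oracle for any energy term."""
    num = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for d in range(3):
            xp = coords.copy()
            xp[i, d] += eps
            ep, _ = term.energy_forces(xp)
            xp[i, d] -= 2 * eps
            em, _ = term.energy_forces(xp)
            num[i, d] = -(ep - em) / (2 * eps)
    return num
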