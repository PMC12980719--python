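import numpy as np
import pytest
from hypothesis import settings

from tsmode.fixtures import (EQUILIBRIUM_NAMES, MODEL_TS_KINDS,
                             make_equilibrium_molecule, make_model_ts)

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(params=MODEL_TS_KINDS)
def model_ts(request):
    return make_model_ts(request.param)


@pytest.fixture
def sn2():
    return make_model_ts("sn2")


@pytest.fixture
def rotation_ts():
    return make_model_ts("rotation")


@pytest.fixture
def inversion_ts():
    return make_model_ts("inversion")


@pytest.fixture(params=EQUILIBRIUM_NAMES)
def equilibrium(request):
    geom, ref = make_equilibrium_molecule(request.param)
    return request.param, geom, ref
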