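import numpy as np
import pytest

from microsma import build_microplane_system, default_niti


@pytest.fixture(scope="session")
def params():
    return default_niti()


@pytest.fixture(scope="session")
def system42():
    return build_microplane_system("bazant_oh_42")


@pytest.fixture(scope="session")
def dense_system():
    return build_microplane_system("dense_grid", (64, 128))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_symmetric(rng, scale=100.0):
    a = rng.normal(size=(3, 3)) * scale
    return 0.5 * (a + a.T)


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
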