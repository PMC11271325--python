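import numpy as np
import pytest

from octavad.synthetic_data import default_config, generate_eye


@pytest.fixture(scope="session")
def small_eye():
    """One deterministic 128 px phantom eye with a CC/choroid deficit."""
    cfg = default_config(seed=7, shape=(128, 128),
                         lesion_deficit={"CC": 0.27, "CHOROID": 0.41})
    return generate_eye(cfg)


@pytest.fixture(scope="session")
def null_eye():
    """One deterministic 128 px phantom eye with no deficit anywhere."""
    return generate_eye(default_config(seed=11, shape=(128, 128)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def disk_mask(shape, center, radius):
    R, C = np.ogrid[: shape[0], : shape[1]]
    return np.hypot(R - center[0], C - center[1]) <= radius


@pytest.fixture
def make_disk():
    return disk_mask
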