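import numpy as np
import pytest


def random_rotation(seed: int) -> np.ndarray:
    """Uniform proper rotation for rigid-motion tests."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
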