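import numpy as np
import pytest

from ddacl.synthetic_data import default_fixture


@pytest.fixture(scope="session")
def fixture_bundle():
    """The default planted-block dataset (60 drugs x 40 diseases, seed 7)."""
    return default_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def finite_difference_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar-valued f at x (dense)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
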