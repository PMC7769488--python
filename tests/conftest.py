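import numpy as np
import pytest

from gaitfda.types import GRID


@pytest.fixture(scope="session")
def grid():
    return GRID


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_curve_set(rng, n, mean=0.0, sd=1.0, m=101):
    """Smooth-ish random curves on the cycle grid."""
    base = rng.normal(mean, sd, size=(n, m))
    k = np.exp(-0.5 * (np.arange(-6, 7) / 2.0) ** 2)
    k /= k.sum()
    return np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 1, base)
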