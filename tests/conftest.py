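import numpy as np
import pytest

from fwtract.gradients import make_gradient_scheme


@pytest.fixture(scope="session")
def scheme():
    """The default two-series single-shell scheme: per series, b0 volume(s)
    plus 21 half-sphere directions and their 21 antipodes at b=1000."""
    return make_gradient_scheme(21, 1000.0, 2)


@pytest.fixture(scope="session")
def small_scheme():
    return make_gradient_scheme(6, 1000.0, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20201120)


def random_spd_tensor(rng, scale=1e-3):
    """Random symmetric positive-definite tensor with WM-like diffusivities."""
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    lam = rng.uniform(0.2, 1.8, 3) * scale
    return (Q * lam) @ Q.T
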