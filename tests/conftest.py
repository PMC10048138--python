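import numpy as np
import pytest

from myinet.phantom import PhantomParams, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """Phantom parameters at 64x64, the desk-scale working resolution."""
    return PhantomParams.default(64)


@pytest.fixture
def small_phantom(small_params):
    return generate_phantom(small_params, seed=5)


def numeric_gradient(f, x, eps=1e-6):
    """Central finite-difference gradient of scalar f() w.r.t. array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
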