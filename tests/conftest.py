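import numpy as np
import pytest

from csfrohf.integrals import model_hamiltonian


def random_integral_set(rng, n_basis, n_electrons, scale=1.0):
    """Random symmetric h and 8-fold symmetric ERI on an orthonormal basis."""
    h = rng.normal(size=(n_basis, n_basis), scale=scale)
    h = 0.5 * (h + h.T)
    eri = rng.normal(size=(n_basis,) * 4, scale=scale)
    eri = eri + eri.transpose(1, 0, 2, 3)
    eri = eri + eri.transpose(0, 1, 3, 2)
    eri = eri + eri.transpose(2, 3, 0, 1)
    return model_hamiltonian(h, eri, rng.normal(), n_electrons)


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)
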