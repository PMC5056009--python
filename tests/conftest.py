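import numpy as np
import pytest

import sparsesense as ss


@pytest.fixture(scope="session")
def small_ds():
    """32x32, 4 coils, 4-fold variable-density undersampling, 30 dB."""
    return ss.make_dataset(ny=32, nx=32, ncoils=4, factor=4, snr_db=30.0, seed=0)


@pytest.fixture(scope="session")
def small_problem(small_ds):
    A = ss.SenseOperator(small_ds.sens, small_ds.mask)
    D = ss.FiniteDifference("tv", "periodic")
    return ss.ReconProblem(A=A, D=D, y=small_ds.kspace, lam=1.0e3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_complex(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
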