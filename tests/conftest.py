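import numpy as np
import pytest

from squigglecall import simdata


@pytest.fixture(scope="session")
def pore_model():
    return simdata.PoreModel.from_seed(7)


@pytest.fixture(scope="session")
def small_read(pore_model):
    """A 300-base simulated read with ground truth."""
    basis = simdata.generate_kmer_basis(12, seed=7)
    ref = simdata.generate_reference(basis, 300, seed=8)
    return simdata.simulate_signal(ref, pore_model, seed=9, read_id="r0")


@pytest.fixture
def rng():
    return np.random.default_rng(123)
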