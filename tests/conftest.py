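import numpy as np
import pytest
from hypothesis import settings

import pchbmc as pm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hubbard2():
    basis, ints = pm.gen_hubbard_chain(2, t=1.0, u=4.0)
    return basis, ints


@pytest.fixture(scope="session")
def hubbard4():
    basis, ints = pm.gen_hubbard_chain(4, t=1.0, u=4.0)
    return basis, ints


@pytest.fixture(scope="session")
def local3():
    """3 spatial orbitals, 4 electrons, S_z = 0: small enough for exhaustive
    path enumeration, with nonzero singles *and* doubles couplings."""
    basis, ints = pm.gen_local_integrals(3, 4, decay_len=1.5, seed=11, ms2=0)
    return basis, ints


@pytest.fixture(scope="session")
def local3_tables(local3):
    return pm.build_tables(*local3)


@pytest.fixture(scope="session")
def hubbard4_tables(hubbard4):
    return pm.build_tables(*hubbard4)


@pytest.fixture(scope="session")
def local3_dets(local3):
    from pchbmc.oracle import enumerate_determinants

    basis, _ = local3
    return enumerate_determinants(basis.n_spatial, basis.n_elec, basis.ms2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
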