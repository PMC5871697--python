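import numpy as np
import pytest

from qmmkit import basis_integrals as bi
from qmmkit.geometry import QMGeometry
from qmmkit.ks_dft import scf_solve

# fixed reference geometries (bohr)
H2O_COORDS = [[0.0, 0.0, 0.2217], [0.0, 1.4309, -0.8867], [0.0, -1.4309, -0.8867]]
H2_COORDS = [[0.0, 0.0, 0.0], [0.0, 0.0, 1.4]]


@pytest.fixture(scope="session")
def h2_geom():
    return QMGeometry(["H", "H"], H2_COORDS)


@pytest.fixture(scope="session")
def h2o_geom():
    return QMGeometry(["O", "H", "H"], H2O_COORDS)


@pytest.fixture(scope="session")
def sto3g():
    return bi.load_bundled_basis("sto-3g")


@pytest.fixture(scope="session")
def dzvp():
    return bi.load_bundled_basis("dzvp")


@pytest.fixture(scope="session")
def h2_basis(h2_geom, sto3g):
    return bi.BasisSet.from_library(sto3g, h2_geom)


@pytest.fixture(scope="session")
def h2o_basis(h2o_geom, sto3g):
    return bi.BasisSet.from_library(sto3g, h2o_geom)


@pytest.fixture(scope="session")
def h2o_scf_lda(h2o_geom, h2o_basis):
    state = scf_solve(h2o_geom, h2o_basis, "lda", grid="coarse")
    assert state.converged
    return state


@pytest.fixture(scope="session")
def h2o_scf_pbe_fine(h2o_geom, h2o_basis):
    state = scf_solve(h2o_geom, h2o_basis, "pbe", grid="fine")
    assert state.converged
    return state


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260903)
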