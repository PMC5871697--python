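"""Gaussian basis handling and analytic one-/two-electron integrals."""

from importlib.resources import files as _files

from .boys import boys
from .eri import ERITensor, eri_tensor, schwarz_bounds
from .gaussian94 import BasisParseError, load_basis, parse_gaussian94
from .oneelectron import (
    DipoleMatrices,
    OneElectronMatrices,
    charge_attraction_matrix,
    core_hamiltonian,
    dipole_matrices,
    kinetic_matrix,
    nuclear_attraction_matrix,
    overlap_matrix,
)
from .shells import BasisSet, GaussianShell, cart_components, ncart

_BUNDLED = {"sto-3g": "sto-3g.gbs", "dzvp": "dzvp.gbs", "6-31g": "6-31g.gbs"}


def bundled_basis_path(name: str):
    """Path to a basis file shipped with the package (sto-3g, dzvp, 6-31g)."""
    key = name.lower()
    if key not in _BUNDLED:
        raise KeyError(f"no bundled basis {name!r}; available: {sorted(_BUNDLED)}")
    return _files("qmmkit").joinpath("data", "basis", _BUNDLED[key])


def load_bundled_basis(name: str, elements=None) -> dict:
    return load_basis(bundled_basis_path(name), elements)


__all__ = [
    "BasisSet", "GaussianShell", "ERITensor", "OneElectronMatrices",
    "DipoleMatrices", "BasisParseError", "boys", "cart_components", "ncart",
    "load_basis", "parse_gaussian94", "load_bundled_basis", "bundled_basis_path",
    "overlap_matrix", "kinetic_matrix", "charge_attraction_matrix",
    "nuclear_attraction_matrix", "dipole_matrices", "core_hamiltonian",
    "eri_tensor", "schwarz_bounds",
]
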