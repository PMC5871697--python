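"""Restricted Kohn-Sham SCF with DIIS.

Core-Hamiltonian initial guess, Pulay DIIS on the orthonormal-basis
commutator FPS - SPF (subspace 8), symmetric orthogonalization with a
linear-dependence cutoff on the overlap spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..basis_integrals import core_hamiltonian, eri_tensor
from ..basis_integrals.eri import ERITensor
from ..basis_integrals.shells import BasisSet
from ..geometry import QMGeometry
from .grid import DFTGrid, eval_basis, grid_from_preset
from .xc import XCFunctionalSpec, eval_xc

logger = logging.getLogger(__name__)

LINDEP_CUTOFF = 1e-7


class SCFConvergenceError(RuntimeError):
    pass


@dataclass
class SCFState:
    density_matrix: np.ndarray
    mo_coefficients: np.ndarray
    orbital_energies: np.ndarray
    fock_matrix: np.ndarray
    overlap: np.ndarray
    core_hamiltonian: np.ndarray
    energy_components: dict
    energy: float
    converged: bool
    iterations: int
    basis: BasisSet = None
    grid: DFTGrid = None
    functional: XCFunctionalSpec = None
    eri: ERITensor = None
    basis_on_grid: tuple = None

    @property
    def n_electrons(self) -> float:
        return float(np.einsum("ij,ji->", self.density_matrix, self.overlap))


class GridXC:
    """Precomputed basis values on a grid; evaluates Exc and Vxc."""

    def __init__(self, basis: BasisSet, grid: DFTGrid, functional: XCFunctionalSpec):
        self.grid = grid
        self.functional = functional
        self.phi, self.dphi = eval_basis(basis, grid.points, gradients=True)
        self.w = grid.weights

    def density_on_grid(self, P: np.ndarray):
        phi = self.phi
        t = phi @ P
        rho = np.einsum("pi,pi->p", t, phi)
        grad = np.empty((3, len(rho)))
        for ax in range(3):
            grad[ax] = 2.0 * np.einsum("pi,pi->p", t, self.dphi[ax])
        return rho, grad

    def exc_and_vxc(self, P: np.ndarray):
        rho, grad = self.density_on_grid(P)
        sigma = np.einsum("ap,ap->p", grad, grad)
        exc, vrho, vsigma = eval_xc(rho, sigma, self.functional)
        Exc = float(np.sum(self.w * rho * exc))
        wa = self.w * vrho
        V = (self.phi * wa[:, None]).T @ self.phi
        if self.functional.is_gga:
            # 2 vsigma grad(rho) . (phi_m grad phi_n + phi_n grad phi_m)
            for ax in range(3):
                wb = 2.0 * self.w * vsigma * grad[ax]
                M = (self.phi * wb[:, None]).T @ self.dphi[ax]
                V += M + M.T
        V = 0.5 * (V + V.T)
        return Exc, V, rho

    def integrate_density(self, P: np.ndarray) -> float:
        rho, _ = self.density_on_grid(P)
        return float(np.sum(self.w * rho))


def orthogonalizer(S: np.ndarray, cutoff: float = LINDEP_CUTOFF) -> np.ndarray:
    """S^{-1/2} on the subspace with overlap eigenvalues above cutoff."""
    vals, vecs = np.linalg.eigh(S)
    if vals[-1] <= 0:
        raise np.linalg.LinAlgError("overlap matrix not positive definite")
    keep = vals > cutoff
    if not np.all(keep):
        logger.warning(
            "dropping %d near-linear-dependent overlap eigenvectors "
            "(min eigenvalue %.3e); consider raising the cutoff",
            int((~keep).sum()), float(vals[0]),
        )
    return vecs[:, keep] / np.sqrt(vals[keep])


def density_from_mos(C: np.ndarray, nocc: int) -> np.ndarray:
    occ = C[:, :nocc]
    return 2.0 * occ @ occ.T


def build_fock(P, hcore, eri: ERITensor, gridxc: GridXC):
    """F = Hcore + J[P] + Vxc[P]; returns (F, coulomb energy, Exc)."""
    if P.shape != hcore.shape:
        raise ValueError("dimension mismatch between density and core Hamiltonian")
    J = eri.coulomb(P)
    Exc, Vxc, _ = gridxc.exc_and_vxc(P)
    F = hcore + J + Vxc
    Ecoul = 0.5 * float(np.einsum("ij,ji->", P, J))
    return F, Ecoul, Exc


def scf_solve(
    geometry: QMGeometry,
    basis: BasisSet,
    functional: XCFunctionalSpec | str = "pbe",
    grid: DFTGrid | str = "default",
    embedding_matrix: np.ndarray | None = None,
    conv_energy: float = 1e-8,
    conv_diis: float = 1e-6,
    max_iter: int = 100,
    eri: ERITensor | None = None,
    screening_threshold: float = 1e-10,
    diis_size: int = 8,
    damping: float = 0.4,
    damp_threshold: float = 0.1,
    level_shift: float = 0.0,
    initial_density: np.ndarray | None = None,
) -> SCFState:
    """Converge a closed-shell Kohn-Sham SCF.

    ``embedding_matrix``, when given, is added to the core Hamiltonian
    (electrostatic embedding of MM point charges).  Convergence demands
    both |dE| < conv_energy and ||FPS-SPF|| (orthonormal basis, max-abs)
    < conv_diis.
    """
    if isinstance(functional, str):
        functional = XCFunctionalSpec(functional)
    if isinstance(grid, str):
        grid = grid_from_preset(geometry, grid)
    nelec = geometry.n_electrons
    if nelec % 2 != 0:
        raise ValueError("open-shell systems are not supported (odd electron count)")
    nocc = nelec // 2

    hcore, one_e = core_hamiltonian(basis)
    S = one_e.overlap
    if embedding_matrix is not None:
        hcore = hcore + embedding_matrix
    if eri is None:
        eri = eri_tensor(basis, screening_threshold)
    gridxc = GridXC(basis, grid, functional)
    X = orthogonalizer(S)

    if initial_density is not None:
        P = np.asarray(initial_density, dtype=float)
        if P.shape != S.shape:
            raise ValueError("initial density has wrong dimensions")
        C = np.zeros_like(S)
    else:
        # core-Hamiltonian guess
        e, c = np.linalg.eigh(X.T @ hcore @ X)
        C = X @ c
        P = density_from_mos(C, nocc)

    enuc = geometry.nuclear_repulsion()
    e_old = 0.0
    diis_F, diis_err = [], []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        F, Ecoul, Exc = build_fock(P, hcore, eri, gridxc)
        err = X.T @ (F @ P @ S - S @ P @ F) @ X
        err_norm = np.max(np.abs(err))

        diis_F.append(F.copy())
        diis_err.append(err.ravel())
        if len(diis_F) > diis_size:
            diis_F.pop(0)
            diis_err.pop(0)
        if len(diis_F) > 1:
            F = _diis_extrapolate(diis_F, diis_err)

        F_orth = X.T @ F @ X
        if level_shift > 0.0 and err_norm > damp_threshold:
            # push virtuals up while the density is still sloshing
            P_orth = X.T @ (S @ P @ S) @ X
            F_orth = F_orth + level_shift * (
                np.eye(F_orth.shape[0]) - 0.5 * P_orth
            )
        e_mo, c = np.linalg.eigh(F_orth)
        C = X @ c
        P_new = density_from_mos(C, nocc)
        # damp the density while far from convergence; undamped once the
        # DIIS error is small enough for extrapolation to be reliable
        if err_norm > damp_threshold:
            P = damping * P_new + (1.0 - damping) * P
        else:
            P = P_new

        e_elec = float(np.einsum("ij,ji->", P, hcore)) + Ecoul + Exc
        e_tot = e_elec + enuc
        de = e_tot - e_old
        logger.info(
            "SCF iter %3d  E=%.10f  dE=%+.3e  |err|=%.3e", it, e_tot, de, err_norm
        )
        if abs(de) < conv_energy and err_norm < conv_diis:
            converged = True
            break
        e_old = e_tot

    F_final, Ecoul, Exc = build_fock(P, hcore, eri, gridxc)
    e_one = float(np.einsum("ij,ji->", P, hcore))
    e_kin = float(np.einsum("ij,ji->", P, one_e.kinetic))
    e_nuc_attr = float(np.einsum("ij,ji->", P, one_e.charge_attraction))
    e_embed = (
        float(np.einsum("ij,ji->", P, embedding_matrix))
        if embedding_matrix is not None
        else 0.0
    )
    components = {
        "kinetic": e_kin,
        "electron_nuclear": e_nuc_attr,
        "coulomb": Ecoul,
        "xc": Exc,
        "nuclear_repulsion": enuc,
        "embedding_electronic": e_embed,
    }
    e_tot = e_one + Ecoul + Exc + enuc
    state = SCFState(
        density_matrix=P,
        mo_coefficients=C,
        orbital_energies=e_mo,
        fock_matrix=F_final,
        overlap=S,
        core_hamiltonian=hcore,
        energy_components=components,
        energy=e_tot,
        converged=converged,
        iterations=it,
        basis=basis,
        grid=grid,
        functional=functional,
        eri=eri,
        basis_on_grid=(gridxc.phi, gridxc.dphi),
    )
    if not converged:
        logger.warning(
            "SCF did not converge in %d iterations (dE=%.3e, |err|=%.3e)",
            max_iter, de, err_norm,
        )
    return state


def _diis_extrapolate(fock_list, err_list):
    n = len(fock_list)
    B = -np.ones((n + 1, n + 1))
    B[n, n] = 0.0
    for i in range(n):
        for j in range(n):
            B[i, j] = float(np.dot(err_list[i], err_list[j]))
    rhs = np.zeros(n + 1)
    rhs[n] = -1.0
    try:
        coef = np.linalg.solve(B, rhs)[:n]
    except np.linalg.LinAlgError:
        return fock_list[-1]
    F = np.zeros_like(fock_list[0])
    for c, Fi in zip(coef, fock_list):
        F += c * Fi
    return F
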