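"""Electrostatic-embedding QM/MM energies and forces.

Total-energy decomposition: E = E_QM + E_MM + E_QM-MM, where E_QM-MM
collects the electron/point-charge embedding term, QM/MM Lennard-Jones,
and the nucleus/point-charge Coulomb sum.  E_QM is the Kohn-Sham energy
evaluated at the MM-polarized density (the polarization energy therefore
lives in E_QM by this convention, which is documented rather than
implied).  Non-periodic clusters; spherical cutoff for MM-MM terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..basis_integrals import charge_attraction_matrix
from ..basis_integrals.shells import BasisSet
from ..constants import BOHR_PER_ANGSTROM
from ..geometry import QMGeometry
from ..ks_dft import scf_solve
from ..ks_dft.xc import XCFunctionalSpec
from .region import MMRegion

MIN_QM_MM_DIST = 0.1  # bohr, overlap guard
DEFAULT_CUTOFF = 12.0 * BOHR_PER_ANGSTROM


@dataclass
class QMMMSystem:
    geometry: QMGeometry
    basis: BasisSet
    mm: MMRegion
    qm_lj_epsilon: np.ndarray = None  # Hartree, one per QM atom
    qm_lj_sigma: np.ndarray = None  # bohr
    functional: XCFunctionalSpec = XCFunctionalSpec("pbe")
    grid_preset: str = "default"
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        n = self.geometry.natoms
        if self.qm_lj_epsilon is None:
            self.qm_lj_epsilon = np.zeros(n)
        if self.qm_lj_sigma is None:
            self.qm_lj_sigma = np.ones(n)
        self.qm_lj_epsilon = np.asarray(self.qm_lj_epsilon, dtype=float).reshape(n)
        self.qm_lj_sigma = np.asarray(self.qm_lj_sigma, dtype=float).reshape(n)
        if self.mm.nsites:
            d = np.linalg.norm(
                self.geometry.coordinates[:, None, :] - self.mm.coordinates[None, :, :],
                axis=2,
            )
            if d.min() < MIN_QM_MM_DIST:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(
                    f"QM atom {i} and MM site {j} are {d.min():.3f} bohr apart "
                    f"(guard: {MIN_QM_MM_DIST} bohr)"
                )


@dataclass
class EnergyReport:
    e_qm: float
    e_mm: float
    e_qmmm_embedding: float
    e_qmmm_lj: float
    e_qmmm_nuc_charge: float
    scf_state: object = None

    @property
    def e_qmmm(self) -> float:
        return self.e_qmmm_embedding + self.e_qmmm_lj + self.e_qmmm_nuc_charge

    @property
    def total(self) -> float:
        return self.e_qm + self.e_mm + self.e_qmmm


def embedding_core_update(basis: BasisSet, mm: MMRegion) -> np.ndarray:
    """One-electron matrix added to Hcore by the MM point charges."""
    if mm.nsites == 0:
        return np.zeros((basis.nbf, basis.nbf))
    charges = [(q, r) for q, r in zip(mm.charges, mm.coordinates)]
    return charge_attraction_matrix(basis, charges)


def lj_energy_forces(coords_a, eps_a, sig_a, coords_b, eps_b, sig_b, cutoff=None):
    """Lennard-Jones between two site sets, Lorentz-Berthelot combining.

    Returns (energy, forces_on_a, forces_on_b); forces are -dE/dR.
    """
    coords_a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    coords_b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    eps_a = np.asarray(eps_a, dtype=float)
    sig_a = np.asarray(sig_a, dtype=float)
    eps_b = np.asarray(eps_b, dtype=float)
    sig_b = np.asarray(sig_b, dtype=float)
    e = 0.0
    fa = np.zeros_like(coords_a)
    fb = np.zeros_like(coords_b)
    for i in range(coords_a.shape[0]):
        if eps_a[i] == 0.0:
            continue
        dr = coords_a[i] - coords_b  # (nb, 3)
        r = np.linalg.norm(dr, axis=1)
        eps = np.sqrt(eps_a[i] * eps_b)
        sig = 0.5 * (sig_a[i] + sig_b)
        act = eps > 0
        if cutoff is not None:
            act &= r < cutoff
        if not act.any():
            continue
        sr6 = (sig[act] / r[act]) ** 6
        e += float(np.sum(4.0 * eps[act] * (sr6**2 - sr6)))
        # dE/dr = 4 eps (-12 sr12 + 6 sr6)/r
        dedr = 4.0 * eps[act] * (-12.0 * sr6**2 + 6.0 * sr6) / r[act]
        fvec = -dedr[:, None] * dr[act] / r[act][:, None]
        fa[i] += fvec.sum(axis=0)
        fb[act] -= fvec
    return e, fa, fb


def lj_qmmm(system: QMMMSystem, cutoff: float | None = None):
    """QM/MM Lennard-Jones energy and forces."""
    if system.mm.nsites == 0:
        return 0.0, np.zeros_like(system.geometry.coordinates), np.zeros((0, 3))
    e, fq, fm = lj_energy_forces(
        system.geometry.coordinates, system.qm_lj_epsilon, system.qm_lj_sigma,
        system.mm.coordinates, system.mm.lj_epsilon, system.mm.lj_sigma,
        cutoff,
    )
    return e, fq, fm


def coulomb_nuc_mm(z_values, z_coords, q_values, q_coords):
    """Pairwise Z_I q_A / |R_I - R_A| energy and forces (no cutoff)."""
    z_coords = np.atleast_2d(z_coords)
    q_coords = np.atleast_2d(q_coords)
    z_values = np.atleast_1d(z_values)
    q_values = np.atleast_1d(q_values)
    e = 0.0
    fz = np.zeros_like(z_coords, dtype=float)
    fq = np.zeros_like(q_coords, dtype=float)
    for i in range(z_coords.shape[0]):
        dr = z_coords[i] - q_coords
        r = np.linalg.norm(dr, axis=1)
        if np.any(r < 1e-10):
            raise ValueError(f"nucleus {i} coincides with a point charge")
        pref = z_values[i] * q_values / r
        e += float(pref.sum())
        fvec = (pref / r**2)[:, None] * dr
        fz[i] += fvec.sum(axis=0)
        fq -= fvec
    return e, fz, fq


def mm_energy(mm: MMRegion, cutoff: float | None = DEFAULT_CUTOFF):
    """Intermolecular MM energy (Coulomb + LJ) and forces.

    Rigid monomers: pairs sharing a molecule_id are excluded.  The
    cutoff applies per site pair (plain truncation, no Ewald).
    """
    n = mm.nsites
    forces = np.zeros((n, 3))
    if n < 2:
        return 0.0, forces
    e = 0.0
    for i in range(n - 1):
        dr = mm.coordinates[i] - mm.coordinates[i + 1:]
        r = np.linalg.norm(dr, axis=1)
        act = mm.molecule_id[i + 1:] != mm.molecule_id[i]
        if cutoff is not None:
            act &= r < cutoff
        if not act.any():
            continue
        rr = r[act]
        drr = dr[act]
        qq = mm.charges[i] * mm.charges[i + 1:][act]
        e += float(np.sum(qq / rr))
        fvec = (qq / rr**3)[:, None] * drr
        eps = np.sqrt(mm.lj_epsilon[i] * mm.lj_epsilon[i + 1:][act])
        sig = 0.5 * (mm.lj_sigma[i] + mm.lj_sigma[i + 1:][act])
        ljmask = eps > 0
        if ljmask.any():
            sr6 = (sig[ljmask] / rr[ljmask]) ** 6
            e += float(np.sum(4.0 * eps[ljmask] * (sr6**2 - sr6)))
            dedr = 4.0 * eps[ljmask] * (-12.0 * sr6**2 + 6.0 * sr6) / rr[ljmask]
            fvec[ljmask] += -dedr[:, None] * drr[ljmask] / rr[ljmask][:, None]
        forces[i] += fvec.sum(axis=0)
        idx = np.flatnonzero(act) + i + 1
        forces[idx] -= fvec
    return e, forces


def total_energy(system: QMMMSystem, scf_kwargs: dict | None = None) -> EnergyReport:
    """Assemble the three-term QM/MM energy with embedding SCF."""
    scf_kwargs = dict(scf_kwargs or {})
    vemb = embedding_core_update(system.basis, system.mm) if system.mm.nsites else None
    state = scf_solve(
        system.geometry, system.basis, system.functional,
        grid=scf_kwargs.pop("grid", system.grid_preset),
        embedding_matrix=vemb, **scf_kwargs,
    )
    if not state.converged:
        raise RuntimeError("embedding SCF did not converge")
    e_embed = state.energy_components["embedding_electronic"]
    e_qm = state.energy - e_embed
    e_lj, _, _ = lj_qmmm(system)
    if system.mm.nsites:
        e_zq, _, _ = coulomb_nuc_mm(
            system.geometry.atomic_numbers.astype(float),
            system.geometry.coordinates,
            system.mm.charges, system.mm.coordinates,
        )
    else:
        e_zq = 0.0
    e_mm, _ = mm_energy(system.mm, system.cutoff)
    return EnergyReport(e_qm, e_mm, e_embed, e_lj, e_zq, state)


def forces(system: QMMMSystem, mode: str = "fd", step: float = 1e-3,
           scf_kwargs: dict | None = None) -> np.ndarray:
    """Forces (-dE/dR) on QM atoms and MM sites, shape (nqm + nmm, 3).

    mode "fd": central differences of the full total energy with SCF
    reconvergence at each displaced geometry.  Robust at desk scale and
    free of Pulay-term bookkeeping; analytic classical-term forces are
    available separately via lj_qmmm / coulomb_nuc_mm / mm_energy.
    """
    nq = system.geometry.natoms
    nm = system.mm.nsites
    if mode == "fd":
        f = np.zeros((nq + nm, 3))
        for i in range(nq + nm):
            for ax in range(3):
                f[i, ax] = -_fd_energy_derivative(system, i, ax, step, scf_kwargs)
        return f
    raise ValueError(f"unknown force mode {mode!r}")


def _displaced(system: QMMMSystem, i: int, ax: int, h: float) -> QMMMSystem:
    nq = system.geometry.natoms
    geom = system.geometry
    mm = system.mm
    if i < nq:
        coords = geom.coordinates.copy()
        coords[i, ax] += h
        geom = QMGeometry(list(geom.symbols), coords, geom.total_charge)
        basis = BasisSet(
            [type(sh)(sh.center_index, sh.angular_momentum, sh.exponents,
                      sh.contraction_coefficients) for sh in system.basis.shells],
            geom,
        )
    else:
        coords = mm.coordinates.copy()
        coords[i - nq, ax] += h
        mm = MMRegion(coords, mm.charges, mm.lj_epsilon, mm.lj_sigma, mm.molecule_id)
        basis = system.basis
    return QMMMSystem(
        geom, basis, mm, system.qm_lj_epsilon, system.qm_lj_sigma,
        system.functional, system.grid_preset, system.cutoff,
    )


def _fd_energy_derivative(system, i, ax, step, scf_kwargs):
    ep = total_energy(_displaced(system, i, ax, +step), scf_kwargs).total
    em = total_energy(_displaced(system, i, ax, -step), scf_kwargs).total
    return (ep - em) / (2.0 * step)
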