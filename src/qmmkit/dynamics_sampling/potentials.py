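"""Potential-energy backends for molecular dynamics.

Everything is in atomic units (bohr, Hartree, electron masses, a.u.
time).  A potential exposes ``energy_forces(positions) -> (E, F)``.
The QM/MM backend wraps the embedding SCF with finite-difference
forces; the analytic ones serve as fast, exactly differentiable test
systems.
"""

from __future__ import annotations

import numpy as np


class HarmonicBond:
    """E = 1/2 k (|r_i - r_j| - r0)^2."""

    def __init__(self, i: int, j: int, k: float, r0: float):
        self.i, self.j, self.k, self.r0 = i, j, k, r0

    def energy_forces(self, x: np.ndarray):
        d = x[self.i] - x[self.j]
        r = float(np.linalg.norm(d))
        e = 0.5 * self.k * (r - self.r0) ** 2
        f = np.zeros_like(x)
        g = self.k * (r - self.r0) * d / r
        f[self.i] -= g
        f[self.j] += g
        return e, f


class DoubleWell1D:
    """E = a (x^2 - b^2)^2 / b^4 on the x coordinate of particle 0.

    Barrier height at x=0 equals ``a``; minima at x = +-b.
    """

    def __init__(self, a: float, b: float):
        self.a, self.b = a, b

    def energy_forces(self, x: np.ndarray):
        q = float(x[0, 0])
        u = q * q - self.b * self.b
        e = self.a * u * u / self.b**4
        f = np.zeros_like(x)
        f[0, 0] = -4.0 * self.a * u * q / self.b**4
        return e, f

    def energy_1d(self, q):
        q = np.asarray(q, dtype=float)
        return self.a * (q * q - self.b**2) ** 2 / self.b**4


class Harmonic1D:
    """E = 1/2 k x^2 on the x coordinate of particle 0."""

    def __init__(self, k: float):
        self.k = k

    def energy_forces(self, x: np.ndarray):
        q = float(x[0, 0])
        f = np.zeros_like(x)
        f[0, 0] = -self.k * q
        return 0.5 * self.k * q * q, f


class LennardJonesCluster:
    """Pairwise LJ between all particles (single species)."""

    def __init__(self, epsilon: float, sigma: float):
        self.epsilon, self.sigma = epsilon, sigma

    def energy_forces(self, x: np.ndarray):
        n = x.shape[0]
        e = 0.0
        f = np.zeros_like(x)
        for i in range(n - 1):
            dr = x[i] - x[i + 1:]
            r = np.linalg.norm(dr, axis=1)
            sr6 = (self.sigma / r) ** 6
            e += float(np.sum(4.0 * self.epsilon * (sr6**2 - sr6)))
            dedr = 4.0 * self.epsilon * (-12.0 * sr6**2 + 6.0 * sr6) / r
            fvec = -dedr[:, None] * dr / r[:, None]
            f[i] += fvec.sum(axis=0)
            f[i + 1:] -= fvec
        return e, f


class QMMMPotential:
    """Born-Oppenheimer QM/MM surface; finite-difference SCF forces.

    Moves QM atoms only (MM frozen) unless ``move_mm`` is set.
    """

    def __init__(self, system, move_mm: bool = False, fd_step: float = 1e-3,
                 scf_kwargs: dict | None = None):
        from ..qmmm_coupling import QMMMSystem, forces, total_energy

        self.system = system
        self.move_mm = move_mm
        self.fd_step = fd_step
        self.scf_kwargs = scf_kwargs
        self._total_energy = total_energy
        self._forces = forces
        self._QMMMSystem = QMMMSystem

    def _with_positions(self, x: np.ndarray):
        s = self.system
        nq = s.geometry.natoms
        from ..geometry import QMGeometry
        from ..qmmm_coupling import MMRegion
        from ..basis_integrals.shells import BasisSet, GaussianShell

        geom = QMGeometry(list(s.geometry.symbols), x[:nq], s.geometry.total_charge)
        basis = BasisSet(
            [GaussianShell(sh.center_index, sh.angular_momentum, sh.exponents,
                           sh.contraction_coefficients) for sh in s.basis.shells],
            geom,
        )
        mm = s.mm
        if self.move_mm and s.mm.nsites:
            mm = MMRegion(x[nq:], s.mm.charges, s.mm.lj_epsilon, s.mm.lj_sigma,
                          s.mm.molecule_id)
        return self._QMMMSystem(geom, basis, mm, s.qm_lj_epsilon, s.qm_lj_sigma,
                                s.functional, s.grid_preset, s.cutoff)

    def energy_forces(self, x: np.ndarray):
        sys_here = self._with_positions(x)
        rep = self._total_energy(sys_here, self.scf_kwargs)
        f_full = self._forces(sys_here, "fd", self.fd_step, self.scf_kwargs)
        nq = sys_here.geometry.natoms
        if self.move_mm:
            return rep.total, f_full
        return rep.total, f_full[:nq]
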