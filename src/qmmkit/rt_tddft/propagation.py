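"""Real-time propagation of the one-electron density matrix.

The density evolves by i d(rho)/dt = [H, rho] (hbar = 1) in the
symmetrically orthonormalized basis.  Two integrators are provided: the
leapfrog commutator scheme rho(t+dt) = rho(t-dt) - 2 i dt [H(t), rho(t)]
and the first-order Magnus scheme, i.e. the truncated nested-commutator
expansion of exp(-i H dt) rho exp(+i H dt) with H taken at the midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..basis_integrals import dipole_matrices
from ..ks_dft.scf import GridXC, SCFState

DEFAULT_MAGNUS_ORDER = 30


@dataclass
class RTParams:
    dt: float  # a.u. time
    nsteps: int
    propagator: str = "magnus"  # or "verlet"
    magnus_order: int = DEFAULT_MAGNUS_ORDER
    kick_strength: float = 1e-3  # a.u. field impulse
    kick_direction: tuple = (0.0, 0.0, 1.0)
    damping_time_fs: float = 2.5
    frozen_hamiltonian: bool = False
    trace_tolerance: float = 1e-6

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.magnus_order < 2:
            raise ValueError("Magnus truncation order must be >= 2")
        if self.propagator not in ("magnus", "verlet"):
            raise ValueError(f"unknown propagator {self.propagator!r}")
        if self.kick_strength <= 0:
            raise ValueError("kick strength must be positive")


@dataclass
class RTState:
    rho: np.ndarray  # complex, orthonormal basis
    hamiltonian: np.ndarray
    time: float
    step: int


@dataclass
class DipoleTrace:
    times: np.ndarray
    mu: np.ndarray  # (nframes, 3), induced dipole (a.u.)
    params: RTParams = None
    energies: np.ndarray = None
    max_trace_drift: float = 0.0  # max |Tr(rho) - N| observed
    final_rho: np.ndarray = None  # orthonormal-basis density at the end


class TraceDriftError(RuntimeError):
    pass


def step_magnus(rho: np.ndarray, H: np.ndarray, dt: float,
                order: int = DEFAULT_MAGNUS_ORDER) -> np.ndarray:
    """Truncated commutator expansion of exp(-iHdt) rho exp(iHdt)."""
    if order < 2:
        raise ValueError("order must be >= 2")
    out = rho.copy()
    term = rho
    for k in range(1, order + 1):
        term = (-1j * dt / k) * (H @ term - term @ H)
        out += term
    return out


def step_verlet(rho_prev: np.ndarray, rho: np.ndarray, H: np.ndarray,
                dt: float) -> np.ndarray:
    """rho(t+dt) = rho(t-dt) - 2 i dt [H(t), rho(t)]."""
    return rho_prev - 2j * dt * (H @ rho - rho @ H)


class RTPropagator:
    """Ties a converged SCF to the time stepper; nuclei are fixed, so the
    ERI tensor and the basis values on the grid are computed once."""

    def __init__(self, scf_state: SCFState, params: RTParams,
                 dipole_origin=(0.0, 0.0, 0.0), gridxc: GridXC | None = None):
        if not scf_state.converged:
            raise ValueError("RT propagation requires a converged SCF state")
        self.params = params
        self.scf = scf_state
        S = scf_state.overlap
        vals, vecs = np.linalg.eigh(S)
        if vals.min() <= 1e-10:
            raise np.linalg.LinAlgError(
                "overlap nearly singular; RT propagation needs a full-rank basis"
            )
        self.X = (vecs * vals**-0.5) @ vecs.T  # S^{-1/2}, symmetric
        self.Xi = (vecs * vals**0.5) @ vecs.T  # S^{+1/2}
        self.hcore = scf_state.core_hamiltonian
        self.eri = scf_state.eri
        self.gridxc = gridxc if gridxc is not None else GridXC(
            scf_state.basis, scf_state.grid, scf_state.functional
        )
        self.dip = dipole_matrices(scf_state.basis, dipole_origin).as_array()
        self.nelec = scf_state.basis.geometry.n_electrons
        self.enuc = scf_state.basis.geometry.nuclear_repulsion()
        self.rho0 = self.Xi @ scf_state.density_matrix @ self.Xi
        self.H0 = self.X @ scf_state.fock_matrix @ self.X

    def fock_on(self, rho: np.ndarray) -> tuple[np.ndarray, float]:
        """Orthonormal-basis KS matrix rebuilt from rho, plus total energy."""
        P = np.real(self.X @ rho @ self.X)
        J = self.eri.coulomb(P)
        Exc, Vxc, _ = self.gridxc.exc_and_vxc(P)
        F = self.hcore + J + Vxc
        E = (
            float(np.einsum("ij,ji->", P, self.hcore))
            + 0.5 * float(np.einsum("ij,ji->", P, J))
            + Exc + self.enuc
        )
        return self.X @ F @ self.X, E

    def delta_kick(self, rho: np.ndarray, strength: float | None = None,
                   direction=None) -> np.ndarray:
        """Unitary field impulse: rho -> e^{i k D} rho e^{-i k D}."""
        strength = self.params.kick_strength if strength is None else strength
        direction = np.asarray(
            self.params.kick_direction if direction is None else direction, dtype=float
        )
        nrm = np.linalg.norm(direction)
        if nrm == 0:
            raise ValueError("kick direction must be a nonzero vector")
        direction = direction / nrm
        D_ao = np.einsum("a,aij->ij", direction, self.dip)
        D = self.X @ D_ao @ self.X
        w, V = np.linalg.eigh(D)
        U = (V * np.exp(1j * strength * w)) @ V.conj().T
        return U @ rho @ U.conj().T

    def dipole(self, rho: np.ndarray) -> np.ndarray:
        """Electronic dipole, -Tr(P D), per Cartesian component."""
        P = np.real(self.X @ rho @ self.X)
        return -np.einsum("aij,ji->a", self.dip, P)

    def propagate(self, kick: bool = True, record_energy: bool = False) -> DipoleTrace:
        p = self.params
        rho = self.rho0.astype(complex)
        if kick:
            rho = self.delta_kick(rho)
        mu_ref = self.dipole(self.rho0)
        frozen = p.frozen_hamiltonian

        times = np.empty(p.nsteps + 1)
        mus = np.empty((p.nsteps + 1, 3))
        energies = np.empty(p.nsteps + 1) if record_energy else None

        H, E = (self.H0, self.scf.energy) if frozen else self.fock_on(rho)
        times[0] = 0.0
        mus[0] = self.dipole(rho) - mu_ref
        if record_energy:
            energies[0] = E

        rho_prev = None
        H_prev = H
        max_drift = 0.0
        for istep in range(1, p.nsteps + 1):
            if p.propagator == "magnus":
                if frozen:
                    rho = step_magnus(rho, H, p.dt, p.magnus_order)
                else:
                    # predictor: extrapolate H to t+dt/2; corrector: midpoint avg
                    H_pred = 1.5 * H - 0.5 * H_prev
                    rho_pred = step_magnus(rho, H_pred, p.dt, p.magnus_order)
                    H_next, _ = self.fock_on(rho_pred)
                    H_mid = 0.5 * (H + H_next)
                    rho_new = step_magnus(rho, H_mid, p.dt, p.magnus_order)
                    H_prev = H
                    rho = rho_new
            else:  # verlet
                if rho_prev is None:
                    # bootstrap rho(dt) with several small Magnus substeps
                    # (an inaccurate start seeds the leapfrog parasitic mode)
                    rho_prev = rho
                    nsub = 8
                    Hs = H
                    for _ in range(nsub):
                        rho = step_magnus(rho, Hs, p.dt / nsub, DEFAULT_MAGNUS_ORDER)
                        if not frozen:
                            Hs, _ = self.fock_on(rho)
                else:
                    rho_new = step_verlet(rho_prev, rho, H, p.dt)
                    rho_prev = rho
                    rho = rho_new

            drift = abs(np.trace(rho).real - self.nelec) + abs(np.trace(rho).imag)
            max_drift = max(max_drift, drift) if np.isfinite(drift) else np.inf
            if not np.isfinite(drift) or drift > p.trace_tolerance:
                raise TraceDriftError(
                    f"electron-number drift {drift:.3e} at step {istep} "
                    f"(dt={p.dt}, propagator={p.propagator})"
                )
            if not frozen:
                H, E = self.fock_on(rho)
            times[istep] = istep * p.dt
            mus[istep] = self.dipole(rho) - mu_ref
            if record_energy:
                energies[istep] = self.scf.energy if frozen else E
        return DipoleTrace(times, mus, p, energies, max_drift, rho)


def max_stable_dt(make_propagator, propagator: str, drift_tol: float = 1e-6,
                  nsteps: int = 100, dt_init: float = 1e-3,
                  rel_precision: float = 0.01) -> float:
    """Largest dt whose total-energy drift over ``nsteps`` stays below
    ``drift_tol`` (Hartree), found by doubling then bisection to ~2
    significant figures.  ``make_propagator(dt, propagator)`` must build a
    fresh :class:`RTPropagator`."""

    def stable(dt: float) -> bool:
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                trace = make_propagator(dt, propagator).propagate(record_energy=True)
        except (TraceDriftError, FloatingPointError, np.linalg.LinAlgError):
            return False
        e = trace.energies
        if not np.all(np.isfinite(e)):
            return False
        return float(np.max(np.abs(e - e[0]))) < drift_tol

    dt = dt_init
    if not stable(dt):
        while dt > 1e-8 and not stable(dt):
            dt /= 2.0
        lo, hi = dt, dt * 2.0
    else:
        while stable(dt * 2.0):
            dt *= 2.0
        lo, hi = dt, dt * 2.0
    while (hi - lo) > rel_precision * lo:
        mid = 0.5 * (lo + hi)
        if stable(mid):
            lo = mid
        else:
            hi = mid
    return lo
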