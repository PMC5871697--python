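"""Born-Oppenheimer MD integrators: velocity Verlet (NVE) and Langevin
(BAOAB splitting), with optional umbrella restraints.

All quantities in atomic units.  Trajectories under a fixed seed are
bitwise reproducible (single RNG, fixed call order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import KB_HARTREE
from .umbrella import UmbrellaWindowSpec, reaction_coordinate, umbrella_energy_force


@dataclass
class MDState:
    positions: np.ndarray  # (n, 3) bohr
    velocities: np.ndarray  # (n, 3) bohr / a.u. time
    masses: np.ndarray  # electron masses
    time: float = 0.0
    forces: np.ndarray | None = None
    potential_energy: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float).reshape(-1)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.velocities))):
            raise ValueError("non-finite state")

    @property
    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.masses[:, None] * self.velocities**2))

    def kinetic_temperature(self, ndof: int | None = None) -> float:
        if ndof is None:
            ndof = 3 * len(self.masses)
        return 2.0 * self.kinetic_energy / (ndof * KB_HARTREE)


@dataclass
class Langevin:
    gamma: float  # friction, 1 / a.u. time
    temperature: float  # K
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self):
        self._rng = np.random.default_rng(self.seed)


@dataclass
class Trajectory:
    times: np.ndarray
    positions: np.ndarray  # (nframes, n, 3)
    velocities: np.ndarray
    potential_energies: np.ndarray
    kinetic_energies: np.ndarray
    rc_values: np.ndarray | None = None  # Angstrom

    @property
    def nframes(self) -> int:
        return len(self.times)


def _eval(potential, x, restraint):
    e, f = potential.energy_forces(x)
    if restraint is not None:
        eb, fb = umbrella_energy_force(x, restraint)
        e += eb
        f = f + fb
    return e, f


def bomd_step(potential, state: MDState, dt: float,
              restraint: UmbrellaWindowSpec | None = None) -> MDState:
    """One velocity-Verlet step (NVE)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    x, v, m = state.positions, state.velocities, state.masses
    if state.forces is None:
        _, f0 = _eval(potential, x, restraint)
    else:
        f0 = state.forces
    a0 = f0 / m[:, None]
    x1 = x + v * dt + 0.5 * a0 * dt * dt
    e1, f1 = _eval(potential, x1, restraint)
    v1 = v + 0.5 * (a0 + f1 / m[:, None]) * dt
    return MDState(x1, v1, m, state.time + dt, f1, e1)


def _baoab_step(potential, state: MDState, dt: float, thermostat: Langevin,
                restraint) -> MDState:
    x, v, m = state.positions, state.velocities, state.masses
    if state.forces is None:
        _, f = _eval(potential, x, restraint)
    else:
        f = state.forces
    minv = 1.0 / m[:, None]
    v = v + 0.5 * dt * f * minv  # B
    x = x + 0.5 * dt * v  # A
    c1 = np.exp(-thermostat.gamma * dt)  # O
    kT = KB_HARTREE * thermostat.temperature
    sigma = np.sqrt(kT * (1.0 - c1 * c1) / m)[:, None]
    v = c1 * v + sigma * thermostat._rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v  # A
    e, f = _eval(potential, x, restraint)
    v = v + 0.5 * dt * f * minv  # B
    return MDState(x, v, m, state.time + dt, f, e)


def run_md(potential, state: MDState, nsteps: int, dt: float,
           thermostat: Langevin | None = None,
           restraint: UmbrellaWindowSpec | None = None,
           sample_every: int = 1) -> Trajectory:
    """Propagate and sample every ``sample_every`` steps (frame 0 included)."""
    if state.forces is None:
        e, f = _eval(potential, state.positions, restraint)
        state = MDState(state.positions, state.velocities, state.masses,
                        state.time, f, e)
    times, xs, vs, pes, kes, rcs = [], [], [], [], [], []

    def record(s):
        times.append(s.time)
        xs.append(s.positions.copy())
        vs.append(s.velocities.copy())
        pes.append(s.potential_energy)
        kes.append(s.kinetic_energy)
        if restraint is not None:
            rcs.append(reaction_coordinate(s.positions, restraint))

    record(state)
    if thermostat is not None:
        # hoisted BAOAB loop: identical math and RNG call order as
        # _baoab_step, without per-step constant recomputation
        c1 = np.exp(-thermostat.gamma * dt)
        kT = KB_HARTREE * thermostat.temperature
        sigma = np.sqrt(kT * (1.0 - c1 * c1) / state.masses)[:, None]
        minv = 1.0 / state.masses[:, None]
        rng = thermostat._rng
        x, v, f = state.positions, state.velocities, state.forces
        m, t = state.masses, state.time
        half_dt = 0.5 * dt
        e = state.potential_energy
        for istep in range(1, nsteps + 1):
            v = v + half_dt * f * minv
            x = x + half_dt * v
            v = c1 * v + sigma * rng.standard_normal(v.shape)
            x = x + half_dt * v
            e, f = _eval(potential, x, restraint)
            v = v + half_dt * f * minv
            t += dt
            if istep % sample_every == 0:
                state = MDState(x, v, m, t, f, e)
                record(state)
        return Trajectory(
            np.array(times), np.array(xs), np.array(vs), np.array(pes),
            np.array(kes), np.array(rcs) if restraint is not None else None,
        )
    for istep in range(1, nsteps + 1):
        state = bomd_step(potential, state, dt, restraint)
        if istep % sample_every == 0:
            record(state)
    return Trajectory(
        np.array(times), np.array(xs), np.array(vs), np.array(pes),
        np.array(kes), np.array(rcs) if restraint is not None else None,
    )
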