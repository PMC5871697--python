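"""Reaction coordinates and harmonic umbrella restraints.

Coordinates are either a single distance d(i,j) or the difference
d(i,j) - d(k,l) (bond-breaking/forming style).  User-facing force
constants are kcal/mol/A^2 and centers are in Angstrom; conversion to
atomic units happens at construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..constants import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM, HARTREE_PER_KCALMOL


@dataclass(frozen=True)
class UmbrellaWindowSpec:
    atoms: tuple  # (i, j) or (i, j, k, l) meaning d(i,j) - d(k,l)
    k_umb: float  # kcal/mol/A^2
    rc0: float  # Angstrom

    def __post_init__(self):
        if len(self.atoms) not in (2, 4):
            raise ValueError("rc spec needs 2 or 4 atom indices")
        if len(self.atoms) == 2 and self.atoms[0] == self.atoms[1]:
            raise ValueError("distance needs two distinct atoms")
        if len(self.atoms) == 4:
            i, j, k, l = self.atoms
            if i == j or k == l:
                raise ValueError("each distance needs distinct atoms")
        if self.k_umb <= 0:
            raise ValueError("force constant must be positive")

    @property
    def k_au(self) -> float:
        return self.k_umb * HARTREE_PER_KCALMOL * ANGSTROM_PER_BOHR**2

    @property
    def rc0_au(self) -> float:
        return self.rc0 * BOHR_PER_ANGSTROM


def reaction_coordinate(positions: np.ndarray, spec: UmbrellaWindowSpec) -> float:
    """Value of the coordinate in Angstrom (positions in bohr)."""
    return _rc_bohr(positions, spec) * ANGSTROM_PER_BOHR


def _rc_bohr(x: np.ndarray, spec: UmbrellaWindowSpec) -> float:
    a = spec.atoms
    d1 = float(np.linalg.norm(x[a[0]] - x[a[1]]))
    if len(a) == 2:
        return d1
    d2 = float(np.linalg.norm(x[a[2]] - x[a[3]]))
    return d1 - d2


def _rc_gradient(x: np.ndarray, spec: UmbrellaWindowSpec) -> np.ndarray:
    g = np.zeros_like(x)
    a = spec.atoms
    d = x[a[0]] - x[a[1]]
    r = np.linalg.norm(d)
    g[a[0]] += d / r
    g[a[1]] -= d / r
    if len(a) == 4:
        d2 = x[a[2]] - x[a[3]]
        r2 = np.linalg.norm(d2)
        g[a[2]] -= d2 / r2
        g[a[3]] += d2 / r2
    return g


def umbrella_energy_force(x: np.ndarray, spec: UmbrellaWindowSpec):
    """Bias 1/2 k (rc - rc0)^2 in Hartree and its force (a.u.)."""
    k = spec.k_au
    rc = _rc_bohr(x, spec)
    drc = rc - spec.rc0_au
    e = 0.5 * k * drc**2
    f = -k * drc * _rc_gradient(x, spec)
    return e, f


def umbrella_force(x: np.ndarray, spec: UmbrellaWindowSpec) -> np.ndarray:
    return umbrella_energy_force(x, spec)[1]
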