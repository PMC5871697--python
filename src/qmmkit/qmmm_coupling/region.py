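"""Classical (MM) region: point charges plus Lennard-Jones sites.

User surfaces speak Angstrom / kcal/mol; everything stored here is in
atomic units.  Rigid-water models keep their internal geometry fixed, so
the MM potential is purely intermolecular (Coulomb + LJ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import BOHR_PER_ANGSTROM, HARTREE_PER_KCALMOL


@dataclass
class MMRegion:
    coordinates: np.ndarray  # (n, 3) bohr
    charges: np.ndarray  # e
    lj_epsilon: np.ndarray  # Hartree
    lj_sigma: np.ndarray  # bohr
    molecule_id: np.ndarray = None
    symbols: list = field(default_factory=list)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        n = self.coordinates.shape[0]
        self.charges = np.asarray(self.charges, dtype=float).reshape(n)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float).reshape(n)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float).reshape(n)
        if self.molecule_id is None:
            self.molecule_id = np.arange(n)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int).reshape(n)
        for arr in (self.coordinates, self.charges, self.lj_epsilon, self.lj_sigma):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite MM region data")
        if np.any(self.lj_epsilon < 0):
            raise ValueError("negative LJ epsilon")
        if np.any((self.lj_epsilon > 0) & (self.lj_sigma <= 0)):
            raise ValueError("LJ sigma must be positive where epsilon > 0")

    @property
    def nsites(self) -> int:
        return self.coordinates.shape[0]

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @classmethod
    def empty(cls) -> "MMRegion":
        z = np.zeros((0, 3))
        return cls(z, np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0, dtype=int))

    @classmethod
    def from_user_units(cls, coords_angstrom, charges, eps_kcalmol, sigma_angstrom,
                        molecule_id=None, symbols=()):
        return cls(
            np.asarray(coords_angstrom, dtype=float) * BOHR_PER_ANGSTROM,
            charges,
            np.asarray(eps_kcalmol, dtype=float) * HARTREE_PER_KCALMOL,
            np.asarray(sigma_angstrom, dtype=float) * BOHR_PER_ANGSTROM,
            molecule_id,
            list(symbols),
        )

    def subset(self, mask) -> "MMRegion":
        mask = np.asarray(mask)
        return MMRegion(
            self.coordinates[mask], self.charges[mask],
            self.lj_epsilon[mask], self.lj_sigma[mask], self.molecule_id[mask],
            [s for s, m in zip(self.symbols, mask) if m] if self.symbols else [],
        )
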