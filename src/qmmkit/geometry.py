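"""Molecular geometry container (atomic units internally)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ELEMENT_NUMBERS


@dataclass
class QMGeometry:
    """A quantum region: element symbols, coordinates in bohr, net charge.

    Only closed-shell systems (multiplicity 1, even electron count) are
    supported by the SCF driver; the constraint is validated here so that
    errors surface at construction time.
    """

    symbols: list[str]
    coordinates: np.ndarray  # (natoms, 3), bohr
    total_charge: int = 0
    multiplicity: int = 1
    atomic_numbers: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if len(self.symbols) != self.coordinates.shape[0]:
            raise ValueError(
                f"{len(self.symbols)} symbols but {self.coordinates.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        try:
            self.atomic_numbers = np.array(
                [ELEMENT_NUMBERS[s] for s in self.symbols], dtype=int
            )
        except KeyError as exc:
            raise ValueError(f"unknown element symbol {exc.args[0]!r}") from exc
        if self.multiplicity != 1:
            raise ValueError("only closed-shell (multiplicity 1) systems are supported")
        if self.n_electrons % 2 != 0:
            raise ValueError(
                f"odd electron count ({self.n_electrons}); closed shell required"
            )

    @property
    def natoms(self) -> int:
        return len(self.symbols)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.total_charge

    def nuclear_repulsion(self) -> float:
        e = 0.0
        z = self.atomic_numbers
        r = self.coordinates
        for i in range(self.natoms):
            for j in range(i + 1, self.natoms):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return float(e)

    def translated(self, shift) -> "QMGeometry":
        return QMGeometry(
            list(self.symbols),
            self.coordinates + np.asarray(shift, dtype=float),
            self.total_charge,
            self.multiplicity,
        )

    def rotated(self, rotation_matrix) -> "QMGeometry":
        rm = np.asarray(rotation_matrix, dtype=float)
        return QMGeometry(
            list(self.symbols),
            self.coordinates @ rm.T,
            self.total_charge,
            self.multiplicity,
        )
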