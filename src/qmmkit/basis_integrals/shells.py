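"""Contracted Cartesian Gaussian shells and basis-set assembly.

Angular momenta up to d are supported, in Cartesian form (6 components
for d).  Primitive coefficients are stored pre-multiplied by the
normalization constant of the (L,0,0) component and rescaled so that the
contracted (L,0,0) function has unit self-overlap; the remaining
per-component angular factors are carried separately in
:attr:`GaussianShell.angular_norms`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import QMGeometry

MAX_L = 2  # s, p, d
_L_LABELS = "SPD"

# Cartesian component tables, canonical order: lx descending, then ly.
# Flattened over L = 0..4 (totals up to g are needed internally by the
# recursion intermediates even though basis functions stop at d).
_MAX_LTOT = 4


def ncart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def cart_components(l: int) -> list[tuple[int, int, int]]:
    return [
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    ]


def _build_tables():
    offs = np.zeros(_MAX_LTOT + 2, dtype=np.int64)
    comps = []
    for l in range(_MAX_LTOT + 1):
        offs[l + 1] = offs[l] + ncart(l)
        comps.extend(cart_components(l))
    comps = np.array(comps, dtype=np.int64)  # (ntot, 3)
    ntot = comps.shape[0]
    index = {}
    for i, (lx, ly, lz) in enumerate(comps):
        index[(lx, ly, lz)] = i
    dec = -np.ones((3, ntot), dtype=np.int64)
    inc = -np.ones((3, ntot), dtype=np.int64)
    for i, (lx, ly, lz) in enumerate(map(tuple, comps)):
        for d, key in enumerate(
            [(lx - 1, ly, lz), (lx, ly - 1, lz), (lx, ly, lz - 1)]
        ):
            if min(key) >= 0:
                dec[d, i] = index[key]
        if lx + ly + lz < _MAX_LTOT:
            for d, key in enumerate(
                [(lx + 1, ly, lz), (lx, ly + 1, lz), (lx, ly, lz + 1)]
            ):
                inc[d, i] = index[key]
    return offs, comps, dec, inc


CART_OFFSETS, CART_COMPS, CART_DEC, CART_INC = _build_tables()


def double_factorial(n: int) -> int:
    if n <= 0:
        return 1
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, l: int) -> float:
    """Normalization constant of the (l,0,0) Cartesian primitive."""
    return (
        (2.0 * alpha / np.pi) ** 0.75
        * (4.0 * alpha) ** (l / 2.0)
        / np.sqrt(double_factorial(2 * l - 1))
    )


def angular_norm_factors(l: int) -> np.ndarray:
    """Per-component factor relative to the (l,0,0) normalization."""
    facs = []
    for lx, ly, lz in cart_components(l):
        facs.append(
            np.sqrt(
                double_factorial(2 * l - 1)
                / (
                    double_factorial(2 * lx - 1)
                    * double_factorial(2 * ly - 1)
                    * double_factorial(2 * lz - 1)
                )
            )
        )
    return np.array(facs)


@dataclass
class GaussianShell:
    """One contracted Cartesian shell on one atomic center."""

    center_index: int
    angular_momentum: int
    exponents: np.ndarray
    contraction_coefficients: np.ndarray  # raw input coefficients
    coefs_normalized: np.ndarray = field(init=False)
    angular_norms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.contraction_coefficients = np.asarray(
            self.contraction_coefficients, dtype=float
        )
        if self.exponents.ndim != 1 or len(self.exponents) == 0:
            raise ValueError("shell needs at least one primitive")
        if len(self.exponents) != len(self.contraction_coefficients):
            raise ValueError("exponent/coefficient length mismatch")
        if np.any(self.exponents <= 0):
            raise ValueError("exponents must be positive")
        l = self.angular_momentum
        if not 0 <= l <= MAX_L:
            raise ValueError(f"angular momentum {l} unsupported (s, p, d only)")
        norms = np.array([primitive_norm(a, l) for a in self.exponents])
        c = self.contraction_coefficients * norms
        # contracted self-overlap of the (l,0,0) component
        p = self.exponents[:, None] + self.exponents[None, :]
        s = (np.pi / p) ** 1.5 * double_factorial(2 * l - 1) / (2.0 * p) ** l
        self_ov = c @ s @ c
        self.coefs_normalized = c / np.sqrt(self_ov)
        self.angular_norms = angular_norm_factors(l)

    @property
    def nprim(self) -> int:
        return len(self.exponents)

    @property
    def ncart(self) -> int:
        return ncart(self.angular_momentum)


class BasisSet:
    """Shells placed on a geometry, with AO bookkeeping."""

    def __init__(self, shells: list[GaussianShell], geometry: QMGeometry):
        for sh in shells:
            if not 0 <= sh.center_index < geometry.natoms:
                raise ValueError(
                    f"shell references center {sh.center_index}, "
                    f"geometry has {geometry.natoms} atoms"
                )
        self.shells = list(shells)
        self.geometry = geometry
        self.offsets = np.zeros(len(shells) + 1, dtype=int)
        for i, sh in enumerate(shells):
            self.offsets[i + 1] = self.offsets[i] + sh.ncart
        self.nbf = int(self.offsets[-1])
        self.ao_center = np.concatenate(
            [[sh.center_index] * sh.ncart for sh in shells]
        ) if shells else np.zeros(0, dtype=int)

    def __len__(self) -> int:
        return len(self.shells)

    def shell_center(self, i: int) -> np.ndarray:
        return self.geometry.coordinates[self.shells[i].center_index]

    @classmethod
    def from_library(cls, library: dict, geometry: QMGeometry) -> "BasisSet":
        """Place shells from an element-keyed library on each atom in order."""
        shells = []
        for iatom, sym in enumerate(geometry.symbols):
            if sym not in library:
                raise KeyError(f"element {sym!r} missing from basis library")
            for l, exps, coefs in library[sym]:
                shells.append(GaussianShell(iatom, l, exps, coefs))
        return cls(shells, geometry)

    def ao_labels(self) -> list[str]:
        labels = []
        for sh in self.shells:
            sym = self.geometry.symbols[sh.center_index]
            for lx, ly, lz in cart_components(sh.angular_momentum):
                tag = "x" * lx + "y" * ly + "z" * lz or "s"
                labels.append(
                    f"{sh.center_index}{sym} {_L_LABELS[sh.angular_momentum].lower()}{tag}"
                )
        return labels
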