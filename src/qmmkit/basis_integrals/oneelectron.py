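"""One-electron integral matrices: overlap, kinetic, charge attraction, dipole.

Overlap/kinetic/dipole use the one-dimensional Obara-Saika recursion on
Gaussian-product factors; the charge-attraction matrix delegates to the
compiled Boys-function recursion kernel (one routine serves both nuclear
Z_I and MM point charges q_A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import attraction_pair
from .shells import BasisSet, cart_components


@dataclass
class OneElectronMatrices:
    overlap: np.ndarray
    kinetic: np.ndarray
    charge_attraction: np.ndarray


@dataclass
class DipoleMatrices:
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    origin: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.stack([self.x, self.y, self.z])


def _os_1d_table(imax: int, jmax: int, xpa: float, xpb: float, p: float) -> np.ndarray:
    """1D overlap factors s(i,j) with s(0,0)=1."""
    s = np.zeros((imax + 1, jmax + 1))
    s[0, 0] = 1.0
    half_p = 0.5 / p
    for i in range(imax + 1):
        for j in range(jmax + 1):
            if i == 0 and j == 0:
                continue
            if i > 0:
                val = xpa * s[i - 1, j]
                if i > 1:
                    val += (i - 1) * half_p * s[i - 2, j]
                if j > 0:
                    val += j * half_p * s[i - 1, j - 1]
            else:
                val = xpb * s[i, j - 1]
                if j > 1:
                    val += (j - 1) * half_p * s[i, j - 2]
            s[i, j] = val
    return s


def _pair_blocks(basis: BasisSet, ish: int, jsh: int, kind: str, origin=None):
    """Primitive-contracted block for a shell pair; kind in {S, T, D}."""
    sa = basis.shells[ish]
    sb = basis.shells[jsh]
    A = basis.shell_center(ish)
    B = basis.shell_center(jsh)
    la, lb = sa.angular_momentum, sb.angular_momentum
    comps_a = cart_components(la)
    comps_b = cart_components(lb)
    AB2 = float(np.dot(A - B, A - B))

    nblocks = 3 if kind == "D" else 1
    blocks = [np.zeros((len(comps_a), len(comps_b))) for _ in range(nblocks)]
    imax = la + 2
    jmax = lb + 2
    for ai, ca in zip(sa.exponents, sa.coefs_normalized):
        for bj, cb in zip(sb.exponents, sb.coefs_normalized):
            p = ai + bj
            P = (ai * A + bj * B) / p
            pref = np.exp(-ai * bj / p * AB2) * (np.pi / p) ** 1.5 * ca * cb
            tables = [
                _os_1d_table(imax, jmax, P[d] - A[d], P[d] - B[d], p)
                for d in range(3)
            ]
            for ia, la_xyz in enumerate(comps_a):
                for jb, lb_xyz in enumerate(comps_b):
                    s1d = [tables[d][la_xyz[d], lb_xyz[d]] for d in range(3)]
                    if kind == "S":
                        blocks[0][ia, jb] += pref * s1d[0] * s1d[1] * s1d[2]
                    elif kind == "T":
                        t1d = []
                        for d in range(3):
                            i, j = la_xyz[d], lb_xyz[d]
                            t = -2.0 * bj * bj * tables[d][i, j + 2] + bj * (
                                2 * j + 1
                            ) * tables[d][i, j]
                            if j >= 2:
                                t -= 0.5 * j * (j - 1) * tables[d][i, j - 2]
                            t1d.append(t)
                        blocks[0][ia, jb] += pref * (
                            t1d[0] * s1d[1] * s1d[2]
                            + s1d[0] * t1d[1] * s1d[2]
                            + s1d[0] * s1d[1] * t1d[2]
                        )
                    else:  # dipole, moment about `origin`
                        for d in range(3):
                            i, j = la_xyz[d], lb_xyz[d]
                            m1d = tables[d][i + 1, j] + (A[d] - origin[d]) * tables[d][i, j]
                            oth = [e for e in range(3) if e != d]
                            blocks[d][ia, jb] += (
                                pref * m1d * s1d[oth[0]] * s1d[oth[1]]
                            )
    ang = np.outer(sa.angular_norms, sb.angular_norms)
    return [b * ang for b in blocks]


def _assemble(basis: BasisSet, kind: str, origin=None):
    nblocks = 3 if kind == "D" else 1
    mats = [np.zeros((basis.nbf, basis.nbf)) for _ in range(nblocks)]
    for ish in range(len(basis)):
        for jsh in range(ish + 1):
            blocks = _pair_blocks(basis, ish, jsh, kind, origin)
            i0, i1 = basis.offsets[ish], basis.offsets[ish + 1]
            j0, j1 = basis.offsets[jsh], basis.offsets[jsh + 1]
            for m, b in zip(mats, blocks):
                m[i0:i1, j0:j1] = b
                if ish != jsh:
                    m[j0:j1, i0:i1] = b.T
    return mats


def overlap_matrix(basis: BasisSet) -> np.ndarray:
    return _assemble(basis, "S")[0]


def kinetic_matrix(basis: BasisSet) -> np.ndarray:
    return _assemble(basis, "T")[0]


def dipole_matrices(basis: BasisSet, origin=(0.0, 0.0, 0.0)) -> DipoleMatrices:
    origin = np.asarray(origin, dtype=float)
    mx, my, mz = _assemble(basis, "D", origin)
    return DipoleMatrices(mx, my, mz, origin)


def charge_attraction_matrix(basis: BasisSet, charges) -> np.ndarray:
    """Matrix of -sum_A q_A <mu| 1/|r - R_A| |nu>.

    ``charges``: iterable of (value, position_bohr) or an (n, 4) array of
    rows (q, x, y, z).  Positive charges lower the energy of the
    electrons (attractive convention).
    """
    charge_list = [(float(q), np.asarray(r, dtype=float)) for q, r in charges]
    if not charge_list:
        raise ValueError("charge list is empty")
    qs = np.array([q for q, _ in charge_list])
    rs = np.array([r for _, r in charge_list]).reshape(-1, 3)
    V = np.zeros((basis.nbf, basis.nbf))
    for ish in range(len(basis)):
        sa = basis.shells[ish]
        for jsh in range(ish + 1):
            sb = basis.shells[jsh]
            block = attraction_pair(
                sa.angular_momentum, sb.angular_momentum,
                basis.shell_center(ish), basis.shell_center(jsh),
                sa.exponents, sa.coefs_normalized,
                sb.exponents, sb.coefs_normalized,
                rs, qs,
            )
            block = block * np.outer(sa.angular_norms, sb.angular_norms)
            i0, i1 = basis.offsets[ish], basis.offsets[ish + 1]
            j0, j1 = basis.offsets[jsh], basis.offsets[jsh + 1]
            V[i0:i1, j0:j1] = block
            if ish != jsh:
                V[j0:j1, i0:i1] = block.T
    return V


def nuclear_attraction_matrix(basis: BasisSet) -> np.ndarray:
    geom = basis.geometry
    charges = [(float(z), geom.coordinates[i]) for i, z in enumerate(geom.atomic_numbers)]
    return charge_attraction_matrix(basis, charges)


def core_hamiltonian(basis: BasisSet) -> tuple[np.ndarray, OneElectronMatrices]:
    S = overlap_matrix(basis)
    T = kinetic_matrix(basis)
    V = nuclear_attraction_matrix(basis)
    return T + V, OneElectronMatrices(S, T, V)
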