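"""Two-electron repulsion integral tensor with Schwarz screening.

The tensor is stored dense; the 8-fold permutational symmetry
(ij|kl)=(ji|kl)=(ij|lk)=(kl|ij) holds exactly because each unique shell
quartet is computed once and written to all equivalent positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import eri_quartet
from .shells import BasisSet

DEFAULT_SCREENING = 1e-10


@dataclass
class ERITensor:
    values: np.ndarray  # (nbf, nbf, nbf, nbf)
    screening_threshold: float

    def __getitem__(self, idx):
        return self.values[idx]

    def coulomb(self, P: np.ndarray) -> np.ndarray:
        """J_{mu nu} = sum_{ls} (mn|ls) P_{ls}."""
        n = self.values.shape[0]
        return (self.values.reshape(n * n, n * n) @ P.ravel()).reshape(n, n)


def _quartet(basis: BasisSet, i: int, j: int, k: int, l: int) -> np.ndarray:
    sa, sb, sc, sd = (basis.shells[m] for m in (i, j, k, l))
    block = eri_quartet(
        sa.angular_momentum, sb.angular_momentum,
        sc.angular_momentum, sd.angular_momentum,
        basis.shell_center(i), basis.shell_center(j),
        basis.shell_center(k), basis.shell_center(l),
        sa.exponents, sa.coefs_normalized,
        sb.exponents, sb.coefs_normalized,
        sc.exponents, sc.coefs_normalized,
        sd.exponents, sd.coefs_normalized,
    )
    block *= (
        sa.angular_norms[:, None, None, None]
        * sb.angular_norms[None, :, None, None]
        * sc.angular_norms[None, None, :, None]
        * sd.angular_norms[None, None, None, :]
    )
    return block


def schwarz_bounds(basis: BasisSet) -> np.ndarray:
    """Q_{ij} = sqrt(max |(ij|ij)|) per shell pair."""
    nsh = len(basis)
    Q = np.zeros((nsh, nsh))
    for i in range(nsh):
        for j in range(i + 1):
            blk = _quartet(basis, i, j, i, j)
            q = np.sqrt(np.max(np.abs(blk)))
            Q[i, j] = Q[j, i] = q
    return Q


def eri_tensor(basis: BasisSet, screening_threshold: float = DEFAULT_SCREENING) -> ERITensor:
    if screening_threshold < 0:
        raise ValueError("screening threshold must be >= 0")
    n = basis.nbf
    nsh = len(basis)
    values = np.zeros((n, n, n, n))
    Q = schwarz_bounds(basis) if screening_threshold > 0 else None

    off = basis.offsets

    def slc(m):
        return slice(off[m], off[m + 1])

    for i in range(nsh):
        for j in range(i + 1):
            for k in range(i + 1):
                lmax = k if k < i else j
                for l in range(lmax + 1):
                    if Q is not None and Q[i, j] * Q[k, l] < screening_threshold:
                        continue
                    blk = _quartet(basis, i, j, k, l)
                    # degenerate quartets: symmetrize so the stored tensor
                    # obeys the permutation group bitwise, not just to
                    # roundoff
                    if i == j:
                        blk = 0.5 * (blk + blk.transpose(1, 0, 2, 3))
                    if k == l:
                        blk = 0.5 * (blk + blk.transpose(0, 1, 3, 2))
                    if i == k and j == l:
                        blk = 0.5 * (blk + blk.transpose(2, 3, 0, 1))
                    si, sj, sk, sl = slc(i), slc(j), slc(k), slc(l)
                    values[si, sj, sk, sl] = blk
                    values[sj, si, sk, sl] = blk.transpose(1, 0, 2, 3)
                    values[si, sj, sl, sk] = blk.transpose(0, 1, 3, 2)
                    values[sj, si, sl, sk] = blk.transpose(1, 0, 3, 2)
                    values[sk, sl, si, sj] = blk.transpose(2, 3, 0, 1)
                    values[sl, sk, si, sj] = blk.transpose(3, 2, 0, 1)
                    values[sk, sl, sj, si] = blk.transpose(2, 3, 1, 0)
                    values[sl, sk, sj, si] = blk.transpose(3, 2, 1, 0)
    return ERITensor(values, screening_threshold)
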