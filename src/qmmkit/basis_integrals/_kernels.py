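"""Numba-compiled Obara-Saika recursion kernels.

Vertical recursions build (e0|f0)-class integrals over primitive
quartets; horizontal recursions act at the contracted level (they only
involve center differences).  Cartesian component bookkeeping uses the
flat tables from :mod:`.shells` (levels 0..4 concatenated).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .shells import CART_COMPS, CART_DEC, CART_INC, CART_OFFSETS

_OFF = CART_OFFSETS.copy()
_COMPS = CART_COMPS.copy()
_DEC = CART_DEC.copy()
_INC = CART_INC.copy()

_SQRT_PI = np.sqrt(np.pi)


@njit(cache=False)
def _boys_nb(mmax, T, out):
    if T < 1e-14:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1) - T / (2 * m + 3)
        return
    if T > 35.0:
        df = 1.0
        for n in range(2 * mmax - 1, 1, -2):
            df *= n
        out[mmax] = df / 2.0 ** (mmax + 1) * np.sqrt(np.pi / T ** (2 * mmax + 1))
        expT = 0.0
    else:
        term = 1.0 / (2 * mmax + 1)
        acc = term
        k = 1
        while k < 500:
            term *= 2.0 * T / (2 * mmax + 2 * k + 1)
            acc += term
            if term < 1e-17 * acc:
                break
            k += 1
        expT = np.exp(-T)
        out[mmax] = expT * acc
    for m in range(mmax - 1, -1, -1):
        out[m] = (2.0 * T * out[m + 1] + expT) / (2 * m + 1)


@njit(cache=False)
def _first_axis(ft):
    # first Cartesian axis with nonzero exponent for flat component ft
    if _COMPS[ft, 0] > 0:
        return 0
    if _COMPS[ft, 1] > 0:
        return 1
    return 2


@njit(cache=False)
def eri_quartet(la, lb, lc, ld, A, B, C, D,
                aexp, acoef, bexp, bcoef, cexp, ccoef, dexp, dcoef):
    """Contracted (ab|cd) block, Cartesian components in canonical order.

    Angular per-component normalization factors are NOT applied here.
    """
    Lbra = la + lb
    Lket = lc + ld
    mmax = Lbra + Lket
    nbra = _OFF[Lbra + 1]
    nket = _OFF[Lket + 1]

    AB = A - B
    CD = C - D
    AB2 = AB[0] ** 2 + AB[1] ** 2 + AB[2] ** 2
    CD2 = CD[0] ** 2 + CD[1] ** 2 + CD[2] ** 2

    ctr = np.zeros((nbra, nket))
    F = np.empty(mmax + 1)
    v = np.empty((mmax + 1, nbra))
    u = np.empty((mmax + 1, nbra, nket))

    for ia in range(aexp.shape[0]):
        a = aexp[ia]
        for ib in range(bexp.shape[0]):
            b = bexp[ib]
            zeta = a + b
            Kab = np.exp(-a * b / zeta * AB2)
            cab = acoef[ia] * bcoef[ib]
            Px = (a * A[0] + b * B[0]) / zeta
            Py = (a * A[1] + b * B[1]) / zeta
            Pz = (a * A[2] + b * B[2]) / zeta
            for ic in range(cexp.shape[0]):
                c = cexp[ic]
                for idd in range(dexp.shape[0]):
                    d = dexp[idd]
                    eta = c + d
                    Kcd = np.exp(-c * d / eta * CD2)
                    cc = cab * ccoef[ic] * dcoef[idd]
                    Qx = (c * C[0] + d * D[0]) / eta
                    Qy = (c * C[1] + d * D[1]) / eta
                    Qz = (c * C[2] + d * D[2]) / eta
                    zpe = zeta + eta
                    rho = zeta * eta / zpe
                    PQ2 = (Px - Qx) ** 2 + (Py - Qy) ** 2 + (Pz - Qz) ** 2
                    T = rho * PQ2
                    pref = (
                        2.0 * np.pi ** 2.5
                        / (zeta * eta * np.sqrt(zpe))
                        * Kab * Kcd
                    )
                    _boys_nb(mmax, T, F)
                    Wx = (zeta * Px + eta * Qx) / zpe
                    Wy = (zeta * Py + eta * Qy) / zpe
                    Wz = (zeta * Pz + eta * Qz) / zpe
                    PA = (Px - A[0], Py - A[1], Pz - A[2])
                    WP = (Wx - Px, Wy - Py, Wz - Pz)
                    QC = (Qx - C[0], Qy - C[1], Qz - C[2])
                    WQ = (Wx - Qx, Wy - Qy, Wz - Qz)

                    # bra VRR: v[m, e-flat] = [e0|00]^m
                    for m in range(mmax + 1):
                        v[m, 0] = pref * F[m]
                    for e in range(1, Lbra + 1):
                        for ft in range(_OFF[e], _OFF[e + 1]):
                            ax = _first_axis(ft)
                            fm1 = _DEC[ax, ft]
                            fm2 = _DEC[ax, fm1]
                            ei = _COMPS[fm1, ax]  # = l_ax(ft) - 1
                            for m in range(mmax + 1 - e):
                                val = PA[ax] * v[m, fm1] + WP[ax] * v[m + 1, fm1]
                                if fm2 >= 0 and ei > 0:
                                    val += ei / (2.0 * zeta) * (
                                        v[m, fm2] - rho / zeta * v[m + 1, fm2]
                                    )
                                v[m, ft] = val

                    # ket VRR: u[m, e-flat, f-flat] = [e0|f0]^m
                    for m in range(mmax + 1):
                        for t in range(nbra):
                            u[m, t, 0] = v[m, t]
                    for f in range(1, Lket + 1):
                        for fs in range(_OFF[f], _OFF[f + 1]):
                            ax = _first_axis(fs)
                            sm1 = _DEC[ax, fs]
                            sm2 = _DEC[ax, sm1]
                            fi = _COMPS[sm1, ax]
                            for m in range(mmax + 1 - f):
                                for t in range(nbra):
                                    val = (
                                        QC[ax] * u[m, t, sm1]
                                        + WQ[ax] * u[m + 1, t, sm1]
                                    )
                                    if sm2 >= 0 and fi > 0:
                                        val += fi / (2.0 * eta) * (
                                            u[m, t, sm2]
                                            - rho / eta * u[m + 1, t, sm2]
                                        )
                                    td = _DEC[ax, t]
                                    if td >= 0:
                                        val += (
                                            _COMPS[t, ax]
                                            / (2.0 * zpe)
                                            * u[m + 1, td, sm1]
                                        )
                                    u[m, t, fs] = val

                    for t in range(nbra):
                        for s in range(nket):
                            ctr[t, s] += cc * u[0, t, s]

    # bra HRR at contracted level: (a, b+1 | f0) = ((a+1), b | f0) + AB (a, b | f0)
    ncb = _OFF[lb + 1] - _OFF[lb]
    prev = np.empty((nbra, 1, nket))
    for t in range(nbra):
        for s in range(nket):
            prev[t, 0, s] = ctr[t, s]
    for bl in range(1, lb + 1):
        nb_l = _OFF[bl + 1] - _OFF[bl]
        nxt = np.zeros((nbra, nb_l, nket))
        for tb in range(nb_l):
            ftb = _OFF[bl] + tb
            ax = _first_axis(ftb)
            tbm = _DEC[ax, ftb] - _OFF[bl - 1]
            for te in range(_OFF[la], _OFF[Lbra - bl + 1]):
                tep = _INC[ax, te]
                if tep < 0:
                    continue
                for s in range(nket):
                    nxt[te, tb, s] = prev[tep, tbm, s] + AB[ax] * prev[te, tbm, s]
        prev = nxt

    nca = _OFF[la + 1] - _OFF[la]
    bra_done = np.empty((nca, ncb, nket))
    for t in range(nca):
        for tb in range(ncb):
            for s in range(nket):
                bra_done[t, tb, s] = prev[_OFF[la] + t, tb, s]

    # ket HRR
    ncd = _OFF[ld + 1] - _OFF[ld]
    prev2 = bra_done.reshape(nca, ncb, nket, 1)
    for dl in range(1, ld + 1):
        nd_l = _OFF[dl + 1] - _OFF[dl]
        nxt2 = np.zeros((nca, ncb, nket, nd_l))
        for td in range(nd_l):
            ftd = _OFF[dl] + td
            ax = _first_axis(ftd)
            tdm = _DEC[ax, ftd] - _OFF[dl - 1]
            for s in range(_OFF[lc], _OFF[Lket - dl + 1]):
                sp = _INC[ax, s]
                if sp < 0:
                    continue
                for t in range(nca):
                    for tb in range(ncb):
                        nxt2[t, tb, s, td] = (
                            prev2[t, tb, sp, tdm] + CD[ax] * prev2[t, tb, s, tdm]
                        )
        prev2 = nxt2

    ncc = _OFF[lc + 1] - _OFF[lc]
    out = np.empty((nca, ncb, ncc, ncd))
    for t in range(nca):
        for tb in range(ncb):
            for s in range(ncc):
                for td in range(ncd):
                    out[t, tb, s, td] = prev2[t, tb, _OFF[lc] + s, td]
    return out


@njit(cache=False)
def attraction_pair(la, lb, A, B, aexp, acoef, bexp, bcoef,
                    charge_pos, charge_val):
    """Contracted block of -sum_A q_A <a| 1/|r-R_A| |b>.

    Negative sign convention: positive charges attract electrons.
    """
    Ltot = la + lb
    nflat = _OFF[Ltot + 1]
    AB = A - B
    AB2 = AB[0] ** 2 + AB[1] ** 2 + AB[2] ** 2

    ctr = np.zeros(nflat)
    F = np.empty(Ltot + 1)
    v = np.empty((Ltot + 1, nflat))

    for ia in range(aexp.shape[0]):
        a = aexp[ia]
        for ib in range(bexp.shape[0]):
            b = bexp[ib]
            p = a + b
            Kab = np.exp(-a * b / p * AB2)
            cab = acoef[ia] * bcoef[ib]
            Px = (a * A[0] + b * B[0]) / p
            Py = (a * A[1] + b * B[1]) / p
            Pz = (a * A[2] + b * B[2]) / p
            PA = (Px - A[0], Py - A[1], Pz - A[2])
            base = 2.0 * np.pi / p * Kab * cab
            for iq in range(charge_pos.shape[0]):
                q = charge_val[iq]
                if q == 0.0:
                    continue
                PCx = Px - charge_pos[iq, 0]
                PCy = Py - charge_pos[iq, 1]
                PCz = Pz - charge_pos[iq, 2]
                PC = (PCx, PCy, PCz)
                T = p * (PCx ** 2 + PCy ** 2 + PCz ** 2)
                _boys_nb(Ltot, T, F)
                for m in range(Ltot + 1):
                    v[m, 0] = base * F[m]
                for e in range(1, Ltot + 1):
                    for ft in range(_OFF[e], _OFF[e + 1]):
                        ax = _first_axis(ft)
                        fm1 = _DEC[ax, ft]
                        fm2 = _DEC[ax, fm1]
                        ei = _COMPS[fm1, ax]
                        for m in range(Ltot + 1 - e):
                            val = PA[ax] * v[m, fm1] - PC[ax] * v[m + 1, fm1]
                            if fm2 >= 0 and ei > 0:
                                val += ei / (2.0 * p) * (
                                    v[m, fm2] - v[m + 1, fm2]
                                )
                            v[m, ft] = val
                for t in range(nflat):
                    ctr[t] += -q * v[0, t]

    # HRR: (a, b+1) = ((a+1), b) + AB (a, b)
    ncb = _OFF[lb + 1] - _OFF[lb]
    prev = ctr.reshape(nflat, 1)
    for bl in range(1, lb + 1):
        nb_l = _OFF[bl + 1] - _OFF[bl]
        nxt = np.zeros((nflat, nb_l))
        for tb in range(nb_l):
            ftb = _OFF[bl] + tb
            ax = _first_axis(ftb)
            tbm = _DEC[ax, ftb] - _OFF[bl - 1]
            for te in range(_OFF[la], _OFF[Ltot - bl + 1]):
                tep = _INC[ax, te]
                if tep < 0:
                    continue
                nxt[te, tb] = prev[tep, tbm] + AB[ax] * prev[te, tbm]
        prev = nxt

    nca = _OFF[la + 1] - _OFF[la]
    out = np.empty((nca, ncb))
    for t in range(nca):
        for tb in range(ncb):
            out[t, tb] = prev[_OFF[la] + t, tb]
    return out
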