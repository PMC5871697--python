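"""Exchange-correlation functionals: LDA (Slater x + PW92 c) and PBE.

Closed-shell (spin-unpolarized) forms only.  All quantities are per
grid point: ``exc`` is energy per particle, ``vrho`` = d(rho*exc)/d(rho),
``vsigma`` = d(rho*exc)/d(sigma) with sigma = |grad rho|^2.  The PBE
constants are the published ones, so its uniform-density limit is
exactly the LDA value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

RHO_CLAMP = 1e-14

# Slater exchange
_CX = -(3.0 / 4.0) * (3.0 / np.pi) ** (1.0 / 3.0)

# PW92 correlation, unpolarized parameter set
_PW_A = 0.0310907
_PW_A1 = 0.21370
_PW_B1 = 7.5957
_PW_B2 = 3.5876
_PW_B3 = 1.6382
_PW_B4 = 0.49294

# PBE
PBE_KAPPA = 0.804
PBE_MU = 0.2195149727645171
PBE_BETA = 0.06672455060314922
PBE_GAMMA = (1.0 - np.log(2.0)) / np.pi**2


@dataclass(frozen=True)
class XCFunctionalSpec:
    name: str  # "lda" or "pbe"

    def __post_init__(self):
        if self.name.lower() not in ("lda", "pbe"):
            raise ValueError(f"unknown functional {self.name!r} (lda or pbe)")

    @property
    def is_gga(self) -> bool:
        return self.name.lower() == "pbe"


def _slater_x(rho):
    ex = _CX * rho ** (1.0 / 3.0)
    vx = (4.0 / 3.0) * ex
    return ex, vx


def _pw92_c(rho):
    rs = (3.0 / (4.0 * np.pi * rho)) ** (1.0 / 3.0)
    srs = np.sqrt(rs)
    Q = 2.0 * _PW_A * (
        _PW_B1 * srs + _PW_B2 * rs + _PW_B3 * rs * srs + _PW_B4 * rs * rs
    )
    log_term = np.log1p(1.0 / Q)
    ec = -2.0 * _PW_A * (1.0 + _PW_A1 * rs) * log_term
    dQ = 2.0 * _PW_A * (
        0.5 * _PW_B1 / srs + _PW_B2 + 1.5 * _PW_B3 * srs + 2.0 * _PW_B4 * rs
    )
    dec_drs = (
        -2.0 * _PW_A * _PW_A1 * log_term
        + 2.0 * _PW_A * (1.0 + _PW_A1 * rs) * dQ / (Q * (Q + 1.0))
    )
    vc = ec - (rs / 3.0) * dec_drs
    return ec, vc, dec_drs, rs


def _pbe_x(rho, sigma):
    exl, _ = _slater_x(rho)
    kf2 = (3.0 * np.pi**2 * rho) ** (2.0 / 3.0)
    s2 = sigma / (4.0 * kf2 * rho**2)
    u = PBE_MU * s2 / PBE_KAPPA
    F = 1.0 + PBE_KAPPA - PBE_KAPPA / (1.0 + u)
    dF_ds2 = PBE_MU / (1.0 + u) ** 2
    ex = exl * F
    # e = rho * exl(rho) * F(s2); exl ~ rho^{1/3}
    ds2_drho = -(8.0 / 3.0) * s2 / rho
    ds2_dsigma = s2 / np.where(sigma > 0, sigma, 1.0)
    ds2_dsigma = np.where(
        sigma > 0, ds2_dsigma, 1.0 / (4.0 * kf2 * rho**2)
    )
    vrho = (4.0 / 3.0) * exl * F + rho * exl * dF_ds2 * ds2_drho
    vsigma = rho * exl * dF_ds2 * ds2_dsigma
    return ex, vrho, vsigma


def _pbe_c(rho, sigma):
    ec_lda, vc_lda, dec_drs, rs = _pw92_c(rho)
    kf = (3.0 * np.pi**2 * rho) ** (1.0 / 3.0)
    ks2 = 4.0 * kf / np.pi
    y = sigma / (4.0 * ks2 * rho**2)  # t^2
    expfac = np.exp(-ec_lda / PBE_GAMMA)
    A = (PBE_BETA / PBE_GAMMA) / (expfac - 1.0)
    N = y * (1.0 + A * y)
    D = 1.0 + A * y + (A * y) ** 2
    g = N / D
    arg = 1.0 + (PBE_BETA / PBE_GAMMA) * g
    H = PBE_GAMMA * np.log(arg)
    gy = ((1.0 + 2.0 * A * y) * D - N * (A + 2.0 * A**2 * y)) / D**2
    gA = (y**2 * D - N * (y + 2.0 * A * y**2)) / D**2
    H_y = PBE_BETA * gy / arg
    H_A = PBE_BETA * gA / arg
    dA_dec = A**2 / PBE_BETA + A / PBE_GAMMA
    drs_drho = -rs / (3.0 * rho)
    dy_drho = -(7.0 / 3.0) * y / rho
    dy_dsigma = y / np.where(sigma > 0, sigma, 1.0)
    dy_dsigma = np.where(sigma > 0, dy_dsigma, 1.0 / (4.0 * ks2 * rho**2))
    dec_lda_drho = dec_drs * drs_drho
    ec = ec_lda + H
    vrho = ec + rho * (
        dec_lda_drho + H_y * dy_drho + H_A * dA_dec * dec_lda_drho
    )
    vsigma = rho * H_y * dy_dsigma
    return ec, vrho, vsigma


def eval_xc(rho, sigma=None, functional: XCFunctionalSpec | str = "lda"):
    """Evaluate exc (per particle), vrho, vsigma on arrays of grid values.

    Tiny/negative densities are clamped at ``RHO_CLAMP``; their
    contributions are zeroed.
    """
    if isinstance(functional, str):
        functional = XCFunctionalSpec(functional)
    rho = np.asarray(rho, dtype=float)
    tiny = rho < RHO_CLAMP
    rho = np.where(tiny, RHO_CLAMP, rho)
    if functional.is_gga:
        if sigma is None:
            raise ValueError("PBE requires sigma = |grad rho|^2")
        sigma = np.maximum(np.asarray(sigma, dtype=float), 0.0)
        ex, vxr, vxs = _pbe_x(rho, sigma)
        ec, vcr, vcs = _pbe_c(rho, sigma)
        exc, vrho, vsigma = ex + ec, vxr + vcr, vxs + vcs
    else:
        ex, vx = _slater_x(rho)
        ec, vc, _, _ = _pw92_c(rho)
        exc, vrho, vsigma = ex + ec, vx + vc, np.zeros_like(rho)
    exc = np.where(tiny, 0.0, exc)
    vrho = np.where(tiny, 0.0, vrho)
    vsigma = np.where(tiny, 0.0, vsigma)
    return exc, vrho, vsigma
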