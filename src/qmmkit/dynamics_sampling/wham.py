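"""Weighted-histogram analysis of umbrella-sampling windows.

User surface is kcal/mol and Angstrom.  The self-consistent WHAM
equations are iterated until the per-window free-energy constants stop
moving; the profile is shifted so its minimum is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..constants import KB_KCALMOL

logger = logging.getLogger(__name__)


@dataclass
class WindowSamples:
    rc_series: np.ndarray  # Angstrom
    rc0: float  # Angstrom
    k_umb: float  # kcal/mol/A^2
    temperature: float = 300.0  # K

    def __post_init__(self):
        self.rc_series = np.asarray(self.rc_series, dtype=float).reshape(-1)
        if len(self.rc_series) < 1:
            raise ValueError("window has no samples")
        if not np.all(np.isfinite(self.rc_series)):
            raise ValueError("non-finite rc samples")
        if self.k_umb < 0:
            raise ValueError("negative force constant")


@dataclass
class FreeEnergyProfile:
    bin_centers: np.ndarray  # Angstrom
    free_energy: np.ndarray  # kcal/mol, min = 0
    uncertainty: np.ndarray  # kcal/mol, crude Poisson estimate
    window_offsets: np.ndarray = field(default=None)

    def value_at(self, rc: float) -> float:
        return float(np.interp(rc, self.bin_centers, self.free_energy))


class WhamOverlapError(RuntimeError):
    pass


def wham(windows, nbins: int = 100, tol: float = 1e-8, max_iter: int = 100000,
         rc_range=None) -> FreeEnergyProfile:
    """Reconstruct the unbiased free-energy profile from biased windows."""
    windows = list(windows)
    if len(windows) < 1:
        raise ValueError("need at least one window")
    T = windows[0].temperature
    for w in windows:
        if abs(w.temperature - T) > 1e-9:
            raise ValueError("windows at different temperatures are not supported")
    beta = 1.0 / (KB_KCALMOL * T)

    if rc_range is None:
        lo = min(w.rc_series.min() for w in windows)
        hi = max(w.rc_series.max() for w in windows)
        pad = 1e-9 * max(1.0, abs(hi - lo))
        rc_range = (lo - pad, hi + pad)
    edges = np.linspace(rc_range[0], rc_range[1], nbins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    nw = len(windows)
    H = np.zeros((nw, nbins))
    N = np.zeros(nw)
    for i, w in enumerate(windows):
        h, _ = np.histogram(w.rc_series, bins=edges)
        H[i] = h
        N[i] = h.sum()
    counts = H.sum(axis=0)

    _check_overlap(windows, H)

    # bias factor per window per bin
    bias = np.array([
        np.exp(-beta * 0.5 * w.k_umb * (centers - w.rc0) ** 2) for w in windows
    ])
    f = np.zeros(nw)  # exp(beta f_i) accumulators as free energies
    for it in range(max_iter):
        expf = np.exp(beta * f)
        denom = (N * expf) @ bias  # (nbins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(denom > 0, counts / denom, 0.0)
        norm = (bias * P[None, :]).sum(axis=1)
        f_new = -np.log(np.where(norm > 0, norm, 1.0)) / beta
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:  # pragma: no cover
        logger.warning("WHAM did not reach tol=%g in %d iterations (delta=%g)",
                       tol, max_iter, delta)

    with np.errstate(divide="ignore"):
        F = np.where(P > 0, -np.log(np.where(P > 0, P, 1.0)) / beta, np.inf)
    finite = np.isfinite(F)
    F = F - F[finite].min()
    err = np.where(counts > 0, 1.0 / (beta * np.sqrt(np.maximum(counts, 1))), np.inf)
    keep = finite
    return FreeEnergyProfile(centers[keep], F[keep], err[keep], f)


def _check_overlap(windows, H):
    """Order windows by center and check adjacent histogram overlap."""
    if len(windows) < 2:
        return
    order = np.argsort([w.rc0 for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        shared = np.minimum(H[a], H[b]).sum()
        if shared == 0:
            raise WhamOverlapError(
                f"no histogram overlap between windows at rc0="
                f"{windows[a].rc0:g} and rc0={windows[b].rc0:g}"
            )
        if shared < 5:
            logger.warning(
                "windows at rc0=%g and rc0=%g share only %d counts",
                windows[a].rc0, windows[b].rc0, int(shared),
            )


def barrier_from_profile(profile: FreeEnergyProfile, reactant_range, ts_range) -> float:
    """Activation free energy: max over ts_range minus min over reactant_range."""
    rc = profile.bin_centers
    F = profile.free_energy
    rmask = (rc >= reactant_range[0]) & (rc <= reactant_range[1])
    tmask = (rc >= ts_range[0]) & (rc <= ts_range[1])
    if not rmask.any() or not tmask.any():
        raise ValueError("range selects no profile bins")
    return float(F[tmask].max() - F[rmask].min())
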