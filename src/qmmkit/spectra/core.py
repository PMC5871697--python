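"""Spectra from time series: autocorrelations, IR/VDOS, UV-vis kick
spectra post-processing, ensemble averaging and convergence diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import (
    AMU_TO_AU,
    CM1_PER_HARTREE,
    EV_NM,
    EV_PER_HARTREE,
    FS_PER_AUTIME,
)


@dataclass
class SignalSeries:
    values: np.ndarray  # (nframes,) or (nframes, d)
    dt: float  # a.u. time

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] < 16:
            raise ValueError("series too short (< 16 frames)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class Spectrum:
    abscissa: np.ndarray  # strictly monotone
    intensity: np.ndarray
    kind: str = ""  # e.g. "wavenumber_cm1", "wavelength_nm", "energy_ev"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        d = np.diff(self.abscissa)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("abscissa must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensity")


@dataclass
class EnsembleSpectrum:
    members: list
    average: Spectrum
    n: int


def autocorrelation(series: SignalSeries, max_lag: int) -> np.ndarray:
    """Origin-averaged correlation C(lag) = <s(t) . s(t+lag)>.

    For vector-valued series the dot product over components is used.
    """
    v = series.values
    n = v.shape[0]
    if max_lag >= n / 2:
        raise ValueError("max_lag must be < length/2")
    if v.ndim == 1:
        v = v[:, None]
    c = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        prod = np.einsum("td,td->t", v[: n - lag], v[lag:])
        c[lag] = prod.mean()
    return c


def _window(n: int, kind: str) -> np.ndarray:
    if kind == "hann":
        return np.hanning(2 * n - 1)[n - 1:]  # half-window, length n, 1 at lag 0
    if kind in (None, "none", "rect"):
        return np.ones(n)
    raise ValueError(f"unknown window {kind!r}")


def ir_spectrum(series: SignalSeries, max_lag: int | None = None,
                window: str = "hann", padding: int = 4) -> Spectrum:
    """I(omega) from the cosine transform of the windowed dipole
    autocorrelation; abscissa in cm^-1, symmetrized (C(-t)=C(t)) so the
    result is real and non-negative up to windowing leakage."""
    n = series.values.shape[0]
    if max_lag is None:
        max_lag = n // 2 - 1
    c = autocorrelation(series, max_lag)
    w = _window(max_lag + 1, window)
    cw = c * w
    m = int(2 ** np.ceil(np.log2((max_lag + 1) * max(1, padding))))
    # cosine transform: I = dt * (C(0)/2 + sum_{t>0} C(t) cos(w t))
    spec = np.fft.rfft(np.concatenate([cw, np.zeros(2 * m - len(cw))]))
    intensity = series.dt * (np.real(spec) - 0.5 * cw[0])
    freqs = np.fft.rfftfreq(2 * m, d=series.dt)  # cycles / a.u. time
    omega = 2.0 * np.pi * freqs  # rad / a.u. time == Hartree
    wavenumber = omega * CM1_PER_HARTREE
    return Spectrum(wavenumber, intensity, "wavenumber_cm1",
                    {"window": window, "max_lag": max_lag, "dt": series.dt})


def normal_modes_fd(positions: np.ndarray, masses_amu: np.ndarray,
                    energy_forces, step: float = 5e-3,
                    drop_trans_rot: bool = True):
    """Harmonic analysis by central differences of forces.

    ``energy_forces(x) -> (E, F)`` in a.u.  Returns (frequencies_cm1,
    modes) with modes[k] a (natoms, 3) Cartesian displacement pattern
    (mass-weighted normal modes back-transformed, unit mass-weighted
    norm).  Near-zero translation/rotation modes are removed.
    """
    x0 = np.asarray(positions, dtype=float)
    n = x0.shape[0]
    m_au = np.repeat(np.asarray(masses_amu, dtype=float) * AMU_TO_AU, 3)
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for ax in range(3):
            xp = x0.copy(); xp[i, ax] += step
            xm = x0.copy(); xm[i, ax] -= step
            _, fp = energy_forces(xp)
            _, fm = energy_forces(xm)
            hess[3 * i + ax] = -(fp - fm).ravel() / (2.0 * step)
    asym = np.max(np.abs(hess - hess.T))
    hess = 0.5 * (hess + hess.T)
    mw = hess / np.sqrt(np.outer(m_au, m_au))
    evals, evecs = np.linalg.eigh(mw)
    freqs = np.sign(evals) * np.sqrt(np.abs(evals)) * CM1_PER_HARTREE
    if np.any(freqs < -100.0):
        import logging
        logging.getLogger(__name__).warning(
            "large imaginary frequency (%.1f cm^-1): not at a minimum", freqs.min()
        )
    if drop_trans_rot:
        keep = np.abs(freqs) > 15.0  # cm^-1
    else:
        keep = np.ones(len(freqs), dtype=bool)
    freqs = freqs[keep]
    modes = evecs[:, keep].T.reshape(-1, n, 3)
    order = np.argsort(freqs)
    return freqs[order], modes[order], asym


def vdos_projected(velocities: np.ndarray, masses_amu: np.ndarray,
                   modes: np.ndarray, dt: float, max_lag: int | None = None,
                   window: str = "hann"):
    """Per-mode vibrational density of states.

    Mass-weighted velocities are projected on each mode vector; each
    projection is autocorrelated and cosine-transformed.  Returns a list
    of Spectrum (one per mode) on a shared wavenumber grid.
    """
    v = np.asarray(velocities, dtype=float)  # (nframes, n, 3)
    sq_m = np.sqrt(np.asarray(masses_amu, dtype=float) * AMU_TO_AU)[None, :, None]
    mwv = (v * sq_m).reshape(v.shape[0], -1)
    out = []
    for k in range(modes.shape[0]):
        mode = modes[k].reshape(-1)
        proj = mwv @ mode
        out.append(ir_spectrum(SignalSeries(proj, dt), max_lag, window))
    return out


def vdos_total(velocities: np.ndarray, masses_amu: np.ndarray, dt: float,
               max_lag: int | None = None, window: str = "hann") -> Spectrum:
    v = np.asarray(velocities, dtype=float)
    sq_m = np.sqrt(np.asarray(masses_amu, dtype=float) * AMU_TO_AU)[None, :, None]
    mwv = (v * sq_m).reshape(v.shape[0], -1)
    return ir_spectrum(SignalSeries(mwv, dt), max_lag, window)


SHARED_LAMBDA_GRID = np.arange(100.0, 800.0 + 1e-9, 0.5)  # nm


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto a shared abscissa (zero outside support)."""
    x = spectrum.abscissa
    y = spectrum.intensity
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    out = np.interp(grid, x, y, left=0.0, right=0.0)
    return Spectrum(grid, out, spectrum.kind, dict(spectrum.metadata))


def ensemble_average(members: list) -> EnsembleSpectrum:
    """E(lambda) = (1/N) sum_j e_j(lambda) on an identical shared grid."""
    if not members:
        raise ValueError("no member spectra")
    grid = members[0].abscissa
    for s in members[1:]:
        if s.abscissa.shape != grid.shape or not np.allclose(s.abscissa, grid):
            raise ValueError("member spectra must share one abscissa grid")
    avg = np.mean([s.intensity for s in members], axis=0)
    return EnsembleSpectrum(list(members), Spectrum(grid, avg, members[0].kind),
                            len(members))


def lambda_max(spectrum: Spectrum, search_range=None) -> float:
    """Abscissa of the maximum, refined by a parabola through the three
    points around the discrete peak."""
    x = spectrum.abscissa
    y = spectrum.intensity
    mask = np.ones(len(x), dtype=bool)
    if search_range is not None:
        mask = (x >= search_range[0]) & (x <= search_range[1])
        if not mask.any():
            raise ValueError("search range selects no points")
    if np.ptp(y[mask]) < 1e-300:
        raise ValueError("no peak: spectrum is flat in the search range")
    ys = np.where(mask, y, -np.inf)
    i = int(np.argmax(ys))
    if 0 < i < len(x) - 1 and mask[i - 1] and mask[i + 1]:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if abs(denom) > 1e-300:
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            return float(x[i] + delta * (x[min(i + 1, len(x) - 1)] - x[i]))
    return float(x[i])


def convergence_curve(members: list, metric: str = "lambda_max",
                      threshold: float | None = None, consecutive: int = 5,
                      search_range=None):
    """Running-mean convergence diagnostics over an ordered spectra set.

    metric "lambda_max": |lambda_max(mean_N) - lambda_max(mean_{N-1})|.
    metric "l2": relative L2 distance between successive running means.
    Returns (values per N, converged_at or None).
    """
    if metric not in ("lambda_max", "l2"):
        raise ValueError(f"unknown metric {metric!r}")
    if threshold is None:
        threshold = 1.0 if metric == "lambda_max" else 1e-2
    grid = members[0].abscissa
    running = np.zeros_like(grid)
    vals = [np.nan]
    prev_mean = None
    prev_lmax = None
    for n, s in enumerate(members, start=1):
        running += s.intensity
        mean = running / n
        if metric == "lambda_max":
            lm = lambda_max(Spectrum(grid, mean, s.kind), search_range)
            if prev_lmax is not None:
                vals.append(abs(lm - prev_lmax))
            prev_lmax = lm
        else:
            if prev_mean is not None:
                num = np.linalg.norm(mean - prev_mean)
                den = max(np.linalg.norm(mean), 1e-300)
                vals.append(num / den)
            prev_mean = mean.copy()
    vals = np.array(vals[: len(members)])
    # converged at N: every observed metric value after N stays below the
    # threshold (looking at up to `consecutive` subsequent additions)
    converged_at = None
    nmem = len(members)
    for n in range(1, nmem + 1):
        tail = vals[n: min(n + consecutive, nmem)]
        tail = tail[~np.isnan(tail)]
        if len(tail) == 0:
            continue
        if np.all(tail < threshold):
            converged_at = n
            break
    if nmem == 1:
        converged_at = 1
    return vals, converged_at


def kick_spectrum(times: np.ndarray, mu_induced: np.ndarray, kick_strength: float,
                  damping_time_fs: float = 2.5, padding: int = 4) -> Spectrum:
    """Absorption S(omega) = omega * Im[FT(mu(t) e^{-t/tau})] / kappa.

    ``mu_induced`` is the induced dipole component along the kick
    direction (or the isotropic average of three runs).  Returns a
    Spectrum on an energy-eV abscissa with wavelength metadata.
    """
    if damping_time_fs <= 0:
        raise ValueError("damping time must be positive")
    t = np.asarray(times, dtype=float)
    mu = np.asarray(mu_induced, dtype=float)
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-8):
        raise ValueError("time grid must be uniform")
    tau = damping_time_fs / FS_PER_AUTIME
    sig = mu * np.exp(-t / tau)
    m = int(2 ** np.ceil(np.log2(len(sig) * max(1, padding))))
    ft = np.fft.rfft(sig, n=2 * m)
    omega = 2.0 * np.pi * np.fft.rfftfreq(2 * m, d=dt)
    # sign fixed so that absorption comes out positive for the e^{+ik D}
    # kick convention used by the propagator
    s = omega * np.imag(ft) * dt / kick_strength
    ev = omega * EV_PER_HARTREE
    with np.errstate(divide="ignore"):
        lam = np.where(ev > 0, EV_NM / np.where(ev > 0, ev, 1.0), np.inf)
    return Spectrum(ev, s, "energy_ev", {"lambda_nm": lam, "tau_fs": damping_time_fs})


def spectrum_in_nm(spectrum: Spectrum, lam_lo: float = 100.0,
                   lam_hi: float = 800.0) -> Spectrum:
    """Convert an energy-eV kick spectrum onto an ascending nm axis."""
    ev = spectrum.abscissa
    lam = np.where(ev > 0, EV_NM / np.where(ev > 0, ev, 1.0), np.inf)
    mask = (lam >= lam_lo) & (lam <= lam_hi)
    lam_sel = lam[mask][::-1]
    int_sel = spectrum.intensity[mask][::-1]
    return Spectrum(lam_sel, int_sel, "wavelength_nm", dict(spectrum.metadata))
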