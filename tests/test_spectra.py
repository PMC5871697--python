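import numpy as np
import pytest

from qmmkit.constants import AMU_TO_AU, CM1_PER_HARTREE
from qmmkit.dynamics_sampling import HarmonicBond, MDState, bomd_step
from qmmkit.spectra import (
    SignalSeries,
    Spectrum,
    autocorrelation,
    convergence_curve,
    ensemble_average,
    ir_spectrum,
    lambda_max,
    normal_modes_fd,
    resample,
    vdos_projected,
    vdos_total,
)


def cm1_to_omega(nu_cm1):
    return nu_cm1 / CM1_PER_HARTREE  # rad / a.u. time


class TestAutocorrelation:
    def test_constant_series(self):
        s = SignalSeries(np.full(100, 3.0), 1.0)
        c = autocorrelation(s, 20)
        np.testing.assert_allclose(c, 9.0, atol=1e-12)

    def test_cosine_series(self):
        w = 0.3
        t = np.arange(4000) * 0.5
        s = SignalSeries(np.cos(w * t), 0.5)
        c = autocorrelation(s, 200)
        lags = np.arange(201) * 0.5
        np.testing.assert_allclose(c, 0.5 * np.cos(w * lags), atol=0.02)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(0)
        n = 20000
        s = SignalSeries(rng.standard_normal(n), 1.0)
        c = autocorrelation(s, 50)
        assert c[0] == pytest.approx(1.0, abs=0.05)
        assert np.max(np.abs(c[1:])) < 3.0 / np.sqrt(n - 50)

    def test_max_lag_validation(self):
        s = SignalSeries(np.zeros(40), 1.0)
        with pytest.raises(ValueError):
            autocorrelation(s, 30)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            SignalSeries(np.zeros(8), 1.0)


class TestIRSpectrum:
    def test_single_cosine_peak_at_frequency(self):
        nu = 642.0  # cm^-1
        w = cm1_to_omega(nu)
        dt = 10.0
        t = np.arange(8192) * dt
        spec = ir_spectrum(SignalSeries(np.cos(w * t), dt))
        peak = spec.abscissa[np.argmax(spec.intensity)]
        res = spec.abscissa[1] - spec.abscissa[0]
        assert abs(peak - nu) <= 2 * res

    def test_two_cosines_intensity_ratio(self):
        w1, w2 = cm1_to_omega(600.0), cm1_to_omega(1500.0)
        a1, a2 = 2.0, 1.0
        dt = 8.0
        t = np.arange(16384) * dt
        sig = a1 * np.cos(w1 * t) + a2 * np.cos(w2 * t)
        spec = ir_spectrum(SignalSeries(sig, dt))
        x, y = spec.abscissa, spec.intensity
        i1 = y[np.abs(x - 600.0) < 50].max()
        i2 = y[np.abs(x - 1500.0) < 50].max()
        assert i1 / i2 == pytest.approx((a1 / a2) ** 2, rel=0.05)

    def test_harmonic_diatomic_md_peak(self):
        # analytic-force MD of a harmonic diatomic; expected peak
        # nu = (1/2 pi c) sqrt(k/mu) -> in a.u. omega = sqrt(k/mu)
        k = 0.3
        m1, m2 = 2000.0, 3000.0
        mu_red = m1 * m2 / (m1 + m2)
        omega = np.sqrt(k / mu_red)
        pot = HarmonicBond(0, 1, k, 2.0)
        state = MDState(
            np.array([[0.0, 0, 0], [0.0, 0, 2.15]]), np.zeros((2, 3)), [m1, m2]
        )
        dt = 5.0
        dip = []
        for _ in range(4096):
            state = bomd_step(pot, state, dt)
            # fake dipole proportional to bond length
            dip.append(state.positions[1, 2] - state.positions[0, 2])
        dip = np.array(dip)
        dip -= dip.mean()  # remove the elastic (zero-frequency) line
        spec = ir_spectrum(SignalSeries(dip, dt))
        peak = spec.abscissa[np.argmax(spec.intensity)]
        res = spec.abscissa[1] - spec.abscissa[0]
        assert abs(peak - omega * CM1_PER_HARTREE) <= 2 * res

    def test_parseval_like_consistency(self):
        rng = np.random.default_rng(1)
        sig = rng.standard_normal(2048)
        dt = 1.0
        series = SignalSeries(sig, dt)
        c = autocorrelation(series, 512)
        spec = ir_spectrum(series, max_lag=512, window="rect")
        # integral of I(omega) d(omega) over the half-line ~ (pi/2) C(0)
        omega = spec.abscissa / CM1_PER_HARTREE
        integral = np.trapezoid(spec.intensity, omega)
        assert integral == pytest.approx(np.pi / 2 * c[0], rel=0.05)


class TestNormalModes:
    def test_diatomic_closed_form(self):
        k = 0.25
        m = [3000.0, 5000.0]  # in amu units below
        m_amu = [m[0] / AMU_TO_AU, m[1] / AMU_TO_AU]
        mu_red = m[0] * m[1] / (m[0] + m[1])
        pot = HarmonicBond(0, 1, k, 2.0)
        x0 = np.array([[0.0, 0, 0], [0.0, 0, 2.0]])
        freqs, modes, asym = normal_modes_fd(x0, m_amu, pot.energy_forces)
        assert len(freqs) == 1
        expected = np.sqrt(k / mu_red) * CM1_PER_HARTREE
        assert freqs[0] == pytest.approx(expected, rel=1e-5)

    def test_triatomic_bend_below_stretch(self):
        # two stiff bonds + soft angle: bending frequency must come lowest
        class BondsAngle:
            def __init__(self, kb, ka):
                self.b1 = HarmonicBond(0, 1, kb, 1.8)
                self.b2 = HarmonicBond(1, 2, kb, 1.8)
                self.ka = ka

            def energy_forces(self, x):
                e1, f1 = self.b1.energy_forces(x)
                e2, f2 = self.b2.energy_forces(x)
                # harmonic in the 0-1-2 angle
                v1 = x[0] - x[1]
                v2 = x[2] - x[1]
                c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                th = np.arccos(np.clip(c, -1, 1))
                th0 = np.deg2rad(104.0)
                e3 = 0.5 * self.ka * (th - th0) ** 2
                f3 = np.zeros_like(x)
                h = 1e-6
                for i in range(3):
                    for ax in range(3):
                        xp = x.copy(); xp[i, ax] += h
                        xm = x.copy(); xm[i, ax] -= h
                        f3[i, ax] = -(self._angle_e(xp) - self._angle_e(xm)) / (2 * h)
                return e1 + e2 + e3, f1 + f2 + f3

            def _angle_e(self, x):
                v1 = x[0] - x[1]
                v2 = x[2] - x[1]
                c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                th = np.arccos(np.clip(c, -1, 1))
                return 0.5 * self.ka * (th - np.deg2rad(104.0)) ** 2

        pot = BondsAngle(kb=0.6, ka=0.05)
        th = np.deg2rad(104.0)
        x0 = 1.8 * np.array([
            [np.sin(th / 2), 0.0, np.cos(th / 2)],
            [0.0, 0.0, 0.0],
            [-np.sin(th / 2), 0.0, np.cos(th / 2)],
        ])
        freqs, modes, _ = normal_modes_fd(x0, [1.0, 16.0, 1.0], pot.energy_forces)
        assert len(freqs) == 3
        assert freqs[0] < freqs[1] <= freqs[2]
        assert freqs[0] < 0.6 * freqs[1]  # bend clearly below stretches

    def test_hessian_symmetry(self):
        pot = HarmonicBond(0, 1, 0.4, 2.0)
        x0 = np.array([[0.1, -0.2, 0], [0.0, 0.1, 2.0]])
        _, _, asym = normal_modes_fd(x0, [1.0, 2.0], pot.energy_forces)
        assert asym < 2e-6  # fd self-consistency bound


class TestVDOS:
    def _modes_and_traj(self):
        # 1-D two-atom chain: one vibrational mode along z; the Hessian is
        # taken at the true minimum so rotations come out at zero frequency
        k = 0.2
        pot = HarmonicBond(0, 1, k, 2.0)
        masses_amu = [2.0, 3.0]
        x_eq = np.array([[0.0, 0, 0], [0.0, 0, 2.0]])
        freqs, modes, _ = normal_modes_fd(x_eq, masses_amu, pot.energy_forces)
        x0 = np.array([[0.0, 0, 0], [0.0, 0, 2.1]])
        state = MDState(x0, np.zeros((2, 3)),
                        np.array(masses_amu) * AMU_TO_AU)
        vel = []
        for _ in range(2048):
            state = bomd_step(pot, state, 5.0)
            vel.append(state.velocities.copy())
        return freqs, modes, np.array(vel), masses_amu

    def test_single_mode_motion_projects_to_one_mode(self):
        freqs, modes, vel, masses = self._modes_and_traj()
        specs = vdos_projected(vel, masses, modes, 5.0)
        powers = [np.trapezoid(s.intensity, s.abscissa) for s in specs]
        assert powers[0] > 0
        assert len(specs) == len(freqs)

    def test_mode_orthonormality(self):
        freqs, modes, _, _ = self._modes_and_traj()
        flat = modes.reshape(len(freqs), -1)
        gram = flat @ flat.T
        np.testing.assert_allclose(gram, np.eye(len(freqs)), atol=1e-6)

    def test_projected_power_sums_to_total(self):
        # complete mode set: project on ALL mass-weighted eigenvectors
        # (including translations/rotations) and compare with total VDOS
        k = 0.2
        pot = HarmonicBond(0, 1, k, 2.0)
        masses_amu = [2.0, 3.0]
        x0 = np.array([[0.0, 0, 0], [0.0, 0, 2.1]])
        freqs, modes, _ = normal_modes_fd(x0, masses_amu, pot.energy_forces,
                                          drop_trans_rot=False)
        rng = np.random.default_rng(5)
        state = MDState(x0, rng.standard_normal((2, 3)) * 1e-4,
                        np.array(masses_amu) * AMU_TO_AU)
        vel = []
        for _ in range(1024):
            state = bomd_step(pot, state, 5.0)
            vel.append(state.velocities.copy())
        vel = np.array(vel)
        per_mode = vdos_projected(vel, masses_amu, modes, 5.0, window="rect")
        total = vdos_total(vel, masses_amu, 5.0, window="rect")
        summed = np.sum([s.intensity for s in per_mode], axis=0)
        np.testing.assert_allclose(summed, total.intensity, atol=1e-8)


class TestEnsemble:
    def _lorentzian(self, grid, center, width=10.0, height=1.0):
        return Spectrum(grid, height * width**2 / ((grid - center) ** 2 + width**2),
                        "wavelength_nm")

    def test_identical_members_average_is_member(self):
        grid = np.linspace(100, 800, 701)
        s = self._lorentzian(grid, 400.0)
        ens = ensemble_average([s, s, s])
        np.testing.assert_allclose(ens.average.intensity, s.intensity)
        assert ens.n == 3

    def test_permutation_invariance(self):
        grid = np.linspace(100, 800, 701)
        members = [self._lorentzian(grid, c) for c in (300, 400, 500)]
        e1 = ensemble_average(members)
        e2 = ensemble_average(members[::-1])
        np.testing.assert_allclose(e1.average.intensity, e2.average.intensity)

    def test_two_delta_like_members_half_heights(self):
        grid = np.linspace(100, 800, 1401)
        s1 = self._lorentzian(grid, 300.0, width=2.0)
        s2 = self._lorentzian(grid, 500.0, width=2.0)
        ens = ensemble_average([s1, s2])
        y = ens.average.intensity
        assert y[np.abs(grid - 300) < 1].max() == pytest.approx(0.5, abs=0.01)
        assert y[np.abs(grid - 500) < 1].max() == pytest.approx(0.5, abs=0.01)

    def test_exact_formula(self):
        rng = np.random.default_rng(2)
        grid = np.linspace(100, 800, 200)
        members = [Spectrum(grid, rng.random(200), "wavelength_nm") for _ in range(7)]
        ens = ensemble_average(members)
        ref = np.mean([m.intensity for m in members], axis=0)
        assert np.array_equal(ens.average.intensity, ref)

    def test_linearity_of_concatenated_sets(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(100, 800, 100)
        a = [Spectrum(grid, rng.random(100), "") for _ in range(3)]
        b = [Spectrum(grid, rng.random(100), "") for _ in range(5)]
        e_all = ensemble_average(a + b).average.intensity
        e_a = ensemble_average(a).average.intensity
        e_b = ensemble_average(b).average.intensity
        np.testing.assert_allclose(e_all, (3 * e_a + 5 * e_b) / 8, atol=1e-14)

    def test_mismatched_grids_rejected(self):
        s1 = Spectrum(np.linspace(100, 800, 100), np.zeros(100), "")
        s2 = Spectrum(np.linspace(100, 800, 101), np.zeros(101), "")
        with pytest.raises(ValueError):
            ensemble_average([s1, s2])


class TestLambdaMax:
    def test_lorentzian_center(self):
        grid = np.linspace(100, 800, 1401)
        width = 25.0
        s = Spectrum(grid, 1.0 / ((grid - 437.3) ** 2 + width**2), "wavelength_nm")
        assert lambda_max(s) == pytest.approx(437.3, abs=0.5)

    def test_flat_spectrum_raises(self):
        s = Spectrum(np.linspace(100, 800, 100), np.ones(100), "")
        with pytest.raises(ValueError, match="flat|peak"):
            lambda_max(s)

    def test_noisy_lorentzian_vs_fit_oracle(self):
        rng = np.random.default_rng(4)
        grid = np.linspace(300, 500, 401)
        width = 10.0
        clean = 1.0 / ((grid - 412.0) ** 2 + width**2)
        noisy = clean * (1.0 + 2e-4 * rng.standard_normal(len(grid)))
        s = Spectrum(grid, noisy, "wavelength_nm")
        # least-squares Lorentzian fit oracle
        from scipy.optimize import curve_fit

        def lor(x, c, w, a):
            return a / ((x - c) ** 2 + w**2)

        popt, _ = curve_fit(lor, grid, noisy, p0=(400.0, 15.0, 1.0))
        assert lambda_max(s) == pytest.approx(popt[0], abs=0.5)


class TestConvergenceCurve:
    def test_identical_spectra_converge_at_one(self):
        grid = np.linspace(100, 800, 200)
        s = Spectrum(grid, np.exp(-((grid - 400) ** 2) / 500.0), "")
        vals, conv = convergence_curve([s] * 6, metric="lambda_max", threshold=0.5)
        assert conv is not None and conv <= 2

    def test_iid_noise_lambda_drift_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(6)
        grid = np.linspace(100, 800, 500)

        def member():
            c = 400.0 + rng.normal(0, 20.0)
            return Spectrum(grid, np.exp(-((grid - c) ** 2) / 800.0), "")

        members = [member() for _ in range(400)]
        vals, _ = convergence_curve(members, metric="lambda_max", threshold=1e-12)
        # |lmax(mean_N) - lmax(mean_{N-1})| ~ sigma / N / sqrt(N) scaling;
        # compare average drift in early vs late blocks
        early = np.nanmean(vals[5:25])
        late = np.nanmean(vals[200:400])
        assert late < early / 3.0

    def test_adversarial_bimodal_not_flagged(self):
        grid = np.linspace(100, 800, 400)
        s1 = Spectrum(grid, np.exp(-((grid - 250) ** 2) / 200.0), "")
        s2 = Spectrum(grid, np.exp(-((grid - 650) ** 2) / 200.0), "")
        members = [s1, s2] * 4  # alternating peaks keep lambda_max hopping
        vals, conv = convergence_curve(members, metric="lambda_max", threshold=1.0)
        assert conv is None


class TestResample:
    def test_linear_interpolation_on_shared_grid(self):
        x = np.linspace(150, 700, 400)
        s = Spectrum(x, np.sin(x / 50.0) + 2.0, "wavelength_nm")
        grid = np.arange(100.0, 800.5, 0.5)
        r = resample(s, grid)
        assert r.abscissa.shape == grid.shape
        inside = (grid > 160) & (grid < 690)
        np.testing.assert_allclose(
            r.intensity[inside], np.sin(grid[inside] / 50.0) + 2.0, atol=1e-3
        )
        assert np.all(r.intensity[grid < 150] == 0.0)
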