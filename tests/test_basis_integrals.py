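import numpy as np
import pytest

from qmmkit import basis_integrals as bi
from qmmkit.basis_integrals.gaussian94 import BasisParseError, parse_gaussian94
from qmmkit.basis_integrals.shells import BasisSet, GaussianShell, cart_components
from qmmkit.geometry import QMGeometry
from qmmkit.ks_dft import scf_solve

from oracles import (
    PrimitiveCart,
    attraction_oracle,
    dipole_oracle,
    eri_ssss_closed_form,
    eri_ssss_montecarlo,
    kinetic_oracle,
    overlap_oracle,
)

# exponents of the vendored dzvp oxygen block, cross-checked against the
# public basis-set repository listing for the DGauss DZVP orbital basis
DZVP_O_SHELLS = [
    (0, [5222.9022, 782.53994, 177.26743, 49.516688, 15.66644, 5.1793599]),
    (0, [10.601441, 0.9423170]),
    (0, [0.2774746]),
    (1, [33.424126, 7.6221714, 2.2382093, 0.6867300]),
    (1, [0.1938135]),
    (2, [0.8]),
]


class TestGaussian94Parser:
    def test_sto3g_hydrogen_is_one_shell_three_primitives(self, sto3g):
        shells = sto3g["H"]
        assert len(shells) == 1
        l, exps, coefs = shells[0]
        assert l == 0 and len(exps) == 3 and len(coefs) == 3

    def test_dzvp_oxygen_matches_reference_listing(self, dzvp):
        shells = dzvp["O"]
        assert len(shells) == len(DZVP_O_SHELLS)
        for (l, exps, _), (lref, exps_ref) in zip(shells, DZVP_O_SHELLS):
            assert l == lref
            np.testing.assert_allclose(exps, exps_ref, rtol=1e-7)

    def test_missing_element_raises_naming_it(self):
        with pytest.raises(KeyError, match="Fe"):
            bi.load_bundled_basis("sto-3g", {"Fe"})

    def test_missing_shell_label_is_parse_error_with_line(self):
        bad = "H     0\nQ    3   1.00\n  1.0 1.0\n****\n"
        with pytest.raises(BasisParseError, match="line 2"):
            parse_gaussian94(bad)

    def test_f_shell_rejected(self):
        bad = "H     0\nF    1   1.00\n  1.0 1.0\n****\n"
        with pytest.raises(BasisParseError, match="not supported"):
            parse_gaussian94(bad)

    def test_sp_shell_split(self):
        txt = (
            "C     0\nSP   2   1.00\n"
            "  2.0  0.1  0.3\n  0.5  0.9  0.8\n****\n"
        )
        lib = parse_gaussian94(txt)
        assert [s[0] for s in lib["C"]] == [0, 1]
        np.testing.assert_allclose(lib["C"][0][2], [0.1, 0.9])
        np.testing.assert_allclose(lib["C"][1][2], [0.3, 0.8])

    def test_fortran_d_exponents(self):
        txt = "H     0\nS    1   1.00\n  0.1873113696D+02  1.0\n****\n"
        lib = parse_gaussian94(txt)
        assert lib["H"][0][1][0] == pytest.approx(18.73113696)


class TestShellNormalization:
    @pytest.mark.parametrize("l", [0, 1, 2])
    def test_primitive_self_overlap_unity(self, l):
        sh = GaussianShell(0, l, [0.7354], [1.0])
        geom = QMGeometry(["He"], [[0.0, 0.0, 0.0]])
        basis = BasisSet([sh], geom)
        S = bi.overlap_matrix(basis)
        np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-10)

    def test_contracted_self_overlap_unity(self, h2o_basis):
        S = bi.overlap_matrix(h2o_basis)
        np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-10)

    def test_shell_validation(self):
        with pytest.raises(ValueError):
            GaussianShell(0, 0, [1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            GaussianShell(0, 3, [1.0], [1.0])
        with pytest.raises(ValueError):
            GaussianShell(0, 0, [-1.0], [1.0])


class TestOverlap:
    def test_identical_s_functions_same_center(self):
        geom = QMGeometry(["He"], [[0.0, 0.0, 0.0]])
        shells = [GaussianShell(0, 0, [0.5], [1.0]), GaussianShell(0, 0, [0.5], [1.0])]
        S = bi.overlap_matrix(BasisSet(shells, geom))
        assert S[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_h2_overlap_vs_quadrature(self, h2_basis):
        S = bi.overlap_matrix(h2_basis)
        sh = h2_basis.shells[0]
        val = 0.0
        for ai, ci in zip(sh.exponents, sh.coefs_normalized):
            for aj, cj in zip(sh.exponents, sh.coefs_normalized):
                pa = PrimitiveCart(ai, [0, 0, 0], (0, 0, 0), ci)
                pb = PrimitiveCart(aj, [0, 0, 1.4], (0, 0, 0), cj)
                val += overlap_oracle(pa, pb)
        assert S[0, 1] == pytest.approx(val, abs=1e-8)

    def test_widely_separated_centers(self):
        geom = QMGeometry(["He", "He"], [[0, 0, 0], [0, 0, 50.0]])
        shells = [GaussianShell(0, 0, [0.8], [1.0]), GaussianShell(1, 0, [0.8], [1.0])]
        S = bi.overlap_matrix(BasisSet(shells, geom))
        assert abs(S[0, 1]) < 1e-12

    def test_positive_definite(self, h2o_basis):
        S = bi.overlap_matrix(h2o_basis)
        assert np.linalg.eigvalsh(S).min() > 0


class TestKinetic:
    def test_s_primitive_diagonal_closed_form(self):
        alpha = 1.3
        geom = QMGeometry(["He"], [[0.0, 0.0, 0.0]])
        T = bi.kinetic_matrix(BasisSet([GaussianShell(0, 0, [alpha], [1.0])], geom))
        assert T[0, 0] == pytest.approx(1.5 * alpha, rel=1e-12)

    def test_p_diagonal_exceeds_s_at_equal_exponent(self):
        alpha = 0.9
        geom = QMGeometry(["He"], [[0.0, 0.0, 0.0]])
        basis = BasisSet(
            [GaussianShell(0, 0, [alpha], [1.0]), GaussianShell(0, 1, [alpha], [1.0])],
            geom,
        )
        T = bi.kinetic_matrix(basis)
        assert T[1, 1] == pytest.approx(2.5 * alpha, rel=1e-12)
        assert T[1, 1] > T[0, 0]

    def test_h2_kinetic_vs_quadrature(self, h2_basis):
        T = bi.kinetic_matrix(h2_basis)
        sh = h2_basis.shells[0]
        val = 0.0
        for ai, ci in zip(sh.exponents, sh.coefs_normalized):
            for aj, cj in zip(sh.exponents, sh.coefs_normalized):
                pa = PrimitiveCart(ai, [0, 0, 0], (0, 0, 0), ci)
                pb = PrimitiveCart(aj, [0, 0, 1.4], (0, 0, 0), cj)
                val += kinetic_oracle(pa, pb)
        assert T[0, 1] == pytest.approx(val, abs=1e-8)


class TestChargeAttraction:
    def test_distant_unit_charge_reduces_to_monopole(self, h2_basis):
        # at r = 1e6 bohr the matrix is the trivial monopole shift -S/r
        # (which itself decays only as 1/r); anything beyond it vanishes
        r = 1e6
        V = bi.charge_attraction_matrix(h2_basis, [(1.0, [0.0, 0.0, r])])
        S = bi.overlap_matrix(h2_basis)
        assert np.abs(V + S / r).max() < 1e-9

    def test_h2_nuclear_attraction_vs_quadrature(self, h2_basis):
        V = bi.nuclear_attraction_matrix(h2_basis)
        sh = h2_basis.shells[0]
        centers = [np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.4])]
        val = 0.0
        for ai, ci in zip(sh.exponents, sh.coefs_normalized):
            for aj, cj in zip(sh.exponents, sh.coefs_normalized):
                pa = PrimitiveCart(ai, centers[0], (0, 0, 0), ci)
                pb = PrimitiveCart(aj, centers[1], (0, 0, 0), cj)
                for C in centers:
                    val += attraction_oracle(pa, pb, C)
        assert V[0, 1] == pytest.approx(val, abs=1e-7)

    def test_linearity_in_charge(self, h2_basis):
        pos = [0.3, -0.4, 0.9]
        V1 = bi.charge_attraction_matrix(h2_basis, [(1.0, pos)])
        V2 = bi.charge_attraction_matrix(h2_basis, [(2.0, pos)])
        np.testing.assert_allclose(V2, 2.0 * V1, atol=1e-13)

    def test_sign_attractive_for_positive_charge(self, h2_basis):
        V = bi.charge_attraction_matrix(h2_basis, [(1.0, [0.0, 0.0, 0.7])])
        assert V[0, 0] < 0  # lowers electron energy

    def test_charge_on_basis_center_is_finite(self, h2_basis):
        V = bi.charge_attraction_matrix(h2_basis, [(1.0, [0.0, 0.0, 0.0])])
        assert np.all(np.isfinite(V))

    def test_empty_charge_list_rejected(self, h2_basis):
        with pytest.raises(ValueError):
            bi.charge_attraction_matrix(h2_basis, [])


class TestERI:
    def test_ssss_closed_form_and_montecarlo(self):
        alpha = 0.8
        geom = QMGeometry(["He"], [[0.0, 0.0, 0.0]])
        basis = BasisSet([GaussianShell(0, 0, [alpha], [1.0])], geom)
        eri = bi.eri_tensor(basis)
        ref = eri_ssss_closed_form(alpha)
        assert eri.values[0, 0, 0, 0] == pytest.approx(ref, rel=1e-12)
        mc, mc_err = eri_ssss_montecarlo(alpha, nsamples=500_000)
        assert eri.values[0, 0, 0, 0] == pytest.approx(mc, abs=5 * mc_err)

    def test_screening_threshold_consistency(self, h2o_basis):
        e0 = bi.eri_tensor(h2o_basis, screening_threshold=0.0)
        e1 = bi.eri_tensor(h2o_basis, screening_threshold=1e-12)
        assert np.abs(e0.values - e1.values).max() < 1e-10

    def test_negative_threshold_rejected(self, h2_basis):
        with pytest.raises(ValueError):
            bi.eri_tensor(h2_basis, screening_threshold=-1.0)

    def test_eightfold_symmetry_bitwise(self, h2o_basis):
        v = bi.eri_tensor(h2o_basis).values
        assert np.array_equal(v, v.transpose(1, 0, 2, 3))
        assert np.array_equal(v, v.transpose(0, 1, 3, 2))
        assert np.array_equal(v, v.transpose(2, 3, 0, 1))

    def test_diagonal_nonnegative(self, h2o_basis):
        v = bi.eri_tensor(h2o_basis).values
        n = v.shape[0]
        diag = np.array([v[i, i, i, i] for i in range(n)])
        assert np.all(diag >= 0)


class TestDipole:
    def test_translation_identity(self, h2o_basis):
        d = np.array([0.3, -0.7, 1.1])
        S = bi.overlap_matrix(h2o_basis)
        M0 = bi.dipole_matrices(h2o_basis, (0.0, 0.0, 0.0)).as_array()
        M1 = bi.dipole_matrices(h2o_basis, d).as_array()
        for ax in range(3):
            np.testing.assert_allclose(M1[ax], M0[ax] - d[ax] * S, atol=1e-12)

    def test_homonuclear_diatomic_electronic_dipole_zero(self, h2_geom, h2_basis):
        state = scf_solve(h2_geom, h2_basis, "lda", grid="coarse")
        M = bi.dipole_matrices(h2_basis, (0.0, 0.0, 0.7)).as_array()
        mu_el = -np.einsum("aij,ji->a", M, state.density_matrix)
        assert abs(mu_el[2]) < 1e-8

    def test_h2o_scf_dipole_vs_reference(self, h2o_geom, h2o_basis):
        # reference: independent implementation (PySCF 2.12, dense grid,
        # identical vendored basis data), total z dipole in a.u.
        REF_Z = -0.6521369753260434
        state = scf_solve(h2o_geom, h2o_basis, "pbe", grid="fine")
        M = bi.dipole_matrices(h2o_basis, (0.0, 0.0, 0.0)).as_array()
        mu_el = -np.einsum("aij,ji->a", M, state.density_matrix)
        mu_nuc = np.einsum(
            "i,ix->x", h2o_geom.atomic_numbers.astype(float), h2o_geom.coordinates
        )
        mu = mu_el + mu_nuc
        assert mu[2] == pytest.approx(REF_Z, abs=1e-4)
        np.testing.assert_allclose(mu[:2], 0.0, atol=1e-6)

    def test_single_quadrature_check(self):
        pa = PrimitiveCart(0.9, [0.1, 0.0, 0.0], (1, 0, 0))
        pb = PrimitiveCart(0.4, [0.0, 0.2, 0.5], (0, 0, 1))
        geom = QMGeometry(["He", "He"], [[0.1, 0.0, 0.0], [0.0, 0.2, 0.5]])
        basis = BasisSet(
            [GaussianShell(0, 1, [0.9], [1.0]), GaussianShell(1, 1, [0.4], [1.0])],
            geom,
        )
        origin = np.array([0.0, 0.1, -0.3])
        M = bi.dipole_matrices(basis, origin).as_array()
        na = basis.shells[0].angular_norms[0] * (2 * 0.9 / np.pi) ** 0.75 * np.sqrt(4 * 0.9)
        nb = basis.shells[1].angular_norms[0] * (2 * 0.4 / np.pi) ** 0.75 * np.sqrt(4 * 0.4)
        ref = dipole_oracle(pa, pb, 1, origin) * na * nb
        assert M[1][0, 5] == pytest.approx(ref, abs=1e-9)


class TestPropertyRandomSystems:
    """Analytic integrals vs quadrature on random two-center systems up to d."""

    @pytest.mark.parametrize("case", range(6))
    def test_one_electron_vs_quadrature(self, case):
        rng = np.random.default_rng(1000 + case)
        la, lb = rng.integers(0, 3, size=2)
        a = float(10 ** rng.uniform(-0.7, 0.7))
        b = float(10 ** rng.uniform(-0.7, 0.7))
        A = rng.uniform(-1.0, 1.0, 3)
        B = rng.uniform(-1.0, 1.0, 3)
        geom = QMGeometry(["He", "He"], [A, B])
        basis = BasisSet(
            [GaussianShell(0, int(la), [a], [1.0]), GaussianShell(1, int(lb), [b], [1.0])],
            geom,
        )
        S = bi.overlap_matrix(basis)
        T = bi.kinetic_matrix(basis)
        C = rng.uniform(-1.5, 1.5, 3)
        V = bi.charge_attraction_matrix(basis, [(1.0, C)])
        sha, shb = basis.shells
        norm_a = [
            sha.angular_norms[i]
            * _prim_norm(a, la)
            for i in range(sha.ncart)
        ]
        norm_b = [
            shb.angular_norms[i] * _prim_norm(b, lb) for i in range(shb.ncart)
        ]
        for ia, pa_pow in enumerate(cart_components(int(la))):
            for jb, pb_pow in enumerate(cart_components(int(lb))):
                pa = PrimitiveCart(a, A, pa_pow, norm_a[ia])
                pb = PrimitiveCart(b, B, pb_pow, norm_b[jb])
                i = ia
                j = sha.ncart + jb
                assert S[i, j] == pytest.approx(overlap_oracle(pa, pb), abs=1e-7)
                assert T[i, j] == pytest.approx(kinetic_oracle(pa, pb), abs=1e-7)
                assert V[i, j] == pytest.approx(
                    attraction_oracle(pa, pb, C), abs=1e-7
                )


def _prim_norm(alpha, l):
    from qmmkit.basis_integrals.shells import primitive_norm

    return primitive_norm(alpha, int(l))


class TestBoys:
    def test_small_t_series_limit(self):
        from qmmkit.basis_integrals import boys

        F = boys(3, 0.0)
        np.testing.assert_allclose(F, [1.0, 1 / 3, 1 / 5, 1 / 7], atol=1e-14)

    def test_against_scipy_gammainc(self):
        from qmmkit.basis_integrals import boys
        from scipy.special import gammainc, gamma

        for T in (0.05, 0.7, 3.0, 12.0, 34.0, 40.0, 200.0):
            for m in (0, 1, 4):
                ref = (
                    0.5 * gamma(m + 0.5) * gammainc(m + 0.5, T) / T ** (m + 0.5)
                )
                assert boys(m, T)[m] == pytest.approx(ref, rel=1e-13, abs=1e-14)
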