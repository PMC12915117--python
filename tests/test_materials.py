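"""Constitutive-model tests: Ogden energy, stresses, tangents, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfm3d import materials as M


def stretches_of(F):
    return np.sqrt(np.linalg.eigvalsh(F.T @ F))


def energy_of_F(mat, F):
    return M.strain_energy(mat, stretches_of(F), J=float(np.linalg.det(F)))


class TestStrainEnergy:
    def test_reference_state_is_stress_free(self, table2):
        assert M.strain_energy(table2, (1, 1, 1), J=1.0) == 0.0

    def test_energy_positive_off_reference(self, table2):
        W = M.strain_energy(table2, (1.01, 0.995, 0.995), J=1.01 * 0.995**2)
        assert W > 0

    def test_small_shear_quadratic_limit(self, table2):
        # W ~ G0 gamma^2 / 2 for simple shear gamma -> 0
        gamma = 1e-3
        F = np.eye(3)
        F[0, 1] = gamma
        W = energy_of_F(table2, F)
        W_ref = 0.5 * table2.shear_modulus * gamma**2
        assert W == pytest.approx(W_ref, rel=0.01)

    def test_invalid_stretch_rejected(self, table2):
        with pytest.raises(M.InvalidDeformationError):
            M.strain_energy(table2, (1.0, -0.5, 1.0))
        with pytest.raises(M.InvalidDeformationError):
            M.strain_energy(table2, (1.0, 1.0, 1.0), J=-1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_energy_nonnegative_on_random_deformations(self, table2, seed):
        rng = np.random.default_rng(seed)
        F = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
        if np.linalg.det(F) <= 0.05:
            return
        assert energy_of_F(table2, F) >= -1e-14

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_frame_indifference(self, table2, seed):
        rng = np.random.default_rng(seed)
        F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        if np.linalg.det(F) <= 0.05:
            return
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        W1, W2 = energy_of_F(table2, F), energy_of_F(table2, Q @ F)
        assert W2 == pytest.approx(W1, rel=1e-10, abs=1e-16)


class TestUniaxial:
    def test_stress_free_reference(self, table2):
        assert M.uniaxial_nominal_stress(table2, 1.0) == 0.0

    def test_initial_slope_is_three_G0(self, table2):
        h = 1e-6
        slope = (M.uniaxial_nominal_stress(table2, 1 + h)
                 - M.uniaxial_nominal_stress(table2, 1 - h)) / (2 * h)
        assert slope == pytest.approx(3 * table2.shear_modulus, rel=1e-6)
        assert slope == pytest.approx(1.411, rel=1e-3)  # 3 x 0.4705 MPa

    def test_matches_energy_differentiation(self, table2):
        # P(lambda) = dW/dlambda along the incompressible uniaxial path
        lam, h = 1.25, 1e-6

        def W(la):
            return M.strain_energy(table2, (la, la**-0.5, la**-0.5), J=1.0)

        P_fd = (W(lam + h) - W(lam - h)) / (2 * h)
        assert M.uniaxial_nominal_stress(table2, lam) == pytest.approx(P_fd, rel=1e-3)

    def test_invalid_stretch_rejected(self, table2):
        with pytest.raises(M.InvalidDeformationError):
            M.uniaxial_nominal_stress(table2, -1.0)


class TestDerivedModuli:
    def test_table_constants_give_nu_045(self, table2):
        assert M.derived_poisson(table2) == pytest.approx(0.45, abs=0.005)

    def test_incompressible_limit(self):
        mat = M.OgdenMaterial(mu=(0.5,), alpha=(2.0,), D=1e-9)
        assert M.derived_poisson(mat) == pytest.approx(0.5, abs=1e-6)

    def test_equal_shear_and_bulk(self):
        # G0 = K implies nu = 1/8 by direct substitution
        G0 = 0.7
        mat = M.OgdenMaterial(mu=(G0,), alpha=(2.0,), D=2.0 / G0)
        assert M.derived_poisson(mat) == pytest.approx(1.0 / 8.0, rel=1e-12)

    @pytest.mark.parametrize("mat,E_expected", [
        (M.UPPER_PDMS, 1.43),
        (M.AVERAGE_PDMS, 1.38),
        (M.LOWER_PDMS, 1.25),
    ])
    def test_youngs_modulus_bounds(self, mat, E_expected):
        assert round(mat.youngs_modulus, 2) == E_expected

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            M.OgdenMaterial(mu=(0.5,), alpha=(2.0, 4.0), D=0.4)
        with pytest.raises(ValueError):
            M.OgdenMaterial(mu=(0.5,), alpha=(2.0,), D=-0.4)
        with pytest.raises(ValueError):
            M.OgdenMaterial(mu=(-0.5,), alpha=(2.0,), D=0.4)


class TestStressAndTangent:
    def test_reference_stress_free(self, table2):
        sig, _ = M.cauchy_stress_and_tangent(table2, np.eye(3))
        assert np.allclose(sig, 0, atol=1e-14)

    def test_small_strain_matches_linear(self, table2):
        eps = 1e-4
        F = np.diag([1 + eps, 1.0, 1.0])
        lin = M.linear_equivalent(table2)
        # uniaxial strain (confined): same F for both models
        sig_o, _ = M.cauchy_stress_and_tangent(table2, F)
        sig_l, _ = M.cauchy_stress_and_tangent(lin, F)
        assert sig_o[2, 2] == pytest.approx(sig_l[2, 2], rel=0.01)
        assert sig_o[0, 0] == pytest.approx(sig_l[0, 0], rel=0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tangent_matches_finite_differences(self, table2, seed):
        rng = np.random.default_rng(seed)
        F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
        assert np.linalg.det(F) > 0.1
        _, A = M.cauchy_stress_and_tangent(table2, F)

        def P_of(F):
            C = F.T @ F
            S, _ = M.ogden_pk2(table2, C, want_tangent=False)
            return F @ S

        h = 1e-7
        A_fd = np.zeros((3, 3, 3, 3))
        for k in range(3):
            for L in range(3):
                dF = np.zeros((3, 3))
                dF[k, L] = h
                A_fd[:, :, k, L] = (P_of(F + dF) - P_of(F - dF)) / (2 * h)
        assert np.max(np.abs(A_fd - A)) / np.max(np.abs(A)) < 1e-4

    def test_repeated_stretch_tangent_finite(self, table2):
        # equibiaxial state has a doubly repeated stretch; the perturbation
        # rule must keep the spectral tangent finite and close to FD
        F = np.diag([1.1, 1.1, 1.0 / 1.21])
        _, A = M.cauchy_stress_and_tangent(table2, F)
        assert np.all(np.isfinite(A))

    def test_inverted_deformation_rejected(self, table2):
        with pytest.raises(M.InvalidDeformationError):
            M.cauchy_stress_and_tangent(table2, -np.eye(3))

    def test_small_strain_consistency_random_directions(self, table2):
        # Ogden and Hookean stresses agree within 1% for strains <= 1e-3
        lin = M.linear_equivalent(table2)
        rng = np.random.default_rng(42)
        for _ in range(10):
            H = 1e-3 * rng.standard_normal((3, 3))
            F = np.eye(3) + H
            sig_o, _ = M.cauchy_stress_and_tangent(table2, F)
            sig_l, _ = M.cauchy_stress_and_tangent(lin, F)
            scale = np.abs(sig_l).max()
            assert np.abs(sig_o - sig_l).max() < 0.01 * scale


class TestFitting:
    def test_recovers_generating_constants(self, table2):
        lam = np.linspace(1.0, 1.3, 21)
        data = M.UniaxialDataset(strain=lam - 1.0,
                                 stress=M.uniaxial_nominal_stress(table2, lam))
        mat, diag = M.fit_ogden(data, order=2, nu_target=0.45)
        assert mat.shear_modulus == pytest.approx(table2.shear_modulus, rel=0.02)
        assert diag.r_squared > 0.999

    def test_neo_hookean_nested_in_two_terms(self):
        nh = M.OgdenMaterial(mu=(0.4,), alpha=(2.0,), D=0.5)
        lam = np.linspace(1.0, 1.4, 25)
        data = M.UniaxialDataset(strain=lam - 1.0,
                                 stress=M.uniaxial_nominal_stress(nh, lam))
        _, diag = M.fit_ogden(data, order=2)
        assert diag.r_squared > 0.999

    def test_fit_is_deterministic_under_seed(self, table2):
        lam = np.linspace(1.0, 1.3, 15)
        rng = np.random.default_rng(7)
        noisy = M.uniaxial_nominal_stress(table2, lam) * (1 + 0.01 * rng.standard_normal(lam.size))
        noisy = np.maximum.accumulate(np.abs(noisy))
        data = M.UniaxialDataset(strain=lam - 1.0, stress=noisy)
        m1, _ = M.fit_ogden(data, seed=123)
        m2, _ = M.fit_ogden(data, seed=123)
        assert m1.mu == m2.mu and m1.alpha == m2.alpha

    def test_bad_order_rejected(self, table2):
        lam = np.linspace(1.0, 1.3, 10)
        data = M.UniaxialDataset(strain=lam - 1.0,
                                 stress=M.uniaxial_nominal_stress(table2, lam))
        with pytest.raises(ValueError):
            M.fit_ogden(data, order=5)

    def test_dataset_validation(self):
        with pytest.raises(ValueError):
            M.UniaxialDataset(strain=[0, 0.1], stress=[0, 0.1])  # too short
        with pytest.raises(ValueError):
            M.UniaxialDataset(strain=[0, 0.2, 0.1, 0.3], stress=[0, 1, 2, 3])

    def test_uniaxial_roundtrip(self, table2, tmp_path):
        lam = np.linspace(1.0, 1.25, 12)
        data = M.UniaxialDataset(strain=lam - 1.0,
                                 stress=M.uniaxial_nominal_stress(table2, lam))
        p = tmp_path / "uniax.txt"
        M.write_uniaxial(data, p)
        back = M.read_uniaxial(p)
        np.testing.assert_allclose(back.strain, data.strain, rtol=1e-9)
        np.testing.assert_allclose(back.stress, data.stress, rtol=1e-9)
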