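"""Hyperelastic constitutive model: closed forms, consistency, hardening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nlswei.materials import (MaterialParams, StrainState, cauchy_stress,
                              load_tissue_library, strain_energy,
                              tangent_shear_modulus, uniaxial_response)
from .conftest import random_plane_strain_F


def numeric_cauchy(params, F, h=1e-6):
    """Independent oracle: sigma = (dU/dF) F^T / J by central differences."""
    P = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P[i, j] = (strain_energy(params, StrainState.from_deformation_gradient(Fp))
                       - strain_energy(params, StrainState.from_deformation_gradient(Fm))) / (2 * h)
    return P @ F.T / np.linalg.det(F)


class TestClosedForms:
    def test_initial_shear_moduli_from_table(self, tumor, benign):
        # mu0 = 2(C10 + C01) under the MPa reading of the parameter table
        assert tumor.mu0 == pytest.approx(5.64, rel=1e-12)
        assert benign.mu0 == pytest.approx(1.50, rel=1e-12)

    def test_energy_zero_at_identity(self, tumor, benign):
        s = StrainState.identity()
        assert strain_energy(tumor, s) == 0.0
        assert strain_energy(benign, s) == 0.0
        assert np.allclose(cauchy_stress(tumor, s), 0.0)

    def test_energy_polynomial_expansion(self, benign):
        # I1 = I2 = 3.01, Jel = 1: direct term-by-term evaluation
        s = StrainState(np.eye(2), 3.01, 3.01, 1.0)
        expected = ((benign.c10 + benign.c01) * 0.01
                    + benign.c11 * 1e-4 + (benign.c20 + benign.c02) * 1e-4)
        assert strain_energy(benign, s) == pytest.approx(expected, rel=1e-12)

    def test_energy_uniaxial_stretch_tumor(self, tumor):
        # plane-strain incompressible stretch 0.9; oracle: direct polynomial
        lam = 0.9
        F = np.diag([1 / lam, lam])
        s = StrainState.from_deformation_gradient(F)
        i1 = lam**2 + lam**-2 + 1.0
        e = i1 - 3.0
        expected = ((tumor.c10 + tumor.c01) * e + tumor.c11 * e * e
                    + (tumor.c20 + tumor.c02) * e * e)
        assert strain_energy(tumor, s) == pytest.approx(expected, rel=1e-10)

    def test_small_shear_slope_is_mu0(self, tumor):
        gamma = 1e-6
        F = np.array([[1.0, 0.0], [gamma, 1.0]])
        s = StrainState.from_deformation_gradient(F)
        sig = cauchy_stress(tumor, s)
        assert sig[0, 1] / gamma == pytest.approx(tumor.mu0, rel=1e-3)

    def test_tangent_at_identity(self, tumor, benign):
        s = StrainState.identity()
        assert tangent_shear_modulus(tumor, s) == pytest.approx(5.64, rel=1e-6)
        assert tangent_shear_modulus(benign, s) == pytest.approx(1.50, rel=1e-6)
        assert tangent_shear_modulus(tumor, s, mode="energy") == pytest.approx(
            5.64, rel=1e-3)


class TestConsistency:
    @given(seed=st.integers(0, 200))
    @settings(max_examples=30, deadline=None)
    def test_stress_is_energy_gradient(self, seed):
        """Analytic Cauchy stress equals the numerical energy gradient."""
        rng = np.random.default_rng(seed)
        params = load_tissue_library()["tumor" if seed % 2 else "benign"]
        F = random_plane_strain_F(rng)
        s = StrainState.from_deformation_gradient(F)
        sig = cauchy_stress(params, s)[:2, :2]
        ref = numeric_cauchy(params, F)
        assert np.abs(sig - ref).max() <= 1e-5 * max(1.0, np.abs(ref).max())

    @given(seed=st.integers(0, 200))
    @settings(max_examples=20, deadline=None)
    def test_objectivity_under_rotation(self, seed, tumor):
        """Energy is invariant under superposed in-plane rotation."""
        rng = np.random.default_rng(seed)
        F = random_plane_strain_F(rng)
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        u1 = strain_energy(tumor, StrainState.from_deformation_gradient(F))
        u2 = strain_energy(tumor, StrainState.from_deformation_gradient(R @ F))
        assert u2 == pytest.approx(u1, abs=1e-10 * max(1.0, abs(u1)))

    def test_tangent_matches_independent_stress_oracle(self, tumor):
        """Tangent modulus at 20% compression equals differencing the
        energy-gradient stress under superposed shear, and hardens."""
        lam = 0.8
        F = np.diag([1 / lam, lam])
        mu_t = tangent_shear_modulus(
            tumor, StrainState.from_deformation_gradient(F))
        g = 1e-5
        Sp = np.array([[1, 0], [g, 1.0]]) @ F
        Sm = np.array([[1, 0], [-g, 1.0]]) @ F
        oracle = (numeric_cauchy(tumor, Sp)[0, 1]
                  - numeric_cauchy(tumor, Sm)[0, 1]) / (2 * g)
        assert mu_t == pytest.approx(oracle, rel=1e-3)
        assert mu_t > tumor.mu0


class TestHardeningAndValidation:
    @pytest.mark.parametrize("name", ["tumor", "benign"])
    def test_strain_hardening_monotone(self, name):
        params = load_tissue_library()[name]
        r = uniaxial_response(params, np.linspace(0, 0.30, 16))
        assert np.all(np.diff(r["tangent_modulus"]) >= -1e-9)
        assert np.all(np.diff(r["nominal_stress"]) > 0)

    def test_hardening_is_convex_and_tumor_dominates(self, tumor, benign):
        rt = uniaxial_response(tumor, [0.0, 0.10, 0.30])
        rb = uniaxial_response(benign, [0.0, 0.10, 0.30])
        # ratio to mu0 grows faster between 10% and 30% than 0 and 10%
        for r in (rt, rb):
            m = r["tangent_modulus"]
            assert m[2] / m[0] > m[1] / m[0]
        ratio = rt["tangent_modulus"] / rb["tangent_modulus"]
        assert ratio[2] > ratio[1] > ratio[0]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MaterialParams.from_coefficients(c10=-1.0, c01=0.0, c11=0, c20=0, c02=0)
        with pytest.raises(ValueError):
            MaterialParams.from_coefficients(c10=1.0, c01=1.0, c11=0, c20=0,
                                             c02=0, poisson_ratio=0.6)

    def test_degenerate_state_rejected(self, tumor):
        with pytest.raises(ValueError):
            StrainState(np.eye(2), 3.0, 3.0, -1.0)

    def test_scaled_coefficients_scale_moduli(self, tumor):
        s4 = tumor.scaled(4.0)
        assert s4.mu0 == pytest.approx(4 * tumor.mu0)
        lam = 0.85
        F = np.diag([1 / lam, lam])
        st_ = StrainState.from_deformation_gradient(F)
        assert tangent_shear_modulus(s4, st_) == pytest.approx(
            4 * tangent_shear_modulus(tumor, st_), rel=1e-6)
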