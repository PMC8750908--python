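"""Unit and property tests for the closed-form magneto-diffusion calculators."""

import math

import pytest
from hypothesis import given, strategies as st

from magnetodiffusion import physics
from magnetodiffusion.physics import (
    CONSTANTS,
    DiffusionSuppressedError,
    FieldCondition,
    InvalidParameterError,
    NoCriticalFieldError,
    PhysicalConstants,
    UndefinedOnsetError,
)

# Registry susceptibilities used repeatedly below (m^3/mol)
CHI_DEOXYHB = +60.4e-8
CHI_OXYHB = -4.754e-7
CHI_FECL3 = +2.573e-8

MU0 = 4e-7 * math.pi


def direct_beta(chi, B, T):
    """Independent arithmetic for chi B^2 / (2 mu0 R T)."""
    return chi * B * B / (2.0 * MU0 * 8.31 * T)


class TestConstants:
    def test_defaults_are_mutually_consistent(self):
        c = PhysicalConstants()
        assert c.R_gas / (c.N_A * c.k_B) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("field", ["mu0", "R_gas", "k_B", "N_A"])
    def test_nonpositive_constant_rejected(self, field):
        with pytest.raises(InvalidParameterError):
            PhysicalConstants(**{field: 0.0})

    def test_inconsistent_molar_molecular_routes_rejected(self):
        with pytest.raises(InvalidParameterError):
            PhysicalConstants(k_B=1.5e-23)

    def test_immutable(self):
        with pytest.raises(AttributeError):
            CONSTANTS.mu0 = 1.0


class TestFieldCondition:
    def test_negative_field_rejected(self):
        with pytest.raises(InvalidParameterError):
            FieldCondition(B=-1.0)

    @pytest.mark.parametrize("T", [0.0, -10.0])
    def test_nonpositive_temperature_rejected(self, T):
        with pytest.raises(InvalidParameterError):
            FieldCondition(B=1.0, T=T)


class TestBeta:
    def test_zero_field_gives_zero(self):
        assert physics.beta(CHI_DEOXYHB, FieldCondition(B=0.0)).beta == 0.0

    def test_deoxyhemoglobin_at_tabulated_onset_field(self):
        # 22.8 T is the 3-s.f. onset field, so beta returns ~0.05
        res = physics.beta(CHI_DEOXYHB, FieldCondition(B=22.8, T=300.0))
        assert res.beta == pytest.approx(0.05, rel=5e-3)

    def test_diamagnetic_value_matches_direct_arithmetic(self):
        res = physics.beta(CHI_OXYHB, FieldCondition(B=10.0, T=300.0))
        assert res.beta == pytest.approx(direct_beta(CHI_OXYHB, 10.0, 300.0), rel=1e-12)
        assert res.beta == pytest.approx(-7.587e-3, rel=1e-3)

    @pytest.mark.parametrize(
        "beta_value,regime",
        [
            (1.5, "supercritical"),
            (1.0, "near-critical"),
            (0.97, "near-critical"),
            (0.5, "paramagnetic-slowed"),
            (0.0501, "paramagnetic-slowed"),
            (0.01, "negligible"),
            (0.0, "negligible"),
            (-0.01, "negligible"),
            (-0.0501, "diamagnetic-accelerated"),
            (-0.5, "diamagnetic-accelerated"),
        ],
    )
    def test_regime_classification(self, beta_value, regime):
        # choose chi so that beta comes out at the requested value at B=10, T=300
        chi = beta_value * 2.0 * MU0 * 8.31 * 300.0 / 100.0
        if chi == 0.0:
            res = physics.beta(1e-8, FieldCondition(B=0.0))
        else:
            res = physics.beta(chi, FieldCondition(B=10.0, T=300.0))
        assert res.regime == regime

    @given(
        chi=st.floats(1e-9, 1e-6),
        B=st.floats(0.1, 100.0),
        T=st.floats(270.0, 320.0),
    )
    def test_quadratic_in_field(self, chi, B, T):
        b1 = physics.beta(chi, FieldCondition(B=B, T=T)).beta
        b2 = physics.beta(chi, FieldCondition(B=2 * B, T=T)).beta
        assert b2 == pytest.approx(4.0 * b1, rel=1e-14)

    @given(
        chi=st.floats(1e-9, 1e-6),
        B=st.floats(0.1, 100.0),
        T1=st.floats(200.0, 400.0),
        T2=st.floats(200.0, 400.0),
    )
    def test_inverse_temperature_scaling(self, chi, B, T1, T2):
        b1 = physics.beta(chi, FieldCondition(B=B, T=T1)).beta
        b2 = physics.beta(chi, FieldCondition(B=B, T=T2)).beta
        assert b1 * T1 == pytest.approx(b2 * T2, rel=1e-12)

    @given(chi=st.floats(-1e-6, 1e-6), B=st.floats(0.1, 100.0))
    def test_sign_follows_susceptibility(self, chi, B):
        b = physics.beta(chi, FieldCondition(B=B)).beta
        assert math.copysign(1.0, b) == math.copysign(1.0, chi) or chi == 0


class TestEffectiveDiffusion:
    def test_zero_field_identity(self):
        assert physics.effective_diffusion(1e-9, CHI_DEOXYHB, FieldCondition(B=0.0)) == 1e-9

    def test_half_beta_halves_diffusivity(self):
        # pick B so beta = 0.5 exactly for this chi
        chi = 1e-7
        B = math.sqrt(0.5 * 2 * MU0 * 8.31 * 300.0 / chi)
        d = physics.effective_diffusion(1e-9, chi, FieldCondition(B=B, T=300.0))
        assert d == pytest.approx(0.5e-9, rel=1e-12)

    def test_diamagnetic_enhancement_matches_arithmetic(self):
        d = physics.effective_diffusion(1e-9, CHI_OXYHB, FieldCondition(B=10.0, T=300.0))
        assert d == pytest.approx(1e-9 * (1.0 - direct_beta(CHI_OXYHB, 10.0, 300.0)), rel=1e-12)
        assert d == pytest.approx(1.00759e-9, rel=1e-5)

    def test_nonpositive_diffusivity_rejected(self):
        with pytest.raises(InvalidParameterError):
            physics.effective_diffusion(0.0, CHI_DEOXYHB, FieldCondition(B=1.0))

    @given(B=st.floats(0.1, 99.0))
    def test_monotone_in_field(self, B):
        f_lo, f_hi = FieldCondition(B=B), FieldCondition(B=B + 1.0)
        assert physics.effective_diffusion(1e-9, 1e-7, f_hi) < physics.effective_diffusion(
            1e-9, 1e-7, f_lo
        )
        assert physics.effective_diffusion(1e-9, -1e-7, f_hi) > physics.effective_diffusion(
            1e-9, -1e-7, f_lo
        )


class TestOnsetAndCriticalField:
    def test_deoxyhemoglobin_onset_to_three_figures(self):
        assert physics.onset_field(CHI_DEOXYHB, 0.05, 300.0) == pytest.approx(22.8, abs=0.05)

    def test_ferric_chloride_onset_to_three_figures(self):
        assert physics.onset_field(CHI_FECL3, 0.05, 300.0) == pytest.approx(110.0, abs=0.5)

    @given(
        chi=st.floats(1e-9, 1e-6),
        beta0=st.floats(1e-3, 0.2),
        T=st.floats(270.0, 320.0),
    )
    def test_square_root_scaling(self, chi, beta0, T):
        assert physics.onset_field(chi, 4 * beta0, T) == pytest.approx(
            2 * physics.onset_field(chi, beta0, T), rel=1e-12
        )

    @given(
        chi=st.one_of(st.floats(1e-9, 1e-6), st.floats(-1e-6, -1e-9)),
        beta0=st.floats(1e-3, 0.9),
        T=st.floats(270.0, 320.0),
    )
    def test_round_trip_through_beta(self, chi, beta0, T):
        B0 = physics.onset_field(chi, beta0, T)
        b = physics.beta(chi, FieldCondition(B=B0, T=T)).beta
        assert abs(b) == pytest.approx(beta0, rel=1e-12)

    def test_zero_susceptibility_has_no_onset(self):
        with pytest.raises(UndefinedOnsetError):
            physics.onset_field(0.0, 0.05, 300.0)

    def test_critical_field_is_unit_beta_onset(self):
        assert physics.critical_field(CHI_DEOXYHB, 300.0) == pytest.approx(
            physics.onset_field(CHI_DEOXYHB, 1.0, 300.0), rel=1e-15
        )
        # 22.774 T / sqrt(0.05)
        assert physics.critical_field(CHI_DEOXYHB, 300.0) == pytest.approx(101.9, abs=0.2)

    def test_beta_at_critical_field_is_one(self):
        Bcr = physics.critical_field(CHI_DEOXYHB, 300.0)
        assert physics.beta(CHI_DEOXYHB, FieldCondition(B=Bcr, T=300.0)).beta == pytest.approx(
            1.0, rel=1e-12
        )

    def test_diamagnet_has_no_critical_field(self):
        with pytest.raises(NoCriticalFieldError):
            physics.critical_field(CHI_OXYHB, 300.0)


class TestForcesAndDrift:
    def test_uniform_concentration_gives_no_force(self):
        assert physics.force_density(CHI_DEOXYHB, 10.0, 0.0) == 0.0
        assert physics.force_per_molecule(CHI_DEOXYHB, 10.0, 5.5, 0.0) == 0.0

    def test_force_density_value_and_field_scaling(self):
        grad_n = 1.375e6
        f = physics.force_density(CHI_DEOXYHB, 100.0, grad_n)
        assert f == pytest.approx(CHI_DEOXYHB * 1e4 * grad_n / (2 * MU0), rel=1e-12)
        assert f == pytest.approx(3.304e9, rel=1e-3)
        assert physics.force_density(CHI_DEOXYHB, 200.0, grad_n) == pytest.approx(4 * f, rel=1e-12)

    def test_force_sign_tracks_susceptibility(self):
        assert physics.force_density(CHI_DEOXYHB, 10.0, 1.0) > 0
        assert physics.force_density(CHI_OXYHB, 10.0, 1.0) < 0

    def test_per_molecule_force_for_deoxyhemoglobin_layer(self):
        n, R_c = 5.5, 4e-6
        f1 = physics.force_per_molecule(CHI_DEOXYHB, 100.0, n, n / R_c)
        expected = physics.force_density(CHI_DEOXYHB, 100.0, n / R_c) / (n * CONSTANTS.N_A)
        assert f1 == pytest.approx(expected, rel=1e-12)
        assert f1 == pytest.approx(1.0e-15, rel=5e-2)

    def test_per_molecule_force_independent_of_concentration_for_fixed_relative_gradient(self):
        R_c = 4e-6
        f1 = physics.force_per_molecule(CHI_DEOXYHB, 100.0, 5.5, 5.5 / R_c)
        f2 = physics.force_per_molecule(CHI_DEOXYHB, 100.0, 11.0, 11.0 / R_c)
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_per_molecule_force_requires_positive_concentration(self):
        with pytest.raises(InvalidParameterError):
            physics.force_per_molecule(CHI_DEOXYHB, 10.0, 0.0, 1.0)

    def test_drift_velocity_nernst_einstein(self):
        u = physics.drift_velocity(1.6e-11, 300.0, 9.98e-16)
        gamma = 1.6e-11 / (CONSTANTS.k_B * 300.0)
        assert u == pytest.approx(gamma * 9.98e-16, rel=1e-12)
        assert u == pytest.approx(3.9e-6, rel=2e-2)
        assert physics.drift_velocity(1.6e-11, 300.0, 0.0) == 0.0
        assert physics.drift_velocity(1e-9, 300.0, 2e-15) == pytest.approx(
            2 * physics.drift_velocity(1e-9, 300.0, 1e-15), rel=1e-12
        )

    def test_drift_velocity_rejects_bad_parameters(self):
        with pytest.raises(InvalidParameterError):
            physics.drift_velocity(1e-9, 0.0, 1e-15)
        with pytest.raises(InvalidParameterError):
            physics.drift_velocity(0.0, 300.0, 1e-15)


class TestMagneticPressure:
    def test_zero_field_gives_zero(self):
        assert physics.magnetic_pressure(CHI_DEOXYHB, 4e-6, 0.0, 1.375e6) == 0.0

    def test_deoxygenated_cell_pressure(self):
        p = physics.magnetic_pressure(CHI_DEOXYHB, 4e-6, 100.0, 5.5 / 4e-6)
        assert p == pytest.approx(4406.0, rel=1e-3)  # full-precision value
        assert round(p, -3) == 4000.0  # one significant figure

    @given(
        chi=st.floats(-1e-6, 1e-6),
        R_c=st.floats(1e-6, 1e-5),
        B=st.floats(0.0, 100.0),
        grad_n=st.floats(0.0, 1e7),
    )
    def test_equals_force_density_times_third_of_radius(self, chi, R_c, B, grad_n):
        assert physics.magnetic_pressure(chi, R_c, B, grad_n) == pytest.approx(
            physics.force_density(chi, B, grad_n) * R_c / 3.0, rel=1e-14, abs=1e-300
        )

    def test_requires_positive_cell_radius(self):
        with pytest.raises(InvalidParameterError):
            physics.magnetic_pressure(CHI_DEOXYHB, 0.0, 10.0, 1.0)


class TestCharacteristicTime:
    def test_oxygen_time_in_rbc(self):
        assert physics.characteristic_time(3e-6, 1e-9, 0.0) == pytest.approx(9e-3, rel=1e-12)

    def test_hemoglobin_time_in_rbc(self):
        assert physics.characteristic_time(3e-6, 1.6e-11, 0.0) == pytest.approx(0.5625, rel=1e-12)

    def test_field_slowed_hemoglobin(self):
        b = direct_beta(CHI_DEOXYHB, 20.0, 300.0)
        tau = physics.characteristic_time(3e-6, 1.6e-11, b)
        assert b == pytest.approx(0.03856, rel=1e-3)
        assert tau == pytest.approx(0.585, rel=1e-3)

    @given(beta_value=st.floats(-2.0, 0.99))
    def test_relative_change_identity(self, beta_value):
        tau0 = physics.characteristic_time(3e-6, 1e-9, 0.0)
        tau = physics.characteristic_time(3e-6, 1e-9, beta_value)
        assert (tau - tau0) / tau0 == pytest.approx(
            beta_value / (1.0 - beta_value), rel=1e-12, abs=1e-15
        )

    def test_diamagnetic_shortens_time(self):
        assert physics.characteristic_time(3e-6, 1e-9, -0.5) < physics.characteristic_time(
            3e-6, 1e-9, 0.0
        )

    @pytest.mark.parametrize("beta_value", [1.0, 1.5])
    def test_suppressed_diffusion_raises(self, beta_value):
        with pytest.raises(DiffusionSuppressedError):
            physics.characteristic_time(3e-6, 1e-9, beta_value)


class TestGradientForceRatio:
    def test_uniform_field_gives_zero(self):
        assert physics.gradient_force_ratio(0.0, 4e-6) == 0.0

    def test_mri_scale_estimate_is_nano(self):
        assert physics.gradient_force_ratio(1e-3, 4e-6) == pytest.approx(8e-9, rel=1e-12)

    @given(a=st.floats(0.0, 1e-2), b=st.floats(0.0, 1e-4))
    def test_bilinear(self, a, b):
        assert physics.gradient_force_ratio(2 * a, b) == pytest.approx(
            2 * physics.gradient_force_ratio(a, b), rel=1e-12, abs=1e-300
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            physics.gradient_force_ratio(-1e-3, 4e-6)
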