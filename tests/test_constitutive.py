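"""Unit and property tests of the ISV material point and the water EOS."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from brainmech.constitutive import (
    DRY_BRAIN, WATER, IntegrationError, LockingError, MaterialConstants,
    MaterialState, StressStrainCurve, WaterEOSParams, back_stress,
    elastic_modulus, equivalent_stress_invariants, inverse_langevin,
    mandel_stress, plastic_shear_rate, simulate_uniaxial, update_isvs,
    water_axial_stress)

I3 = np.eye(3)


# ---------------------------------------------------------------------------
# elastic law
# ---------------------------------------------------------------------------


class TestMandelStress:
    def test_zero_strain_gives_zero_stress(self):
        assert np.allclose(mandel_stress(np.zeros((3, 3)), DRY_BRAIN), 0.0)

    def test_traceless_strain_collapses_to_shear_term(self):
        Ee = np.diag([-0.01, 0.005, 0.005])
        M = mandel_stress(Ee, DRY_BRAIN)
        assert np.allclose(M, np.diag([-0.016, 0.008, 0.008]))

    def test_volumetric_strain_direct_evaluation(self):
        # independent scalar computation: 2*mu*e + (K - 2mu/3)*3e
        e = 0.003
        expected = 2 * 0.80 * e + (399.73 - 2 * 0.80 / 3) * 3 * e
        M = mandel_stress(e * I3, DRY_BRAIN)
        assert np.allclose(M, expected * I3)
        assert math.isclose(expected, 3.5976, rel_tol=2e-4)

    @given(st.floats(-0.05, 0.05), st.floats(-0.05, 0.05),
           st.floats(-0.05, 0.05), st.floats(0.1, 5.0))
    def test_linearity_in_strain(self, a, b, c, scale):
        Ee = np.diag([a, b, c])
        M1 = mandel_stress(Ee, DRY_BRAIN)
        M2 = mandel_stress(scale * Ee, DRY_BRAIN)
        assert np.allclose(M2, scale * M1, atol=1e-12)

    def test_rejects_non_symmetric_input(self):
        bad = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            mandel_stress(bad, DRY_BRAIN)


class TestEquivalentStressInvariants:
    def test_pure_hydrostatic_has_no_deviator(self):
        tau, pi = equivalent_stress_invariants(2.5 * I3)
        assert tau == pytest.approx(0.0, abs=1e-14)
        assert pi == pytest.approx(-2.5)

    def test_deviatoric_norm_by_brute_force(self):
        M = np.diag([2.0, -1.0, -1.0])  # kPa, already traceless
        expected = 0.5 * math.sqrt(sum(v * v for v in (2.0, -1.0, -1.0)))
        tau, pi = equivalent_stress_invariants(M)
        assert tau == pytest.approx(expected)
        assert tau == pytest.approx(0.5 * math.sqrt(6.0))
        assert pi == pytest.approx(0.0)

    def test_identical_tensors_give_zero_shear(self):
        M = np.diag([3.0, 1.0, -0.5])
        tau, _ = equivalent_stress_invariants(M, alpha=M)
        assert tau == pytest.approx(0.0, abs=1e-14)

    def test_alternative_convention_factor(self):
        M = np.diag([2.0, -1.0, -1.0])
        tau_half, _ = equivalent_stress_invariants(M, factor=0.5)
        tau_sqrt, _ = equivalent_stress_invariants(M, factor=1 / math.sqrt(2))
        assert tau_sqrt == pytest.approx(tau_half * math.sqrt(2.0))


class TestPlasticShearRate:
    def test_macaulay_clamps_below_threshold(self):
        assert plastic_shear_rate(0.01, 0.02, 0.0, 0.0, DRY_BRAIN) == 0.0

    def test_pressure_insensitive_at_default_alpha_p(self):
        rates = [plastic_shear_rate(0.05, 0.0, 0.0, pi, DRY_BRAIN)
                 for pi in (-1.0, 0.0, 5.0)]
        assert rates[0] == rates[1] == rates[2] > 0

    def test_reference_rate_recovered_by_sinh_inversion(self):
        drive = DRY_BRAIN.yield_stress * math.asinh(1.0)
        rate = plastic_shear_rate(drive, 0.0, 0.0, 0.0, DRY_BRAIN)
        assert rate == pytest.approx(120_000.0, rel=1e-12)

    @given(st.floats(0.0, 0.5), st.floats(0.001, 0.5))
    def test_monotone_in_driving_stress_and_nonnegative(self, tau, dtau):
        lo = plastic_shear_rate(tau, 0.0, 0.0, 0.0, DRY_BRAIN)
        hi = plastic_shear_rate(tau + dtau, 0.0, 0.0, 0.0, DRY_BRAIN)
        assert 0.0 <= lo <= hi


# ---------------------------------------------------------------------------
# back stress
# ---------------------------------------------------------------------------


def _inverse_langevin_exact(x: float) -> float:
    """Numeric inversion of the Langevin function L(y) = coth(y) - 1/y."""
    langevin = lambda y: 1.0 / math.tanh(y) - 1.0 / y
    return brentq(lambda y: langevin(y) - x, 1e-9, 1e4, xtol=1e-12)


class TestBackStress:
    def test_undeformed_network_gives_zero(self):
        assert np.allclose(back_stress(I3, DRY_BRAIN), 0.0)

    def test_scales_with_rubbery_modulus(self):
        consts = DRY_BRAIN.replace(rubbery_modulus=0.0)
        beta = np.diag([1.3, 0.9, 0.87])
        assert np.allclose(back_stress(beta, consts), 0.0)

    def test_cohen_approximant_against_series_oracle(self):
        # at half the locking stretch the Pade form must track the exact
        # inverse Langevin within its documented few-percent band
        x = 0.5
        assert inverse_langevin(x) == pytest.approx(
            _inverse_langevin_exact(x), rel=0.05)

    def test_half_locking_stretch_back_stress_value(self):
        lam_l, mu_r = 2.00, 0.07
        lam_c = 0.5 * lam_l  # chain stretch 1.0 -> needs tr(beta) = 3
        beta = np.diag([1.4, 0.8, 0.8])  # tr = 3, lam_c = 1 = 0.5 * lam_L
        alpha = back_stress(beta, DRY_BRAIN)
        x = lam_c / lam_l
        pref = (mu_r / 3.0) * (lam_l / lam_c) * inverse_langevin(x)
        expected = pref * (beta - I3 * np.trace(beta) / 3.0)
        assert np.allclose(alpha, expected)
        exact_pref = (mu_r / 3.0) * (lam_l / lam_c) * _inverse_langevin_exact(x)
        assert np.allclose(alpha, exact_pref * (beta - I3), rtol=0.05)
        assert np.trace(alpha) == pytest.approx(0.0, abs=1e-15)

    def test_locking_raises(self):
        beta = np.diag([14.0, 1.0, 1.0])  # tr/3 > lam_L^2
        with pytest.raises(LockingError):
            back_stress(beta, DRY_BRAIN)


# ---------------------------------------------------------------------------
# ISV evolution
# ---------------------------------------------------------------------------


class TestUpdateISVs:
    def make_state(self):
        return MaterialState.initial(DRY_BRAIN)

    def test_no_flow_leaves_state_unchanged(self):
        state = self.make_state()
        Dp = np.diag([-1.0, 0.5, 0.5])
        new = update_isvs(state, 0.0, Dp, 1e-6, DRY_BRAIN)
        assert new.xi1 == state.xi1
        assert new.xistar == state.xistar
        assert np.allclose(new.beta, state.beta)
        assert new.plastic_stretch_axial == state.plastic_stretch_axial
        assert new.time == pytest.approx(state.time + 1e-6)

    def test_saturated_xi1_stays_fixed(self):
        state = self.make_state()
        state.xi1 = state.xistar
        Dp = np.diag([-1.0, 0.5, 0.5])
        new = update_isvs(state, 100.0, Dp, 1e-6, DRY_BRAIN)
        assert new.xi1 == pytest.approx(state.xi1, rel=1e-9)

    def test_h1_zero_freezes_xi2(self):
        state = self.make_state()
        Dp = np.diag([-1.0, 0.5, 0.5])
        for _ in range(50):
            state = update_isvs(state, 1000.0, Dp, 1e-5, DRY_BRAIN)
        assert state.xi2 == DRY_BRAIN.xi2_init

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError, match="dt"):
            update_isvs(self.make_state(), 1.0, np.zeros((3, 3)), 0.0,
                        DRY_BRAIN)

    def test_traceless_flow_preserves_plastic_volume(self):
        state = self.make_state()
        Dp = np.diag([-1.0, 0.5, 0.5]) * 50.0
        for _ in range(200):
            state = update_isvs(state, 10.0, Dp, 1e-5, DRY_BRAIN)
        assert state.det_fp == pytest.approx(1.0, abs=1e-12)

    def test_beta_update_matches_matrix_exponential(self):
        from scipy.linalg import expm

        state = self.make_state()
        Dp = np.diag([-2.0, 1.0, 1.0])
        dt = 1e-3
        new = update_isvs(state, 1.0, Dp, dt, DRY_BRAIN)
        E = expm(DRY_BRAIN.beta_hardening * Dp * dt)
        assert np.allclose(new.beta, E @ state.beta @ E.T, rtol=1e-12)


# ---------------------------------------------------------------------------
# uniaxial simulator
# ---------------------------------------------------------------------------


class TestSimulateUniaxial:
    def test_initial_slope_equals_closed_form_youngs_modulus(self, truth):
        curve = simulate_uniaxial(250.0, 0.001, consts=truth)
        slope = np.polyfit(curve.true_strain, curve.true_stress, 1)[0]
        expected = elastic_modulus(truth) * 1e3  # kPa
        assert slope == pytest.approx(expected, rel=1e-3)
        assert expected == pytest.approx(
            9 * 399.73 * 0.80 / (3 * 399.73 + 0.80) * 1e3, rel=1e-6)

    def test_elastic_consistency_below_threshold(self, truth):
        # a huge yield threshold keeps the response purely elastic; the
        # curve must match the linear-elastic line within 0.1%
        consts = truth.replace(c_kappa1=1e6)
        curve = simulate_uniaxial(0.1, 0.05, consts=consts)
        line = elastic_modulus(consts) * 1e3 * curve.true_strain
        mask = curve.true_strain > 0.005
        assert np.all(np.abs(curve.true_stress[mask] / line[mask] - 1)
                      < 1e-3)
        assert curve.meta["final_state"].gamma_p == 0.0

    def test_tiny_max_strain_gives_minimal_curve(self, truth):
        curve = simulate_uniaxial(250.0, 1e-6, consts=truth)
        assert len(curve) >= 1
        assert curve.true_strain[0] == 0.0
        assert curve.true_stress[0] == 0.0

    def test_rate_ordering_of_flow_stress(self, truth):
        rates = (0.00625, 0.1, 50.0, 250.0, 750.0)
        stresses = [simulate_uniaxial(r, 0.11, consts=truth).stress_at(0.10)
                    for r in rates]
        assert all(lo <= hi for lo, hi in zip(stresses, stresses[1:]))

    def test_time_step_convergence_at_high_rate(self, truth):
        coarse = simulate_uniaxial(250.0, 0.10, dt=1e-7, consts=truth)
        fine = simulate_uniaxial(250.0, 0.10, dt=5e-8, consts=truth)
        rel = abs(coarse.stress_at(0.10) / fine.stress_at(0.10) - 1)
        assert rel < 5e-3

    def test_plastic_incompressibility_over_long_run(self, truth):
        curve = simulate_uniaxial(250.0, 0.30, consts=truth,
                                  record_history=True)
        assert curve.meta["n_steps"] >= 10_000
        assert abs(curve.meta["det_fp"] - 1.0) < 1e-8
        assert np.all(np.abs(curve.meta["history"]["det_fp"] - 1.0) < 1e-8)

    def test_dissipation_sign_over_randomized_sweep(self, truth):
        rng = np.random.default_rng(2024)
        for _ in range(8):
            consts = truth.replace(
                shear_modulus=float(rng.uniform(0.2, 2.0)),
                yield_stress=float(rng.uniform(2.0, 20.0)),
                rubbery_modulus=float(rng.uniform(0.0, 0.2)),
                h0=float(rng.uniform(0.1, 1.0)))
            rate = float(rng.uniform(1.0, 500.0))
            curve = simulate_uniaxial(rate, 0.15, consts=consts,
                                      record_history=True)
            assert np.all(curve.meta["history"]["gamma_dot_p"] >= 0.0)
            assert np.all(np.diff(curve.meta["history"]["gamma_p"]) >= 0.0)

    def test_compression_positive_reporting(self, curve_250):
        assert np.all(curve_250.true_stress >= 0.0)
        assert np.all(curve_250.true_strain >= 0.0)

    def test_invalid_arguments_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate_uniaxial(-1.0, 0.1, consts=truth)
        with pytest.raises(ValueError):
            simulate_uniaxial(250.0, 1.5, consts=truth)
        with pytest.raises(ValueError):
            simulate_uniaxial(250.0, 0.1, dt=-1e-7, consts=truth)


# ---------------------------------------------------------------------------
# water EOS
# ---------------------------------------------------------------------------


class TestWaterEOS:
    def test_reference_state_is_stress_free(self):
        assert water_axial_stress(0.0) == 0.0

    def test_linear_fluid_reduction(self):
        eos = WaterEOSParams(rho0=1000.0, c0=1480.0, s=0.0, gamma0=0.0)
        for eta in (0.001, 0.01, 0.1):
            expected = 1000.0 * 1480.0 ** 2 * eta / 1e6
            assert water_axial_stress(eta, eos) == pytest.approx(expected)

    def test_default_constants_brute_force_evaluation(self):
        eta = 0.01
        p = water_axial_stress(eta, WATER)
        brute = (1000.0 * 1480.0 ** 2 * eta / (1.0 - 1.979 * eta) ** 2
                 * (1.0 - 0.11 * eta / 2.0)) / 1e6
        assert p == pytest.approx(brute, rel=1e-14)
        # first-order check: ~rho0 c0^2 eta
        assert p == pytest.approx(1000.0 * 1480.0 ** 2 * eta / 1e6, rel=0.05)

    def test_densification_singularity_rejected(self):
        with pytest.raises(ValueError, match="singularity"):
            water_axial_stress(1.0 / WATER.s, WATER)
        with pytest.raises(ValueError):
            water_axial_stress(-0.01, WATER)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class TestContainers:
    def test_curve_requires_strictly_increasing_strain(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            StressStrainCurve([0.0, 0.1, 0.1], [0.0, 1.0, 2.0], 1.0)

    def test_curve_requires_equal_lengths(self):
        with pytest.raises(ValueError, match="equal length"):
            StressStrainCurve([0.0, 0.1], [0.0], 1.0)

    def test_constants_defaults_match_reference_values(self):
        c = MaterialConstants()
        assert (c.shear_modulus, c.bulk_modulus) == (0.80, 399.73)
        assert (c.ref_shear_rate, c.rate_sensitivity) == (120_000.0, 0.90)
        assert (c.yield_stress, c.pressure_sensitivity) == (9.00, 0.0)
        assert (c.locking_stretch, c.rubbery_modulus) == (2.00, 0.07)
        assert (c.beta_hardening, c.h0, c.g0, c.h1) == (1.4, 0.41, 0.3, 0.0)
        assert (c.xi1_init, c.xistar_init, c.xistar_sat) == (0.0045, 1.2, 0.001)
        assert (c.xi2_init, c.xi2_sat) == (0.0, 0.4)
        assert (c.c_kappa1, c.c_kappa2) == (0.41, 0.0)

    def test_constants_validation(self):
        with pytest.raises(ValueError):
            MaterialConstants(shear_modulus=-1.0)
        with pytest.raises(ValueError):
            MaterialConstants(locking_stretch=0.9)
        with pytest.raises(KeyError):
            MaterialConstants.from_dict({"nonsense": 1.0})
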