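"""Extended Lipari-Szabo relaxation: forward model, split solver, decay fits.

The rigid-rotor oracle below re-derives the observables from scratch
(single-Lorentzian spectral density, dipolar+CSA expressions retyped
independently of the library implementation).
"""

import numpy as np
import pytest

from oligoprobe import relax, synthetic
from oligoprobe.datatypes import (
    DecaySeries,
    MotionModel,
    RelaxationObservables,
    SpinSystemConstants,
)

# ---- independent oracle ----------------------------------------------------
_MU0 = 4.0e-7 * np.pi
_HBAR = 1.054571817e-34
_GAMMA_H = 2.6752218744e8
_GAMMA_N = -2.7126189e7


def rigid_observables_oracle(tau_m, b0=14.09508, r_nh=1.02, csa=-172.0):
    """Single-Lorentzian (rigid isotropic rotor) R1/R2/NOE, coded from the
    textbook formulas without reference to the package implementation."""
    wh = abs(_GAMMA_H) * b0
    wn = abs(_GAMMA_N) * b0

    def j(w):
        return 0.4 * tau_m / (1.0 + (w * tau_m) ** 2)

    d = _MU0 * _HBAR * abs(_GAMMA_H * _GAMMA_N) / (4.0 * np.pi * (r_nh * 1e-10) ** 3)
    c = wn * csa * 1e-6 / np.sqrt(3.0)
    r1 = (d**2 / 4.0) * (j(wh - wn) + 3 * j(wn) + 6 * j(wh + wn)) + c**2 * j(wn)
    r2 = (d**2 / 8.0) * (
        4 * j(0.0) + j(wh - wn) + 3 * j(wn) + 6 * j(wh) + 6 * j(wh + wn)
    ) + (c**2 / 6.0) * (4 * j(0.0) + 3 * j(wn))
    noe = 1.0 + (_GAMMA_H / _GAMMA_N) * (d**2 / 4.0) * (
        6 * j(wh + wn) - j(wh - wn)
    ) / r1
    return r1, r2, noe


def rigid_motion(tau_m):
    return MotionModel(s2f=1.0, s2s=1.0, tau_f=1e-12, tau_s=1e-10, tau_m=tau_m)


# ---- spectral density ------------------------------------------------------
class TestSpectralDensity:
    def test_rigid_limit_is_single_lorentzian(self):
        m = rigid_motion(17e-9)
        for w in (0.0, 1e8, 6e8, 4e9):
            expect = 0.4 * 17e-9 / (1.0 + (w * 17e-9) ** 2)
            assert relax.spectral_density(m, w) == pytest.approx(expect, rel=1e-12)

    def test_j0_rigid_17ns(self):
        assert relax.spectral_density(rigid_motion(17e-9), 0.0) == pytest.approx(
            6.8e-9, rel=1e-9
        )

    def test_monotone_decreasing_in_omega(self):
        m = MotionModel(s2f=0.6, s2s=0.4, tau_f=50e-12, tau_s=2e-9, tau_m=17e-9)
        w = np.logspace(6, 10.5, 200)
        j = relax.spectral_density(m, w)
        assert np.all(np.diff(j) < 0)

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError):
            relax.spectral_density(rigid_motion(17e-9), -1.0)

    def test_motion_invariants_enforced(self):
        with pytest.raises(ValueError):
            MotionModel(s2f=1.0, s2s=1.0, tau_f=1e-9, tau_s=1e-10, tau_m=17e-9)
        with pytest.raises(ValueError):
            MotionModel(s2f=1.2, s2s=1.0, tau_f=1e-12, tau_s=1e-10, tau_m=17e-9)


# ---- forward observables ---------------------------------------------------
class TestForward:
    @pytest.mark.parametrize("tau_m", [2e-9, 10e-9, 17e-9, 52e-9])
    def test_rigid_equivalence_against_oracle(self, tau_m):
        obs = relax.forward_observables(rigid_motion(tau_m))
        r1, r2, noe = rigid_observables_oracle(tau_m)
        assert obs.r1 == pytest.approx(r1, rel=1e-12)
        assert obs.r2 == pytest.approx(r2, rel=1e-12)
        assert obs.noe == pytest.approx(noe, rel=1e-12)

    def test_extreme_narrowing_ratio(self):
        # With J flat, R1 = 2.5 d2 J + c2 J and R2 = 2.5 d2 J + (7/6) c2 J:
        # the dipolar parts match but the CSA weighting leaves a small excess.
        m = MotionModel(s2f=1.0, s2s=1.0, tau_f=1e-15, tau_s=1e-14, tau_m=1e-12)
        obs = relax.forward_observables(m)
        wn = abs(_GAMMA_N) * 14.09508
        d = _MU0 * _HBAR * abs(_GAMMA_H * _GAMMA_N) / (4.0 * np.pi * (1.02e-10) ** 3)
        c = wn * -172.0 * 1e-6 / np.sqrt(3.0)
        limit = (2.5 * d**2 + (7.0 / 6.0) * c**2) / (2.5 * d**2 + c**2)
        assert obs.r2_over_r1 == pytest.approx(limit, rel=1e-3)

    def test_r2_monotone_in_tau_m(self):
        taus = np.linspace(1e-9, 60e-9, 40)
        r2 = [relax.forward_observables(rigid_motion(t)).r2 for t in taus]
        assert np.all(np.diff(r2) > 0)

    def test_noe_physical_range(self):
        for s2f, s2s in [(1.0, 1.0), (0.9, 0.5), (0.5, 0.32), (0.45, 0.36)]:
            m = MotionModel(s2f=s2f, s2s=s2s, tau_f=100e-12, tau_s=1.4e-9, tau_m=17e-9)
            obs = relax.forward_observables(m)
            assert -3.6 <= obs.noe <= 1.0

    def test_custom_constants_respected(self):
        c = SpinSystemConstants(b0=18.79, r_nh=1.04, csa=-160.0)
        a = relax.forward_observables(rigid_motion(10e-9))
        b = relax.forward_observables(rigid_motion(10e-9), c)
        assert a.r1 != b.r1


# ---- order-parameter split -------------------------------------------------
class TestOrderSplit:
    def test_worked_example_noe_near_zero(self):
        motion, obs = relax.solve_order_split(0.16, 100e-12, 1.4e-9, 17e-9)
        assert abs(obs.noe) <= 0.05
        assert motion.s2 == pytest.approx(0.16, rel=1e-9)
        assert 0.16 <= motion.s2f <= 1.0

    def test_s2_total_one_forces_rigid(self):
        motion, _ = relax.solve_order_split(1.0, 100e-12, 1.4e-9, 17e-9)
        assert motion.s2f == 1.0 and motion.s2s == 1.0

    def test_noe_zero_crossing_exists_across_splits(self):
        # "S2 varies from 0.1 to 0.4": a zero-NOE split exists across it
        for s2 in (0.1, 0.2, 0.3, 0.4):
            _, obs = relax.solve_order_split(s2, 100e-12, 1.4e-9, 17e-9)
            assert abs(obs.noe) <= 0.05

    def test_joint_objective(self):
        motion, obs = relax.solve_order_split(
            0.16, 100e-12, 1.4e-9, 17e-9,
            objective="joint", r2_over_r1_target=4.0,
        )
        assert abs(obs.noe) < 0.25

    def test_unreachable_split_reports_best(self):
        # high total order parameter: NOE stays near the rigid value
        with pytest.raises(ValueError, match="best achievable"):
            relax.solve_order_split(0.95, 20e-12, 1e-9, 17e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            relax.solve_order_split(0.0, 100e-12, 1.4e-9, 17e-9)
        with pytest.raises(ValueError):
            relax.solve_order_split(0.16, 100e-12, 1.4e-9, 17e-9, objective="x")
        with pytest.raises(ValueError):
            relax.solve_order_split(0.16, 100e-12, 1.4e-9, 17e-9, objective="joint")


# ---- decay fitting ---------------------------------------------------------
class TestFitDecay:
    def test_exact_decay(self):
        t = np.array([0.05, 0.2, 0.5, 0.9, 1.2])
        series = DecaySeries(delays=t, heights=5.0 * np.exp(-2.0 * t))
        rate, sd, h0 = relax.fit_decay(series)
        assert rate == pytest.approx(2.0, rel=1e-9)
        assert h0 == pytest.approx(5.0, rel=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_noisy_recovery_within_3sd(self):
        rng = np.random.default_rng(42)
        t = synthetic.DEFAULT_R1_DELAYS
        h = np.exp(-1.2 * t) + rng.normal(0.0, 0.02, t.size)
        rate, sd, _ = relax.fit_decay(DecaySeries(delays=t, heights=h, heights_sd=0.02))
        assert abs(rate - 1.2) <= 3.0 * sd

    def test_min_points_enforced(self):
        with pytest.raises(ValueError):
            DecaySeries(delays=[0.1, 0.2], heights=[1.0, 0.5])

    def test_non_decaying_rejected(self):
        t = np.array([0.1, 0.2, 0.4, 0.8])
        with pytest.raises(ValueError, match="decay"):
            relax.fit_decay(DecaySeries(delays=t, heights=np.exp(+0.5 * t)))


class TestNoeFromIntensities:
    def test_plain_ratio(self):
        assert relax.noe_from_intensities(0.8, 1.0, 0.0) == (0.8, 0.0)

    def test_zero_saturated_keeps_finite_sd(self):
        noe, sd = relax.noe_from_intensities(0.0, 1.0, 0.05)
        assert noe == 0.0
        assert sd == pytest.approx(0.05, rel=1e-9)

    def test_negative_noe_preserved(self):
        assert relax.noe_from_intensities(-1.0, 1.0, 0.0) == (-1.0, 0.0)

    def test_zero_unsaturated_rejected(self):
        with pytest.raises(ValueError):
            relax.noe_from_intensities(0.5, 0.0)

    def test_matches_propagation_formula(self):
        i_sat, i_unsat, s = 0.6, 1.2, 0.04
        noe, sd = relax.noe_from_intensities(i_sat, i_unsat, s)
        expect = abs(noe) * np.sqrt((s / i_sat) ** 2 + (s / i_unsat) ** 2)
        assert sd == pytest.approx(expect, rel=1e-9)


def test_r2_over_r1_property():
    obs = RelaxationObservables(r1=2.0, r2=5.0, noe=0.1)
    assert obs.r2_over_r1 == 2.5
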