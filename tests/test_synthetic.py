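"""Generator contracts: determinism, closed-form agreement, recoverability."""

import numpy as np
import pytest

from oligoprobe import binding, relax, saxs, sec_cd, shifts, synthetic
from oligoprobe.datatypes import MotionModel


def test_synthetic_spec_validation():
    spec = synthetic.SyntheticSpec(kind="saxs_sphere", params={"radius": 99.4})
    assert spec.noise_sd == 0.0
    with pytest.raises(ValueError):
        synthetic.SyntheticSpec(kind="not-a-kind")
    with pytest.raises(ValueError):
        synthetic.SyntheticSpec(kind="sensorgram", noise_sd=-1.0)


def test_default_q_grid_instrument_range():
    q = synthetic.default_q_grid()
    assert q[0] == pytest.approx(0.008)
    assert q[-1] == pytest.approx(0.208)
    assert np.all(np.diff(q) > 0)


class TestSphereSaxs:
    def test_forward_limit_q_to_zero(self):
        # I(q)/i0 -> 1 as q -> 0
        c = synthetic.gen_sphere_saxs(100.0, q_grid=[1e-9, 1e-5, 1e-4, 1e-3, 2e-3])
        assert c.intensity[0] == pytest.approx(1.0, abs=1e-12)
        # float cancellation dominates at small-but-finite q
        assert c.intensity[1] == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_matches_closed_form(self):
        c = synthetic.gen_sphere_saxs(99.4, i0=2.0)
        expect = saxs.sphere_form_factor(c.q, 99.4, 2.0)
        assert np.allclose(c.intensity, expect, rtol=1e-12)
        assert c.sigma is None

    def test_determinism(self):
        a = synthetic.gen_sphere_saxs(99.4, noise_sd=0.01, seed=7)
        b = synthetic.gen_sphere_saxs(99.4, noise_sd=0.01, seed=7)
        assert np.array_equal(a.intensity, b.intensity)
        assert np.array_equal(a.sigma, b.sigma)
        c = synthetic.gen_sphere_saxs(99.4, noise_sd=0.01, seed=8)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_sigma_column_set_with_noise(self):
        c = synthetic.gen_sphere_saxs(50.0, noise_sd=0.01, seed=0)
        assert c.sigma is not None and np.all(c.sigma > 0)

    def test_errors(self):
        with pytest.raises(ValueError):
            synthetic.gen_sphere_saxs(-1.0)
        with pytest.raises(ValueError):
            synthetic.gen_sphere_saxs(50.0, q_grid=[])


class TestEllipsoidSaxs:
    def test_unit_axial_ratio_equals_sphere(self):
        e = synthetic.gen_ellipsoid_saxs(60.0, 1.0)
        s = synthetic.gen_sphere_saxs(60.0)
        assert np.allclose(e.intensity, s.intensity, rtol=1e-9)

    def test_elongation_is_detectable(self):
        e = synthetic.gen_ellipsoid_saxs(60.0, 3.0)
        s = synthetic.gen_sphere_saxs(60.0)
        assert not np.allclose(e.intensity, s.intensity, rtol=0.01)


class TestRelaxDecay:
    motion = MotionModel(s2f=0.5, s2s=0.32, tau_f=100e-12, tau_s=1.4e-9, tau_m=17e-9)

    def test_noiseless_exact_recovery(self):
        data = synthetic.gen_relax_decay(self.motion)
        r1, _, h0 = relax.fit_decay(data["r1_series"])
        assert r1 == pytest.approx(data["truth"].r1, rel=1e-9)
        assert h0 == pytest.approx(1.0, rel=1e-9)

    def test_worked_example_split_noe_near_zero(self):
        motion, obs = relax.solve_order_split(0.16, 100e-12, 1.4e-9, 17e-9)
        data = synthetic.gen_relax_decay(motion)
        i_sat, i_unsat = data["noe_pair"]
        assert abs(i_sat / i_unsat) <= 0.05

    def test_determinism(self):
        a = synthetic.gen_relax_decay(self.motion, noise_sd=0.02, seed=3)
        b = synthetic.gen_relax_decay(self.motion, noise_sd=0.02, seed=3)
        assert np.array_equal(a["r1_series"].heights, b["r1_series"].heights)
        assert a["noe_pair"] == b["noe_pair"]

    def test_default_delay_grids(self):
        data = synthetic.gen_relax_decay(self.motion)
        assert data["r1_series"].delays[0] == pytest.approx(0.05)
        assert data["r1_series"].delays[-1] == pytest.approx(1.2)
        assert data["r2_series"].delays[0] == pytest.approx(0.017)
        assert data["r2_series"].delays[-1] == pytest.approx(0.22)

    def test_bad_delays(self):
        with pytest.raises(ValueError):
            synthetic.gen_relax_decay(self.motion, delays_r1=[0.1, 0.2])


class TestShiftTable:
    def test_all_coil_scores_identically_zero(self):
        table = synthetic.gen_shift_table(30, [])
        prof = shifts.ssp_profile(table)
        assert np.all(prof["ssp"].to_numpy() == 0.0)

    def test_helix_segment_scores_near_one_inside(self):
        table = synthetic.gen_shift_table(30, [(11, 20, "helix")])
        prof = shifts.ssp_profile(table)
        center = prof.loc[14:17, "ssp"]
        assert np.all(center > 0.95)
        outside = prof.loc[[1, 2, 3, 28, 29, 30], "ssp"]
        assert np.all(outside == 0.0)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_shift_table(30, [(5, 10, "helix"), (8, 12, "strand")])

    def test_segment_bounds_and_state_validated(self):
        with pytest.raises(ValueError):
            synthetic.gen_shift_table(30, [(0, 5, "helix")])
        with pytest.raises(ValueError):
            synthetic.gen_shift_table(30, [(1, 5, "turn")])

    def test_jitter_reproducible(self):
        a = synthetic.gen_shift_table(20, [(5, 10, "helix")], jitter_sd=0.2, seed=1)
        b = synthetic.gen_shift_table(20, [(5, 10, "helix")], jitter_sd=0.2, seed=1)
        assert a.equals(b)


class TestSensorgram:
    def test_zero_koff_dissociation_constant(self):
        grams = synthetic.gen_sensorgram(1e5, 0.0, 100.0, conc=[5e-7])
        g = grams[0]
        post = g.response[g.time >= g.t_stop]
        assert np.allclose(post, post[0], rtol=1e-12)

    def test_half_saturation_identity(self):
        kon, koff, rmax = 1e5, 5.5e-2, 100.0
        conc = koff / kon  # C = Kd
        r = binding.langmuir_response(
            np.array([1e6]), conc, kon, koff, rmax, t_stop=2e6
        )
        assert r[0] == pytest.approx(rmax / 2.0, rel=1e-9)

    def test_default_concentrations(self):
        grams = synthetic.gen_sensorgram(1e5, 5.5e-2, 100.0)
        concs = [g.analyte_conc for g in grams]
        assert concs == pytest.approx([0.2e-6, 0.4e-6, 0.6e-6, 0.8e-6])
        assert grams[0].t_stop == pytest.approx(180.0)

    def test_determinism(self):
        a = synthetic.gen_sensorgram(1e5, 5.5e-2, 100.0, noise_sd=1.0, seed=11)
        b = synthetic.gen_sensorgram(1e5, 5.5e-2, 100.0, noise_sd=1.0, seed=11)
        for ga, gb in zip(a, b):
            assert np.array_equal(ga.response, gb.response)

    def test_nonpositive_constants_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_sensorgram(-1e5, 1e-2, 100.0)
        with pytest.raises(ValueError):
            synthetic.gen_sensorgram(1e5, 1e-2, 100.0, conc=[])


@pytest.fixture(scope="module")
def calibration():
    standards = [(86.0, 7.2), (45.6, 9.1), (36.2, 9.9), (21.4, 11.8), (16.3, 12.6)]
    return sec_cd.fit_calibration(standards)


class TestChromatogram:
    def test_single_peak_exact_recovery(self, calibration):
        chrom, truth = synthetic.gen_chromatogram([(30.0, 1.0, 0.25)], calibration)
        peaks = sec_cd.decompose_peaks(chrom, n_peaks=1)
        assert len(peaks) == 1
        center, width, frac = peaks[0]
        assert frac == pytest.approx(1.0, abs=1e-9)
        assert center == pytest.approx(truth[0][0], rel=1e-3)

    def test_fraction_sum_validated(self, calibration):
        with pytest.raises(ValueError):
            synthetic.gen_chromatogram([(30.0, 0.9, 0.25)], calibration)

    def test_out_of_range_species_flagged(self, calibration):
        chrom, truth = synthetic.gen_chromatogram(
            [(120.0, 0.5, 0.3), (30.0, 0.5, 0.25)], calibration
        )
        assert truth[0][1] is True  # beyond largest standard -> flagged
        assert truth[1][1] is False

    def test_determinism(self, calibration):
        species = [(23.8, 0.666, 0.25), (29.9, 0.277, 0.25), (86.0, 0.057, 0.3)]
        a, _ = synthetic.gen_chromatogram(species, calibration, noise_sd=0.002, seed=5)
        b, _ = synthetic.gen_chromatogram(species, calibration, noise_sd=0.002, seed=5)
        assert np.array_equal(a.absorbance, b.absorbance)


class TestCdDenaturation:
    def test_native_signal_at_zero_urea(self):
        s = synthetic.gen_cd_denaturation(
            3.0, 2.0, native_signal=-10.0, unfolded_signal=-2.0,
            urea_grid=[0.0, 1.0, 3.0, 5.0, 7.0],
        )
        assert s.observable[0] == pytest.approx(-10.0, abs=0.05)

    def test_midpoint_recovery_under_noise(self):
        span = 8.0
        s = synthetic.gen_cd_denaturation(
            3.0, 2.0, native_signal=-10.0, unfolded_signal=-2.0,
            noise_sd=0.02 * span, seed=17,
        )
        norm = sec_cd.normalize_denaturation(s)
        assert norm.midpoint == pytest.approx(3.0, rel=0.05)

    def test_grid_bounds(self):
        with pytest.raises(ValueError):
            synthetic.gen_cd_denaturation(3.0, 2.0, -10.0, -2.0, urea_grid=[])
        with pytest.raises(ValueError):
            synthetic.gen_cd_denaturation(3.0, 2.0, -10.0, -2.0, urea_grid=[0, 9])

    def test_determinism(self):
        a = synthetic.gen_cd_denaturation(3.0, 2.0, -10.0, -2.0, noise_sd=0.1, seed=2)
        b = synthetic.gen_cd_denaturation(3.0, 2.0, -10.0, -2.0, noise_sd=0.1, seed=2)
        assert np.array_equal(a.observable, b.observable)
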