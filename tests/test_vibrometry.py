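"""Vibrometry analysis chain: decomposition, ellipse, profiles, metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oocmech import vibrometry
from oocmech.vibrometry import (DeflectionProfile, MotionVector, align_rigid,
                                compose_two_angle, contact_stiffness,
                                corner_frequency, decompose_two_angle,
                                ellipse_major_axis, fwhm_fraction,
                                hair_bundle_deflection,
                                hf_slope_db_per_octave, ncc_displacement,
                                phase_accumulation_deg, volume_compliance)

# frozen oracle: independent linear solve of the 2x2 system at the worked
# angle pair [d1, d2] = [[sin(-30), cos(-30)], [sin 13, cos 13]] [d_r, d_t]
# with d1 = d2 = 1 (numpy.linalg.solve, frozen)
_DR_EXPECTED = -0.15886352130064912
_DT_EXPECTED = 1.0629806415919099


class TestTwoAngleDecomposition:
    def test_axis_aligned_identity(self):
        v = decompose_two_angle(0.3 + 0.1j, 0.7 - 0.2j, 90.0, 0.0)
        assert v.d_r == pytest.approx(0.3 + 0.1j)
        assert v.d_t == pytest.approx(0.7 - 0.2j)

    def test_worked_angle_pair(self):
        v = decompose_two_angle(1.0, 1.0, -30.0, 13.0)
        assert v.d_r == pytest.approx(_DR_EXPECTED, rel=1e-12)
        assert v.d_t == pytest.approx(_DT_EXPECTED, rel=1e-12)

    def test_singular_geometry_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            decompose_two_angle(1.0, 1.0, 13.0, 13.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(dr_re=st.floats(-1, 1), dr_im=st.floats(-1, 1),
           dt_re=st.floats(-1, 1), dt_im=st.floats(-1, 1),
           t1=st.floats(-80, 80), dt_ang=st.floats(5, 90))
    def test_compose_decompose_roundtrip(self, dr_re, dr_im, dt_re, dt_im,
                                         t1, dt_ang):
        truth = MotionVector(complex(dr_re, dr_im), complex(dt_re, dt_im))
        t2 = t1 + dt_ang
        d1 = compose_two_angle(truth, t1)
        d2 = compose_two_angle(truth, t2)
        back = decompose_two_angle(d1, d2, t1, t2)
        assert abs(back.d_r - truth.d_r) < 1e-9
        assert abs(back.d_t - truth.d_t) < 1e-9


def _brute_force_major_axis(v: MotionVector, n=4096):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    traj = np.stack([np.real(v.d_r * np.exp(1j * t)),
                     np.real(v.d_t * np.exp(1j * t))])
    i = np.argmax(np.hypot(*traj))
    return np.hypot(*traj)[i], traj[:, i]


class TestEllipse:
    def test_pure_transverse(self):
        ax = ellipse_major_axis(MotionVector(0.0, 2.5))
        assert ax.amplitude == pytest.approx(2.5)
        assert ax.theta_deg == pytest.approx(0.0)

    def test_circular_motion_flagged(self):
        ax = ellipse_major_axis(MotionVector(1.0, 1.0j))
        assert ax.amplitude == pytest.approx(1.0)
        assert ax.degenerate

    def test_zero_vector(self):
        ax = ellipse_major_axis(MotionVector(0.0, 0.0))
        assert ax.amplitude == 0.0 and ax.degenerate

    def test_in_phase_angle(self):
        ax = ellipse_major_axis(MotionVector(0.5, 1.0))
        assert ax.theta_deg == pytest.approx(math.degrees(math.atan2(0.5, 1.0)),
                                             abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1),
           st.floats(-1, 1))
    def test_matches_time_sampled_oracle(self, a, b, c, d):
        v = MotionVector(complex(a, b), complex(c, d))
        ax = ellipse_major_axis(v)
        amp, direction = _brute_force_major_axis(v)
        assert ax.amplitude == pytest.approx(amp, rel=1e-5, abs=1e-9)
        if amp > 1e-6 and not ax.degenerate:
            got = math.radians(ax.theta_deg)
            want = math.atan2(direction[0], direction[1])
            diff = abs(got - want) % math.pi
            assert min(diff, math.pi - diff) < 1e-2


class TestHairBundle:
    def test_equal_vectors_zero(self):
        u = MotionVector(1.0 + 2.0j, -0.5j)
        assert hair_bundle_deflection(u, u) == 0.0

    def test_zero_reference(self):
        u = MotionVector(0.3, 0.4)
        assert hair_bundle_deflection(u, MotionVector(0, 0)) \
            == pytest.approx(0.5)

    def test_antiphase_doubling(self):
        u = MotionVector(0.3, 0.4)
        minus = MotionVector(-0.3, -0.4)
        assert hair_bundle_deflection(u, minus) == pytest.approx(1.0)


class TestProfiles:
    def _triangle(self):
        r = np.linspace(0.0, 300.0, 31)
        w = 100.0 * (1 - np.abs(r - 150.0) / 150.0)
        return DeflectionProfile(r, w, pressure_pa=5.6, bm_width_um=300.0)

    def test_triangle_volume_compliance(self):
        peak, vol = volume_compliance(self._triangle())
        # hand value: 0.5 * 100 nm * 300 um / 5.6 Pa = 2.68 mm^4/N
        assert vol == pytest.approx(2.68, abs=0.01)
        assert peak == pytest.approx(100.0 / 5.6, rel=1e-6)

    def test_zero_profile(self):
        prof = DeflectionProfile(np.linspace(0, 300, 11), np.zeros(11),
                                 pressure_pa=5.6, bm_width_um=300.0)
        assert volume_compliance(prof)[1] == 0.0

    def test_zero_pressure_rejected(self):
        prof = self._triangle()
        prof.pressure_pa = 0.0
        with pytest.raises(ValueError):
            volume_compliance(prof)

    def test_compliance_linear_fwhm_invariant_under_scaling(self):
        prof = self._triangle()
        scaled = DeflectionProfile(prof.positions_um,
                                   3.0 * prof.displacement_nm,
                                   prof.pressure_pa, prof.bm_width_um)
        assert volume_compliance(scaled)[1] == pytest.approx(
            3.0 * volume_compliance(prof)[1])
        assert fwhm_fraction(scaled) == pytest.approx(fwhm_fraction(prof))

    def test_triangle_fwhm_half_base(self):
        assert fwhm_fraction(self._triangle()) == pytest.approx(0.5, abs=1e-6)

    def test_half_cosine_fwhm(self):
        r = np.linspace(0.0, 300.0, 601)
        w = 100.0 * np.cos(np.pi * (r - 150.0) / 300.0)
        prof = DeflectionProfile(r, w, 5.6, 300.0)
        assert fwhm_fraction(prof) == pytest.approx(2.0 / 3.0, abs=1e-3)

    def test_bimodal_uses_peak_region(self):
        r = np.linspace(0.0, 300.0, 301)
        w = 100.0 * np.exp(-((r - 100) / 20.0) ** 2) \
            + 70.0 * np.exp(-((r - 250) / 20.0) ** 2)
        prof = DeflectionProfile(r, w, 5.6, 300.0)
        # FWHM of the 100-nm peak alone: 2*sigma*sqrt(ln 2) with sigma 20
        assert fwhm_fraction(prof) == pytest.approx(
            2 * 20.0 * math.sqrt(math.log(2)) / 300.0, rel=0.05)

    def test_positions_must_increase(self):
        with pytest.raises(ValueError):
            DeflectionProfile(np.array([0.0, 2.0, 1.0]), np.zeros(3), 1.0,
                              300.0)


class TestImageDisplacement:
    def test_identical_images_zero_shift(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((96, 96))
        est = ncc_displacement(img, img, window=31)
        assert est.valid.all()
        assert np.allclose(est.shifts_px, 0.0)

    def test_integer_shift_recovered_exactly(self):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((96, 96))
        moved = np.roll(img, 3, axis=0)
        est = ncc_displacement(img, moved, window=31, upsample=1)
        shifts = est.shifts_px[est.valid]
        assert np.allclose(shifts[:, 0], 3.0)
        assert np.allclose(shifts[:, 1], 0.0)

    def test_flat_window_flagged_not_raised(self):
        img = np.zeros((64, 64))
        est = ncc_displacement(img, img, window=31)
        assert not est.valid.any()
        with pytest.raises(ValueError):
            est.mean_shift_px()

    def test_even_window_rejected(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError):
            ncc_displacement(img, img, window=16)

    def test_rigid_alignment_roundtrip(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(0, 100, size=(14, 2))
        ang = 0.3
        rot = np.array([[math.cos(ang), -math.sin(ang)],
                        [math.sin(ang), math.cos(ang)]])
        dst = src @ rot.T + [5.0, -3.0]
        tf = align_rigid(src, dst)
        assert np.allclose(tf(src), dst, atol=1e-8)


class TestModelProbes:
    def test_contact_stiffness_constrained_node_rejected(self, small_system):
        with pytest.raises(ValueError, match="constrained"):
            contact_stiffness(small_system, node=0)

    def test_contact_stiffness_monotone_in_bm_modulus(self, mats):
        from oocmech import pipeline
        vals = []
        for scale in (1.0, 2.0):
            cfg = pipeline.ModelConfig(span_mm=0.2, bm_scale=scale,
                                       with_fluid=False)
            system, _ = pipeline.build_model(cfg, mats)
            vals.append(contact_stiffness(system))
        assert vals[1] > vals[0]


class TestResponseMetrics:
    @staticmethod
    def _resonator(q=1.0, f0=1000.0):
        f = np.geomspace(10.0, 100000.0, 300)
        u = f / f0
        h = 1.0 / (1.0 - u ** 2 + 1j * u / q)
        return f, h

    def test_corner_frequency_near_resonance(self):
        f, h = self._resonator()
        fc = corner_frequency(f, h)
        assert 1000.0 < fc < 2000.0

    def test_high_frequency_slope_is_minus_12(self):
        f, h = self._resonator()
        slope = hf_slope_db_per_octave(f, h, (50000.0, 100000.0))
        assert slope == pytest.approx(-12.0, abs=0.5)

    def test_phase_accumulation_is_180(self):
        f, h = self._resonator()
        assert phase_accumulation_deg(f, h) == pytest.approx(180.0, abs=5.0)
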