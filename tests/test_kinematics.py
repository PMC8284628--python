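"""Saccade synthesis, filtering, segmentation, and trial-pair analysis."""

import numpy as np
import pytest

from saccade_adapt.errors import KinematicsError
from saccade_adapt.kinematics import (
    ProfileConfig, SaccadeTrace, chsp_filter, clamp_landing_prediction,
    classify_pair_error, compensation_onset, lowpass_filter, pair_response,
    phase_displacements, profile_accel_fraction, segment_by_peak_speed,
    synthesize_saccade,
)


def _integral(v, t_ms):
    return np.trapezoid(v, t_ms / 1000.0)


class TestSynthesis:
    def test_pure_vertical_saccade(self):
        tr = synthesize_saccade(15.0)
        assert np.all(tr.Hdot == 0.0)
        assert _integral(tr.Vdot, tr.t) == pytest.approx(15.0, abs=1e-6)

    def test_components_sum_to_horizontal_displacement(self):
        tr = synthesize_saccade(15.0, 1.2, 0.5, -0.3)
        assert _integral(tr.Hdot, tr.t) == pytest.approx(1.4, abs=1e-6)

    def test_component_confinement(self):
        tr = synthesize_saccade(15.0, 0.0, 0.5, 0.5)
        seg = segment_by_peak_speed(tr)
        yA, yD = phase_displacements(tr, seg)
        assert yA == pytest.approx(0.5, abs=0.01)
        assert yD == pytest.approx(0.5, abs=0.01)

    def test_negative_duration_rejected(self):
        with pytest.raises(KinematicsError):
            ProfileConfig(accel_ms=-5.0)


class TestLowpass:
    def test_dc_passes_unchanged(self):
        t = np.arange(200, dtype=float)
        const = np.full(200, 3.3)
        tr = SaccadeTrace(t, const, const, const, const)
        out = lowpass_filter(tr)
        np.testing.assert_allclose(out.Hdot, const, atol=1e-9)

    def test_double_cutoff_component_strongly_attenuated(self):
        t = np.arange(1000, dtype=float)
        sine = np.sin(2 * np.pi * 400.0 * t / 1000.0)
        tr = SaccadeTrace(t, sine, sine, sine, sine)
        out = lowpass_filter(tr)
        mid = out.Hdot[200:800]
        assert np.abs(mid).max() < 0.1  # > 90 % attenuation at 400 Hz

    def test_near_idempotent_in_passband(self):
        t = np.arange(1000, dtype=float)
        sine = np.sin(2 * np.pi * 50.0 * t / 1000.0)
        tr = SaccadeTrace(t, sine, sine, sine, sine)
        once = lowpass_filter(tr)
        twice = lowpass_filter(once)
        mid = slice(100, 900)
        assert np.abs(twice.Hdot[mid] - once.Hdot[mid]).max() < 0.01

    def test_short_trace_rejected(self):
        t = np.arange(5, dtype=float)
        z = np.zeros(5)
        with pytest.raises(KinematicsError, match="short"):
            lowpass_filter(SaccadeTrace(t, z, z, z, z))


class TestSegmentation:
    def test_symmetric_triangular_profile_peaks_at_midpoint(self):
        t = np.arange(100, dtype=float)
        v = np.zeros(100)
        v[10:81] = 400.0 * (1.0 - np.abs(t[10:81] - 45.0) / 35.0)
        tr = SaccadeTrace(t, np.zeros(100), np.zeros(100), np.zeros(100), v)
        seg = segment_by_peak_speed(tr)
        assert seg.t_peak == 45
        assert abs(seg.accel_duration_ms - seg.decel_duration_ms) <= 1

    def test_default_profile_accel_duration(self):
        tr = synthesize_saccade(15.0)
        seg = segment_by_peak_speed(tr)
        assert seg.accel_duration_ms == pytest.approx(20, abs=1)
        assert seg.decel_duration_ms == pytest.approx(50, abs=2)

    def test_peak_timing_stable_under_horizontal_component(self):
        """Adding horizontal displacement up to 3 deg leaves the timing of
        peak speed unchanged within one sample."""
        base = segment_by_peak_speed(synthesize_saccade(15.0)).t_peak
        for aim in (0.5, 1.5, 3.0):
            tr = synthesize_saccade(15.0, aim, 0.0, 0.0)
            assert abs(segment_by_peak_speed(tr).t_peak - base) <= 1

    def test_no_saccade_raises(self):
        t = np.arange(100, dtype=float)
        z = np.zeros(100)
        with pytest.raises(KinematicsError, match="not detected"):
            segment_by_peak_speed(SaccadeTrace(t, z, z, z, z))


class TestPhaseDisplacements:
    def test_rectangle_integral(self):
        t = np.arange(120, dtype=float)
        hdot = np.zeros(120)
        vdot = np.zeros(120)
        hdot[40:101] = 50.0
        vdot[40:101] = 500.0 * (1.0 - np.abs(t[40:101] - 60.0) / 40.0)
        vdot[40:101] = np.maximum(vdot[40:101], 1.0)
        tr = SaccadeTrace(t, np.zeros(120), np.zeros(120), hdot, vdot)
        seg = segment_by_peak_speed(tr)
        yA, yD = phase_displacements(tr, seg)
        assert yA == pytest.approx(50.0 * (seg.t_peak - seg.onset) / 1000.0,
                                   rel=0.06)
        assert yA + yD == pytest.approx(
            _integral(hdot[seg.onset:seg.offset + 1],
                      t[seg.onset:seg.offset + 1]), abs=1e-9)

    def test_zero_velocity_gives_zero_displacement(self):
        tr = synthesize_saccade(15.0)
        seg = segment_by_peak_speed(tr)
        assert phase_displacements(tr, seg) == (0.0, 0.0)

    def test_round_trip_recovers_components(self):
        """Random (aim, acc, dec) triples survive synthesis -> filtering ->
        segmentation -> integration within 0.02 deg per channel."""
        p = profile_accel_fraction()
        rng = np.random.default_rng(4)
        for _ in range(40):
            aim, acc, dec = rng.uniform(-1.5, 1.5, 3)
            tr = lowpass_filter(synthesize_saccade(15.0, aim, acc, dec))
            seg = segment_by_peak_speed(tr)
            yA, yD = phase_displacements(tr, seg)
            assert yA == pytest.approx(p * aim + acc, abs=0.02)
            assert yD == pytest.approx((1 - p) * aim + dec, abs=0.02)


class TestClampLanding:
    def test_closed_form_example(self):
        assert clamp_landing_prediction(14.0, 150.0, -7500.0) == \
            pytest.approx(15.5)

    def test_already_stopped(self):
        assert clamp_landing_prediction(14.0, 0.0, -100.0) == 14.0

    def test_exact_for_constant_deceleration(self):
        # simulate a decelerating axis, sample at the 150 deg/s threshold
        a = -8000.0
        v0 = 600.0
        t = np.arange(0, 0.08, 1e-3)
        v = v0 + a * t
        x = v0 * t + 0.5 * a * t**2
        stop = -v0**2 / (2 * a) + 0.0  # true stop position
        i = np.argmax(v < 150.0)
        pred = clamp_landing_prediction(x[i], v[i], a)
        assert pred == pytest.approx(v0**2 / (-2 * a), abs=1e-9)

    def test_residual_grows_with_jerk(self):
        """Extrapolation error is monotone in the jerk magnitude."""
        errors = []
        for jerk in (0.0, 2e4, 4e4, 8e4):
            a0, v0 = -8000.0, 600.0
            dt = 1e-5
            t = np.arange(0, 0.2, dt)
            acc = a0 + jerk * t
            v = v0 + np.cumsum(acc) * dt
            x = np.cumsum(v) * dt
            stop_i = np.argmax(v <= 0.0)
            i = np.argmax(v < 150.0)
            pred = clamp_landing_prediction(x[i], v[i], acc[i])
            errors.append(abs(pred - x[stop_i]))
        assert errors == sorted(errors)

    def test_non_decelerating_raises(self):
        with pytest.raises(KinematicsError, match="decelerating"):
            clamp_landing_prediction(1.0, 100.0, 50.0)


class TestPairAnalysis:
    @pytest.mark.parametrize("err,expected", [
        (3.0, "Hplus"), (-3.0, "Hminus"), (2.0, "excluded"),
        (-2.0, "excluded"),
    ])
    def test_classify_pair_error(self, err, expected):
        assert classify_pair_error(err) == expected

    @pytest.mark.parametrize("d,keep", [
        (0.6, False), (0.0, True), (-0.4, True), (-0.7, False)])
    def test_chsp_filter(self, d, keep):
        assert chsp_filter(0.0, d) is keep

    def test_identical_traces_give_zero_response(self):
        tr = synthesize_saccade(15.0, 1.0, 0.0, 0.0)
        resp = pair_response(tr, tr, 3.0)
        assert np.all(resp.dHdot == 0.0)
        assert resp.error_class == "Hplus"

    def test_constant_offset_recovered(self):
        tr = synthesize_saccade(15.0)
        shifted = SaccadeTrace(tr.t, tr.H, tr.V, tr.Hdot + 10.0, tr.Vdot)
        resp = pair_response(tr, shifted, -3.0)
        np.testing.assert_allclose(resp.dHdot, 10.0)
        assert resp.error_class == "Hminus"

    def test_deceleration_only_difference(self):
        a = synthesize_saccade(15.0, 1.0, 0.2, 0.3)
        b = synthesize_saccade(15.0, 1.0, 0.2, 0.8)
        resp = pair_response(a, b, 3.0)
        seg = segment_by_peak_speed(a)
        assert np.abs(resp.dHdot[:seg.t_peak + 1]).max() < 1e-9
        assert np.abs(resp.dHdot[seg.t_peak:seg.offset]).max() > 1.0


class TestCompensationOnset:
    def test_single_crossing(self):
        x = np.concatenate([np.full(24, -1.0), np.full(40, 5.0)])
        assert compensation_onset(x, baseline_sd=1.0) == 24

    def test_positive_from_start(self):
        assert compensation_onset(np.full(40, 5.0), baseline_sd=1.0) == 0

    def test_no_qualifying_crossing(self):
        assert compensation_onset(np.full(40, -1.0), baseline_sd=1.0) is None

    def test_brief_blip_does_not_count(self):
        x = np.full(60, -1.0)
        x[10:15] = 5.0  # 5 ms < 10 ms hold
        x[30:] = 5.0
        assert compensation_onset(x, baseline_sd=1.0) == 30

    def test_single_error_correction_onset_near_deceleration_start(self):
        """A deceleration-confined correction yields an onset within ~2 ms
        of the start of the deceleration period."""
        base = synthesize_saccade(15.0)
        corrected = synthesize_saccade(15.0, 0.0, 0.0, 0.5)
        resp = pair_response(base, corrected, 3.0)
        seg = segment_by_peak_speed(base)
        onset = compensation_onset(resp.dHdot, baseline_sd=0.1)
        assert onset is not None
        assert abs(onset - seg.t_peak) <= 2
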