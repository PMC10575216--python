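"""Gait event detection and spatiotemporal parameter recovery."""

import numpy as np
import pytest

from pdkin import synthetic as syn
from pdkin.errors import DegenerateGeometryError, InsufficientGaitError
from pdkin.gait import (GaitEvents, detect_gait_events, gait_feature_vector,
                        joint_angles, spatiotemporal_params)
from pdkin.mocap import CANONICAL_MARKERS, Recording

RATE = 120.0


def test_detects_ground_truth_strikes(walk_recording):
    rec, gt = walk_recording
    events = detect_gait_events(rec)
    for truth, detected in ((gt.heel_strike_times_left, events.heel_strikes_left),
                            (gt.heel_strike_times_right,
                             events.heel_strikes_right)):
        matched = sum(np.min(np.abs(detected - t)) < 0.05 for t in truth)
        assert matched / len(truth) >= 0.95


def test_standing_recording_raises(simple_recording):
    with pytest.raises(InsufficientGaitError):
        detect_gait_events(simple_recording)


def test_turning_in_place_yields_no_walking_events(pigd_participant):
    rec, _ = syn.synthesize_session(pigd_participant, "turn_360",
                                    duration=30.0, seed=3)
    with pytest.raises(InsufficientGaitError):
        detect_gait_events(rec)


def test_time_shift_equivariance(walk_recording):
    rec, _ = walk_recording
    events = detect_gait_events(rec)
    shift_frames = 120  # crop the first second
    cropped = Recording(data=rec.data[shift_frames:], sampling_rate=RATE,
                        marker_names=list(rec.marker_names))
    shifted = detect_gait_events(cropped)
    offset = shift_frames / RATE
    expected = events.heel_strikes_left[events.heel_strikes_left > offset + 0.3]
    for t in expected[:-1]:
        assert np.min(np.abs(shifted.heel_strikes_left - (t - offset))) < 0.02


class TestSpatiotemporalDefinitions:
    """Hand-built events with known geometry."""

    def _recording(self, n_sec=6.0, speed=100.0):
        n = int(n_sec * RATE)
        t = np.arange(n) / RATE
        data = np.zeros((n, len(CANONICAL_MARKERS), 3))
        names = list(CANONICAL_MARKERS)
        data[:, names.index("Sacral"), 2] = speed * t
        data[:, names.index("L.Heel"), 0] = -10.0
        data[:, names.index("R.Heel"), 0] = 10.0
        data[:, names.index("L.Heel"), 2] = speed * t
        data[:, names.index("R.Heel"), 2] = speed * t
        return Recording(data=data, sampling_rate=RATE, marker_names=names)

    def _events(self, n_sec=6.0):
        left = np.arange(0.5, n_sec - 0.5, 1.0)
        right = left + 0.5
        return GaitEvents(heel_strikes_left=left,
                          heel_strikes_right=right,
                          toe_offs_left=left + 0.6,
                          toe_offs_right=right + 0.6)

    def test_cadence_from_half_second_steps(self):
        # alternating strikes every 0.5 s -> 120 steps/min
        gp = spatiotemporal_params(self._recording(), self._events(),
                                   include_angles=False)
        assert gp.cadence_avg == pytest.approx(120.0, rel=1e-6)

    def test_step_width_from_lateral_offsets(self):
        gp = spatiotemporal_params(self._recording(), self._events(),
                                   include_angles=False)
        assert gp.step_width == pytest.approx(20.0, abs=1e-9)

    def test_stride_and_step_lengths_track_speed(self):
        # heels ride the sacral path at 100 cm/s; 1 s between ipsilateral
        # strikes -> 100 cm strides, 50 cm steps
        gp = spatiotemporal_params(self._recording(), self._events(),
                                   include_angles=False)
        assert gp.stride_length_avg_left == pytest.approx(100.0, rel=1e-9)
        assert gp.step_length_avg_left == pytest.approx(50.0, rel=1e-9)
        assert gp.forward_velocity_avg == pytest.approx(100.0, rel=1e-6)

    def test_support_phase_fractions(self):
        gp = spatiotemporal_params(self._recording(), self._events(),
                                   include_angles=False)
        assert gp.total_support_pct_left == pytest.approx(60.0, abs=0.5)
        assert gp.swing_pct_left + gp.total_support_pct_left == pytest.approx(
            100.0, abs=1e-9)
        assert gp.initial_double_support_pct_left == pytest.approx(10.0, abs=0.5)
        assert gp.single_support_pct_left == pytest.approx(40.0, abs=0.5)


def test_recovery_against_generator_truth(cohort6):
    stride_err, cadence_err, support_err = [], [], []
    for p in cohort6:
        rec, gt = syn.synthesize_session(p, "walk_thru", duration=10.0, seed=4)
        gp = spatiotemporal_params(rec, detect_gait_events(rec),
                                   include_angles=False)
        stride = np.nanmean([gp.stride_length_avg_left,
                             gp.stride_length_avg_right])
        stride_err.append(abs(stride - gt.true_stride_length)
                          / gt.true_stride_length)
        cadence_err.append(abs(gp.cadence_avg - gt.true_cadence)
                           / gt.true_cadence)
        support = np.nanmean([gp.total_support_pct_left,
                              gp.total_support_pct_right])
        support_err.append(abs(support - gt.true_support_pct)
                           / gt.true_support_pct)
    assert np.median(stride_err) < 0.05
    assert np.median(cadence_err) < 0.05
    assert np.median(support_err) < 0.10


def test_rigid_translation_invariance(walk_recording):
    rec, _ = walk_recording
    moved = rec.copy()
    moved.data += np.array([55.0, -20.0, 1000.0])
    a = spatiotemporal_params(rec, detect_gait_events(rec),
                              include_angles=False).to_series()
    b = spatiotemporal_params(moved, detect_gait_events(moved),
                              include_angles=False).to_series()
    keep = [k for k in a.index if "angle" not in k]
    np.testing.assert_allclose(a[keep].to_numpy(float),
                               b[keep].to_numpy(float), rtol=1e-6)


class TestJointAngles:
    def _rec(self, thigh, shank, heel, sacral=(0.0, 100.0, 0.0)):
        data = np.zeros((10, len(CANONICAL_MARKERS), 3))
        names = list(CANONICAL_MARKERS)
        for nm, pos in (("Sacral", sacral), ("L.Thigh", thigh),
                        ("L.Shank", shank), ("L.Heel", heel)):
            data[:, names.index(nm)] = pos
        # keep the right side non-degenerate
        for nm, pos in (("R.Thigh", (5, 60, 0)), ("R.Shank", (5, 30, 5)),
                        ("R.Heel", (5, 5, 0))):
            data[:, names.index(nm)] = pos
        return Recording(data=data, sampling_rate=RATE, marker_names=names)

    def test_collinear_gives_zero(self):
        rec = self._rec(thigh=(0, 60, 0), shank=(0, 20, 0), heel=(0, 0, 10))
        ja = joint_angles(rec)
        np.testing.assert_allclose(ja.knee_left, 0.0, atol=1e-9)

    def test_right_angle_pose(self):
        # Sacral->Thigh straight down, Thigh->Shank straight forward
        rec = self._rec(thigh=(0, 60, 0), shank=(0, 60, 40), heel=(0, 20, 40))
        ja = joint_angles(rec)
        np.testing.assert_allclose(ja.knee_left, 90.0, atol=1e-9)
        np.testing.assert_allclose(ja.ankle_left, 90.0, atol=1e-9)

    def test_coincident_markers_name_frame(self):
        rec = self._rec(thigh=(0, 100, 0), shank=(0, 30, 0), heel=(0, 0, 0),
                        sacral=(0, 100, 0))
        with pytest.raises(DegenerateGeometryError, match="frame 0"):
            joint_angles(rec)

    def test_angle_range_recovery(self, walk_recording):
        rec, gt = walk_recording
        ja = joint_angles(rec)
        true_range = float(np.ptp(gt.true_knee_angle))
        assert np.ptp(ja.knee_left) == pytest.approx(true_range, rel=0.10)


class TestGaitFeatureVector:
    def test_height_normalization_arithmetic(self, walk_recording):
        rec, _ = walk_recording
        raw = gait_feature_vector(rec, include_angles=False)
        norm = gait_feature_vector(rec, height=180.0,
                                   normalize_by_height=True,
                                   include_angles=False)
        assert norm["step_length_avg_left"] == pytest.approx(
            raw["step_length_avg_left"] / 180.0)

    def test_default_height_imputed_as_180(self, walk_recording):
        rec, _ = walk_recording
        a = gait_feature_vector(rec, normalize_by_height=True,
                                include_angles=False)
        b = gait_feature_vector(rec, height=180.0, normalize_by_height=True,
                                include_angles=False)
        np.testing.assert_allclose(a.to_numpy(float), b.to_numpy(float))

    def test_flag_off_keeps_raw_cm(self, walk_recording):
        rec, _ = walk_recording
        raw = gait_feature_vector(rec, height=160.0, normalize_by_height=False,
                                  include_angles=False)
        assert raw["stride_length_avg_left"] > 50  # plausible cm scale

    def test_insufficient_gait_propagates(self, simple_recording):
        with pytest.raises(InsufficientGaitError):
            gait_feature_vector(simple_recording)
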