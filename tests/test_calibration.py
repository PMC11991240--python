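"""Stance detection and the three-axis drift calibration."""

import numpy as np
import pytest

from imugait import calibration as cal
from imugait import trajectory as tj
from imugait.errors import CalibrationError
from imugait.io import EulerSeries, FootRecording, SixAxisSeries
from imugait.trajectory import Trajectory


def make_rec(gyro, fs=200.0):
    n = len(gyro)
    t = np.arange(n) / fs
    z = np.zeros(n)
    return FootRecording(
        side="left",
        six_axis=SixAxisSeries(t=t, gyro=gyro, acc=np.zeros((n, 3))),
        euler=EulerSeries(t=t, roll=z, pitch=z, yaw=z),
        sample_rate_hz=fs,
    )


def make_traj(n=1000, fs=200.0, x=None, y=None, z=None, pitch=None):
    t = np.arange(n) / fs
    zero = np.zeros(n)
    return Trajectory(
        t=t,
        x=zero if x is None else x,
        y=zero if y is None else y,
        z=zero if z is None else z,
        pitch=zero if pitch is None else pitch,
    )


class TestStanceDetection:
    def test_zero_gyro_gives_one_full_window(self):
        rec = make_rec(np.zeros((400, 3)))
        st = cal.detect_stance_windows(rec)
        assert st.windows == [(0, 400)]

    def test_zero_threshold_on_noisy_data_fails(self, rng):
        rec = make_rec(rng.normal(0, 5, (400, 3)))
        with pytest.raises(CalibrationError, match="no stance window"):
            cal.detect_stance_windows(rec, gyro_thresh_dps=0.0)

    def test_short_quiet_bursts_are_rejected(self):
        gyro = np.full((400, 3), 100.0)
        gyro[100:110] = 0.0  # 50 ms, below the 200 ms minimum
        gyro[200:280] = 0.0  # 400 ms, long enough
        rec = make_rec(gyro)
        st = cal.detect_stance_windows(rec)
        assert st.windows == [(200, 280)]

    def test_matches_generator_truth(self, drifting_walk, drifting_analysis):
        """Detected windows overlap ground-truth stance with Jaccard >= 0.8."""
        for side in ("left", "right"):
            detected = drifting_analysis.stance[side].windows
            truth = getattr(drifting_walk, f"truth_stance_{side}")
            n = len(getattr(drifting_walk.session, side).t)
            det = np.zeros(n, bool)
            tru = np.zeros(n, bool)
            for a, b in detected:
                det[a:b] = True
            for a, b in truth:
                tru[a:b] = True
            jaccard = (det & tru).sum() / (det | tru).sum()
            assert jaccard >= 0.8


def two_window_stance(n=1000):
    return cal.StanceWindows([(0, 100), (n - 100, n)])


class TestCalibrateX:
    def test_identity_when_already_correct(self):
        x = np.linspace(0, 10, 1000)
        x[-100:] = 10.0
        traj = make_traj(x=x)
        out = cal.calibrate_x(traj, 10.0, two_window_stance())
        np.testing.assert_allclose(out.x, traj.x, atol=1e-12)
        assert out.calibrated

    def test_rescales_to_lane_length(self):
        x = np.linspace(0, 11.2, 1000)
        x[-100:] = 11.2
        out = cal.calibrate_x(make_traj(x=x), 10.0, two_window_stance())
        np.testing.assert_allclose(out.x, x * (10.0 / 11.2), atol=1e-12)
        assert out.x[-1] == pytest.approx(10.0, abs=1e-9)

    def test_degenerate_endpoint_rejected(self):
        x = np.full(1000, 0.05)
        with pytest.raises(CalibrationError, match="1%"):
            cal.calibrate_x(make_traj(x=x), 10.0, two_window_stance())


class TestCalibrateY:
    def test_identity_when_start_equals_end(self):
        y = np.zeros(1000)
        out = cal.calibrate_y(make_traj(y=y, x=np.linspace(0, 10, 1000)),
                              two_window_stance())
        np.testing.assert_allclose(out.y, y, atol=1e-12)

    def test_constant_mode_applies_printed_formula(self):
        y = np.full(1000, 2.0)
        y[:100] = 0.0  # start windows at 0, end at 2
        out = cal.calibrate_y(make_traj(y=y), two_window_stance(), mode="constant")
        np.testing.assert_allclose(out.y, y - 2.0, atol=1e-12)
        # end-of-walk lateral position re-seated on the start's lane line
        assert abs(np.mean(out.y[-100:])) < 1e-12

    def test_linear_mode_removes_accumulating_drift(self):
        x = np.linspace(0, 10, 1000)
        x[:100] = 0.0
        x[-100:] = 10.0
        y = 0.2 * x  # heading drift growing with forward distance
        out = cal.calibrate_y(make_traj(x=x, y=y), two_window_stance(), mode="linear")
        assert abs(np.mean(out.y[-100:]) - np.mean(out.y[:100])) < 1e-9
        np.testing.assert_allclose(out.y, 0.0, atol=1e-9)


class TestCalibrateZ:
    def test_constant_offset_removed(self):
        z = np.full(1000, 0.3)
        out = cal.calibrate_z(make_traj(z=z), two_window_stance())
        np.testing.assert_allclose(out.z, 0.0, atol=1e-12)

    def test_linear_drift_flattened_peaks_preserved(self):
        n = 1000
        t = np.arange(n) / 200.0
        drift = 0.01 * t
        bump = np.where((t > 2) & (t < 3), 0.05 * np.sin(np.pi * (t - 2)) ** 2, 0.0)
        st = cal.StanceWindows([(0, 100), (620, 700), (n - 100, n)])
        out = cal.calibrate_z(make_traj(n=n, z=drift + bump), st)
        mids = st.midpoints()
        np.testing.assert_allclose(out.z[mids], 0.0, atol=1e-9)
        # the swing bump keeps its height relative to the local baseline
        assert out.z.max() == pytest.approx(0.05, abs=1e-3)

    def test_needs_two_windows(self):
        with pytest.raises(CalibrationError, match=">= 2"):
            cal.calibrate_z(make_traj(), cal.StanceWindows([(0, 100)]))


class TestFullCalibration:
    def test_anchor_invariants_on_drifting_session(self, drifting_walk, drifting_analysis):
        """Forward distance, lateral return and stance heights after calibration."""
        lane = drifting_walk.session.lane_length_m
        for side in ("left", "right"):
            traj = drifting_analysis.trajectories[side]
            stance = drifting_analysis.stance[side]
            mids = stance.midpoints()
            assert traj.x[mids[-1]] == pytest.approx(lane, abs=1e-9)
            (a0, b0), (a1, b1) = stance.windows[0], stance.windows[-1]
            assert abs(np.mean(traj.y[a1:b1]) - np.mean(traj.y[a0:b0])) < 1e-9
            for a, b in stance.windows:
                assert abs(np.mean(traj.z[a:b])) < 0.005

    def test_idempotent(self, drifting_walk, drifting_analysis):
        lane = drifting_walk.session.lane_length_m
        for side in ("left", "right"):
            traj = drifting_analysis.trajectories[side]
            stance = drifting_analysis.stance[side]
            twice, _ = cal.calibrate(traj, lane, stance)
            np.testing.assert_allclose(twice.x, traj.x, atol=1e-9)
            np.testing.assert_allclose(twice.y, traj.y, atol=1e-9)
            np.testing.assert_allclose(twice.z, traj.z, atol=1e-9)

    def test_axis_order_commutes(self, drifting_walk):
        rec = drifting_walk.session.right
        raw = tj.reconstruct(rec)
        stance = cal.detect_stance_windows(rec)
        lane = drifting_walk.session.lane_length_m
        xyz = cal.calibrate_z(
            cal.calibrate_y(cal.calibrate_x(raw, lane, stance), stance),
            stance,
        )
        zyx = cal.calibrate_x(
            cal.calibrate_y(cal.calibrate_z(raw, stance), stance), lane, stance
        )
        np.testing.assert_allclose(xyz.x, zyx.x, atol=1e-9)
        np.testing.assert_allclose(xyz.y, zyx.y, atol=1e-9)
        np.testing.assert_allclose(xyz.z, zyx.z, atol=1e-9)
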