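"""Three-axis drift calibration anchored on straight-lane walking geometry.

Double-integrated IMU trajectories drift: the forward distance misses the
known lane length, the lateral track veers off the lane, and the height
"floats" upward over the walk.  Because the trial is a straight walk of known
length that starts and ends standing still, three cheap anchors fix all of
this without optical motion capture:

* **X** — the forward distance at the final stance must equal the lane
  length; the whole x series is rescaled by ``lane_length / X_end``.
* **Y** — the subject starts and finishes on the lane line, so the lateral
  offset accumulated between the first and last stance is heading drift; it
  is removed either as a constant shift or (default) as a linear-in-x
  de-trend, both of which restore ``y_end == y_start``.
* **Z** — whenever the foot is flat on the ground its height is zero; a
  piecewise-linear baseline through the per-stance height anchors is
  subtracted, flattening every stationary point onto the floor.

Stance windows are detected as intervals where the gyro magnitude stays
small: a foot that is flat on the ground does not rotate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import CalibrationError
from .io import FootRecording
from .trajectory import Trajectory

__all__ = [
    "StanceWindows",
    "CalibrationRecord",
    "detect_stance_windows",
    "calibrate_x",
    "calibrate_y",
    "calibrate_z",
    "calibrate",
]


@dataclass
class StanceWindows:
    """Half-open ``[start, end)`` sample-index intervals of flat-foot stance."""

    windows: list[tuple[int, int]]

    def __post_init__(self) -> None:
        ws = [(int(a), int(b)) for a, b in self.windows]
        if any(b <= a for a, b in ws):
            raise CalibrationError("empty stance window")
        if any(ws[i + 1][0] < ws[i][1] for i in range(len(ws) - 1)):
            raise CalibrationError("stance windows overlap or are unsorted")
        self.windows = ws

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def midpoints(self) -> np.ndarray:
        """Integer midpoint sample index of each window."""
        return np.array([(a + b - 1) // 2 for a, b in self.windows], dtype=int)


@dataclass
class CalibrationRecord:
    """The anchors actually applied: useful for reporting and debugging."""

    x_scale: float
    y_offset: float
    z_anchors: np.ndarray  # height anchor per stance window [m]


def detect_stance_windows(
    rec: FootRecording,
    gyro_thresh_dps: float = 20.0,
    min_duration_s: float = 0.2,
) -> StanceWindows:
    """Maximal intervals where ||gyro|| stays below a threshold long enough.

    Parameters follow the physiology: a swinging foot rotates at hundreds of
    deg/s while a planted foot is essentially still, so a 20 deg/s threshold
    separates the two robustly; 0.2 s rejects the brief mid-swing instant
    where the rotation reverses sign.
    """
    gmag = np.linalg.norm(rec.six_axis.gyro, axis=1)
    quiet = gmag < gyro_thresh_dps
    min_len = max(2, int(round(min_duration_s * rec.sample_rate_hz)))
    windows: list[tuple[int, int]] = []
    edges = np.diff(quiet.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if quiet[0]:
        starts.insert(0, 0)
    if quiet[-1]:
        ends.append(len(quiet))
    for a, b in zip(starts, ends):
        if b - a >= min_len:
            windows.append((a, b))
    if not windows:
        raise CalibrationError(
            f"no stance window found (gyro_thresh={gyro_thresh_dps} deg/s, "
            f"min_duration={min_duration_s} s): cannot anchor calibration"
        )
    return StanceWindows(windows)


def _require_windows(stance: StanceWindows, n: int, what: str) -> None:
    if len(stance) < n:
        raise CalibrationError(f"{what} needs >= {n} stance windows, got {len(stance)}")


def calibrate_x(
    traj: Trajectory, lane_length_m: float, stance: StanceWindows
) -> Trajectory:
    """Rescale x so the final-stance position equals the lane length.

    ``X_end`` is the x value at the midpoint of the last stance window; the
    whole series is multiplied by ``lane_length / X_end``.
    """
    _require_windows(stance, 1, "x calibration")
    x_end = float(traj.x[stance.midpoints()[-1]])
    if abs(x_end) < 0.01 * lane_length_m:
        raise CalibrationError(
            f"X_end = {x_end:.4f} m is below 1% of the lane length; "
            "cannot rescale a degenerate forward track"
        )
    out = traj.copy()
    out.x = out.x * (lane_length_m / x_end)
    out.calibrated = True
    return out


def calibrate_y(
    traj: Trajectory,
    stance: StanceWindows,
    mode: Literal["constant", "linear"] = "linear",
) -> Trajectory:
    """Remove lateral heading drift so the walk ends on the lane line.

    ``Y_start``/``Y_end`` are means of y over the first/last stance window.
    ``constant`` subtracts the single offset ``Y_end - Y_start`` everywhere
    (the literal correction formula, which re-seats the end of the walk on the
    start's lane line); ``linear`` (default) de-trends linearly in the forward
    position, which flattens drift that accumulates during the walk and makes
    the end-of-walk stance mean equal the start-of-walk stance mean exactly.
    """
    _require_windows(stance, 2, "y calibration")
    (a0, b0), (a1, b1) = stance.windows[0], stance.windows[-1]
    y_start = float(np.mean(traj.y[a0:b0]))
    y_end = float(np.mean(traj.y[a1:b1]))
    out = traj.copy()
    if mode == "constant":
        # the literal printed formula: one constant shift of the whole series
        out.y = traj.y - (y_end - y_start)
    elif mode == "linear":
        x_start = float(np.mean(traj.x[a0:b0]))
        x_end = float(np.mean(traj.x[a1:b1]))
        if x_end == x_start:
            raise CalibrationError("degenerate forward track: x_start == x_end")
        # unclipped ramp: its means over the anchor windows are exactly 0 and
        # 1, which makes the endpoint condition exact and the step idempotent
        frac = (traj.x - x_start) / (x_end - x_start)
        out.y = traj.y - frac * (y_end - y_start)
    else:
        raise CalibrationError(f"unknown y calibration mode {mode!r}")
    out.calibrated = True
    return out


def calibrate_z(
    traj: Trajectory, stance: StanceWindows, anchor_spacing_s: float = 0.4
) -> Trajectory:
    """Flatten every flat-foot stance onto the floor.

    Height anchors are read inside each stance window — at both window edges
    and every ``anchor_spacing_s`` in between, so curved drift cannot bow
    away between knots and no drift is left dangling past the outermost
    anchor — and the piecewise-linear baseline through the (anchor time,
    height) knots, held constant outside the outermost knots, is subtracted.
    Afterwards the height is exactly zero at every anchor and continuous
    everywhere, while swing peaks keep their height relative to the local
    baseline.
    """
    _require_windows(stance, 2, "z calibration")
    dt = float(np.mean(np.diff(traj.t)))
    idxs: list[int] = []
    for a, b in stance.windows:
        k = max(2, int(np.ceil((b - a) * dt / anchor_spacing_s)) + 1)
        pos = np.linspace(a, b - 1, k).round().astype(int)
        idxs.extend(int(i) for i in pos)
    idxs = sorted(set(idxs))
    anchors = traj.z[idxs]
    baseline = np.interp(np.arange(len(traj)), idxs, anchors)
    out = traj.copy()
    out.z = traj.z - baseline
    out.calibrated = True
    return out


def calibrate(
    traj: Trajectory,
    lane_length_m: float,
    stance: StanceWindows,
    y_mode: Literal["constant", "linear"] = "linear",
) -> tuple[Trajectory, CalibrationRecord]:
    """Apply the X, Y and Z calibrations (they commute) and report the anchors."""
    mids = stance.midpoints()
    record = CalibrationRecord(
        x_scale=lane_length_m / float(traj.x[mids[-1]]),
        y_offset=float(
            np.mean(traj.y[slice(*stance.windows[-1])])
            - np.mean(traj.y[slice(*stance.windows[0])])
        ),
        z_anchors=traj.z[mids].copy(),
    )
    out = calibrate_x(traj, lane_length_m, stance)
    out = calibrate_y(out, stance, mode=y_mode)
    out = calibrate_z(out, stance)
    return out, record
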