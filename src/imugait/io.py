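"""Reading, writing and aligning per-foot IMU recordings.

The on-disk dialect mirrors the CSV export of a heel-mounted six-axis IMU
logger: each foot produces two comma-separated files sampled nominally at
200 Hz.  The *six-axis* file has seven numeric columns — time [s], angular
velocity about x/y/z [deg/s], linear acceleration along x/y/z [g].  The
*Euler* file has four columns — time [s], roll, pitch, yaw [deg].  A single
non-numeric header line is tolerated and skipped.  A walking session is four
files (two per foot) named by a small YAML manifest.

Axis convention: x forward along the walking lane, y to the subject's left,
z up.  Pitch is dorsal-positive (toe up).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .errors import AlignmentError, DataError, FormatError

__all__ = [
    "SixAxisSeries",
    "EulerSeries",
    "FootRecording",
    "WalkSession",
    "read_six_axis_csv",
    "read_euler_csv",
    "write_six_axis_csv",
    "write_euler_csv",
    "align_streams",
    "load_session",
    "write_session",
]

Side = Literal["left", "right"]

#: numeric text format used by all writers; round-trips float64 exactly
_FMT = "%.17g"


def _as_f64(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _check_time(t: np.ndarray, what: str, min_n: int = 2) -> None:
    if t.size < min_n:
        raise DataError(f"{what}: need at least {min_n} samples, got {t.size}")
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise DataError(f"{what}: time not strictly increasing at row {bad[0] + 1}")


@dataclass
class SixAxisSeries:
    """Time-stamped gyroscope [deg/s] and accelerometer [g] channels."""

    t: np.ndarray
    gyro: np.ndarray  # (n, 3) deg/s
    acc: np.ndarray  # (n, 3) g

    def __post_init__(self) -> None:
        self.t = _as_f64(self.t)
        self.gyro = _as_f64(self.gyro).reshape(-1, 3)
        self.acc = _as_f64(self.acc).reshape(-1, 3)
        _check_time(self.t, "six-axis series")
        if not (len(self.t) == len(self.gyro) == len(self.acc)):
            raise DataError("six-axis series: channel lengths differ")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.t)))


@dataclass
class EulerSeries:
    """Time-stamped roll/pitch/yaw orientation angles in degrees."""

    t: np.ndarray
    roll: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray

    def __post_init__(self) -> None:
        self.t = _as_f64(self.t)
        self.roll = _as_f64(self.roll)
        self.pitch = _as_f64(self.pitch)
        self.yaw = _as_f64(self.yaw)
        _check_time(self.t, "euler series", min_n=1)
        n = len(self.t)
        if not (len(self.roll) == len(self.pitch) == len(self.yaw) == n):
            raise DataError("euler series: channel lengths differ")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class FootRecording:
    """One foot's six-axis and Euler streams resampled to a common uniform grid."""

    side: Side
    six_axis: SixAxisSeries
    euler: EulerSeries
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise DataError(f"side must be 'left' or 'right', got {self.side!r}")
        if len(self.six_axis) != len(self.euler):
            raise DataError("six-axis and euler streams not aligned")
        if not np.allclose(self.six_axis.t, self.euler.t, atol=1e-12, rtol=0):
            raise DataError("six-axis and euler time bases differ")

    @property
    def t(self) -> np.ndarray:
        return self.six_axis.t

    def __len__(self) -> int:
        return len(self.six_axis)


@dataclass
class WalkSession:
    """A two-foot straight-lane walking trial."""

    left: FootRecording
    right: FootRecording
    lane_length_m: float = 10.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.lane_length_m <= 0:
            raise DataError("lane_length_m must be positive")


def _read_numeric_csv(path, min_cols: int, what: str) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{what}: file not found: {path}")
    try:
        df = pd.read_csv(path, header=None, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DataError(f"{what}: empty file: {path}") from None
    # auto-detect a single non-numeric header line
    first = df.iloc[0]
    if any(not _is_number(v) for v in first):
        df = df.iloc[1:]
    if df.shape[1] < min_cols:
        raise FormatError(
            f"{what}: expected >= {min_cols} numeric columns, found {df.shape[1]} in {path}"
        )
    try:
        arr = df.iloc[:, :min_cols].to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise DataError(f"{what}: non-numeric data in {path}: {exc}") from None
    if np.isnan(arr).any():
        raise DataError(f"{what}: missing values in {path}")
    return arr


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def read_six_axis_csv(path) -> SixAxisSeries:
    """Read a six-axis file: columns time, gyro x/y/z [deg/s], accel x/y/z [g]."""
    arr = _read_numeric_csv(path, 7, "six-axis file")
    return SixAxisSeries(t=arr[:, 0], gyro=arr[:, 1:4], acc=arr[:, 4:7])


def read_euler_csv(path) -> EulerSeries:
    """Read an Euler-angle file: columns time, roll, pitch, yaw [deg]."""
    arr = _read_numeric_csv(path, 4, "euler file")
    return EulerSeries(t=arr[:, 0], roll=arr[:, 1], pitch=arr[:, 2], yaw=arr[:, 3])


def write_six_axis_csv(path, series: SixAxisSeries) -> None:
    arr = np.column_stack([series.t, series.gyro, series.acc])
    np.savetxt(path, arr, delimiter=",", fmt=_FMT)


def write_euler_csv(path, series: EulerSeries) -> None:
    arr = np.column_stack([series.t, series.roll, series.pitch, series.yaw])
    np.savetxt(path, arr, delimiter=",", fmt=_FMT)


def align_streams(
    six_axis: SixAxisSeries, euler: EulerSeries, rate_hz: float = 200.0
) -> "FootRecording":
    """Interpolate both streams onto one uniform grid over their time overlap.

    The grid starts at the overlap start and steps by exactly ``1/rate_hz``;
    no sample is extrapolated beyond the overlap.  Yaw is interpolated on the
    unwrapped angle to avoid artefacts at the +-180 deg seam, then re-wrapped.
    Returns a :class:`FootRecording` with ``side`` unset ("left"); callers
    normally re-tag it via :func:`dataclasses.replace`.
    """
    t0 = max(six_axis.t[0], euler.t[0])
    t1 = min(six_axis.t[-1], euler.t[-1])
    if t1 <= t0:
        raise AlignmentError(
            f"streams do not overlap: six-axis [{six_axis.t[0]}, {six_axis.t[-1]}], "
            f"euler [{euler.t[0]}, {euler.t[-1]}]"
        )
    n = int(np.floor((t1 - t0) * rate_hz)) + 1
    t = t0 + np.arange(n) / rate_hz

    def interp(ts, ys):
        return np.interp(t, ts, ys)

    gyro = np.column_stack([interp(six_axis.t, six_axis.gyro[:, i]) for i in range(3)])
    acc = np.column_stack([interp(six_axis.t, six_axis.acc[:, i]) for i in range(3)])
    roll = interp(euler.t, euler.roll)
    pitch = interp(euler.t, euler.pitch)
    yaw_unwrapped = np.unwrap(np.deg2rad(euler.yaw))
    yaw = np.rad2deg(
        np.angle(np.exp(1j * np.interp(t, euler.t, yaw_unwrapped)))
    )
    return FootRecording(
        side="left",
        six_axis=SixAxisSeries(t=t, gyro=gyro, acc=acc),
        euler=EulerSeries(t=t, roll=roll, pitch=pitch, yaw=yaw),
        sample_rate_hz=float(rate_hz),
    )


_MANIFEST_KEYS = ("left_six_axis", "left_euler", "right_six_axis", "right_euler")


def load_session(manifest_path, rate_hz: float = 200.0) -> WalkSession:
    """Load a four-file session described by a YAML manifest.

    Manifest keys: ``left_six_axis``, ``left_euler``, ``right_six_axis``,
    ``right_euler`` (paths relative to the manifest), ``lane_length_m``
    (default 10) and ``subject_id`` (optional).
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"manifest {manifest_path} is not a mapping")
    missing = [k for k in _MANIFEST_KEYS if k not in cfg]
    if missing:
        raise FormatError(f"manifest {manifest_path} missing keys: {missing}")
    base = manifest_path.parent

    def rec(side: Side) -> FootRecording:
        six = read_six_axis_csv(base / cfg[f"{side}_six_axis"])
        eul = read_euler_csv(base / cfg[f"{side}_euler"])
        return replace(align_streams(six, eul, rate_hz), side=side)

    return WalkSession(
        left=rec("left"),
        right=rec("right"),
        lane_length_m=float(cfg.get("lane_length_m", 10.0)),
        subject_id=str(cfg.get("subject_id", "")),
    )


def write_session(directory, session: WalkSession, stem: str = "session") -> Path:
    """Write the four CSV files plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = {"lane_length_m": session.lane_length_m, "subject_id": session.subject_id}
    for side in ("left", "right"):
        foot: FootRecording = getattr(session, side)
        six_name = f"{stem}_{side}_sixaxis.csv"
        eul_name = f"{stem}_{side}_euler.csv"
        write_six_axis_csv(directory / six_name, foot.six_axis)
        write_euler_csv(directory / eul_name, foot.euler)
        cfg[f"{side}_six_axis"] = six_name
        cfg[f"{side}_euler"] = eul_name
    manifest = directory / f"{stem}.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return manifest
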