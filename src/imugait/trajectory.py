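"""Strapdown reconstruction of foot trajectories.

Body-frame accelerometer readings are rotated into the earth frame with the
orientation provided by the sensor's attitude estimator (Euler angles), the
gravity vector is removed, and the free acceleration is doubly integrated
(trapezoidal rule) to position.  The subject stands still before walking, so
the initial velocity and position are zero.  Double integration of biased or
noisy acceleration drifts without bound — the companion ``calibration``
module removes that drift using the known straight-lane geometry.

Conventions: earth frame x forward along the lane, y left, z up; pitch is
dorsal-positive (toe up); the body-to-earth rotation is intrinsic Z-Y-X,
``R = Rz(yaw) @ Ry(-pitch) @ Rx(roll)`` (the pitch sign makes a toe-up foot
tilt the forward axis toward +z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .errors import IntegrationError, ShapeError
from .io import FootRecording

__all__ = [
    "STANDARD_GRAVITY",
    "Trajectory",
    "euler_to_matrix",
    "earth_frame_acceleration",
    "integrate_trajectory",
    "reconstruct",
]

STANDARD_GRAVITY = 9.80665  # m/s^2


@dataclass
class Trajectory:
    """A foot's position track [m] with its pitch angle [deg] on one time base."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    pitch: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "z", "pitch"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = len(self.t)
        if any(len(getattr(self, name)) != n for name in ("x", "y", "z", "pitch")):
            raise ShapeError("trajectory channels have unequal lengths")
        if np.any(np.diff(self.t) <= 0):
            raise ShapeError("trajectory time base not strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xyz(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    def copy(self) -> "Trajectory":
        return Trajectory(
            t=self.t.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            z=self.z.copy(),
            pitch=self.pitch.copy(),
            calibrated=self.calibrated,
        )


def euler_to_matrix(roll_deg, pitch_deg, yaw_deg) -> np.ndarray:
    """Body-to-earth rotation matrices from Euler angles in degrees.

    Intrinsic Z-Y-X composition with dorsal-positive pitch:
    ``R = Rz(yaw) @ Ry(-pitch) @ Rx(roll)``.  Accepts scalars or arrays;
    returns shape ``(..., 3, 3)``.
    """
    roll = np.atleast_1d(np.asarray(roll_deg, dtype=np.float64))
    pitch = np.atleast_1d(np.asarray(pitch_deg, dtype=np.float64))
    yaw = np.atleast_1d(np.asarray(yaw_deg, dtype=np.float64))
    angles = np.stack(
        [np.broadcast_arrays(yaw, -pitch, roll)[i] for i in range(3)], axis=-1
    )
    mats = Rotation.from_euler("ZYX", angles, degrees=True).as_matrix()
    if np.ndim(roll_deg) == 0 and np.ndim(pitch_deg) == 0 and np.ndim(yaw_deg) == 0:
        return mats[0]
    return mats


def earth_frame_acceleration(
    rec: FootRecording,
    gravity: float = STANDARD_GRAVITY,
    gravity_included: bool = True,
) -> np.ndarray:
    """Rotate body-frame accelerometer data to the earth frame, in m/s^2.

    The accelerometer measures specific force in g units in the body frame.
    Each sample is rotated by the Euler-angle rotation for that instant and
    converted to m/s^2.  With ``gravity_included=True`` (raw specific force)
    the constant ``(0, 0, gravity)`` is subtracted afterwards, leaving free
    acceleration; attitude estimators that already output gravity-free
    "earth acceleration" are handled with ``gravity_included=False``.
    Returns an ``(n, 3)`` array.
    """
    R = euler_to_matrix(rec.euler.roll, rec.euler.pitch, rec.euler.yaw)
    body_mps2 = rec.six_axis.acc * gravity
    earth = np.einsum("nij,nj->ni", R, body_mps2)
    if gravity_included:
        earth[:, 2] -= gravity
    return earth


def integrate_trajectory(
    accel: np.ndarray,
    t: np.ndarray,
    pitch: np.ndarray,
    rtol_grid: float = 1e-6,
) -> Trajectory:
    """Doubly integrate earth-frame acceleration to position.

    Trapezoidal rule for both stages; initial velocity and position are zero
    (the subject stands still before the walk).  Requires a uniform time grid
    (relative spread of the sampling interval below ``rtol_grid``).
    """
    accel = np.asarray(accel, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if accel.ndim != 2 or accel.shape[1] != 3 or accel.shape[0] != t.shape[0]:
        raise ShapeError(f"accel must be (n, 3) matching t, got {accel.shape}")
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise IntegrationError("time base must be strictly increasing")
    if (dt.max() - dt.min()) > rtol_grid * dt.mean():
        raise IntegrationError("time grid is not uniform; resample first")
    vel = cumulative_trapezoid(accel, t, axis=0, initial=0.0)
    pos = cumulative_trapezoid(vel, t, axis=0, initial=0.0)
    return Trajectory(
        t=t, x=pos[:, 0], y=pos[:, 1], z=pos[:, 2], pitch=np.asarray(pitch, float),
        calibrated=False,
    )


def reconstruct(
    rec: FootRecording,
    gravity: float = STANDARD_GRAVITY,
    gravity_included: bool = True,
) -> Trajectory:
    """Full strapdown reconstruction: rotate, remove gravity, doubly integrate."""
    accel = earth_frame_acceleration(rec, gravity=gravity, gravity_included=gravity_included)
    return integrate_trajectory(accel, rec.t, rec.euler.pitch)
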