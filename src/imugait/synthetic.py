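"""Forward simulation of two-foot straight-lane walking with known truth.

The generator emulates the signals a heel-mounted six-axis IMU produces
during a straight walk of ``n_strides`` strides: per-foot forward position,
lateral position, heel height and pitch angle are built from smooth closed
forms (seventh-order smoothstep advances, warped sin^4 heel lifts,
piecewise-quintic pitch arcs), so body-frame accelerations and the
pitch-rate gyro follow by exact differentiation and inverse rotation — no
numerical differentiation noise.  Sensor imperfections are then layered on:
white accelerometer/gyro noise, a constant accelerometer bias (the quadratic
height drift seen in uncalibrated walks), and a heading offset in the
recorded yaw (the lateral veer that the Y calibration removes).

Hemiparetic asymmetry enters through ``left_step_share`` (spatial step
asymmetry), per-foot pitch amplitudes (reduced push-off/heel-strike arcs on
the affected side), and ``stride_time_asym`` (the affected foot's heel
strike lags a growing fraction of the cycle, so its mean stride time is
longer by exactly that fraction).

Every simulated session carries its ground truth: noise-free trajectories,
the eight gait-cycle events at their exact construction times, and the
flat-foot stance intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DataError
from .events import CANONICAL_ORDER, GaitCycle, GaitEvent, GaitState
from .io import EulerSeries, FootRecording, SixAxisSeries, WalkSession
from .trajectory import STANDARD_GRAVITY, Trajectory

__all__ = [
    "GaitSimParams",
    "SyntheticSession",
    "simulate_walk",
    "simulate_cohort",
    "simulate_repetition_cohort",
]


# ---------------------------------------------------------------- primitives


def _smoothstep(u):
    """Quintic smoothstep: C2, zero first and second derivative at both ends."""
    return u ** 3 * (10.0 - 15.0 * u + 6.0 * u ** 2)


def _smoothstep_d1(u):
    return 30.0 * u ** 2 * (1.0 - u) ** 2


def _smoothstep_d2(u):
    return 60.0 * u * (2.0 * u - 1.0) * (u - 1.0)


def _step7(u):
    """Seventh-order smoothstep: C3, so jerk vanishes at segment boundaries.

    Used for the forward advance: a continuous-jerk position profile keeps
    the trapezoidal re-integration of its sampled acceleration exact to
    numerical precision, so the noise-free round trip closes.
    """
    return u ** 4 * (35.0 - 84.0 * u + 70.0 * u ** 2 - 20.0 * u ** 3)


def _step7_d1(u):
    return 140.0 * u ** 3 * (1.0 - u) ** 3


def _step7_d2(u):
    return 420.0 * u ** 2 * (1.0 - u) ** 2 * (1.0 - 2.0 * u)


def _warp(u, beta):
    """Front-loading phase warp w(0)=0, w(1)=1; larger beta -> earlier peak."""
    return (1.0 + beta) * u - beta * u ** 2


def _warp_d1(u, beta):
    return (1.0 + beta) - 2.0 * beta * u


def _warp_d2(u, beta):
    return -2.0 * beta * np.ones_like(u)


def _solve_warp(c, beta):
    """u in [0, 1] with _warp(u) == c."""
    disc = (1.0 + beta) ** 2 - 4.0 * beta * c
    return ((1.0 + beta) - np.sqrt(disc)) / (2.0 * beta) if beta != 0 else c


def _solve_smoothstep(c):
    """u in [0, 1] with _smoothstep(u) == c."""
    return brentq(lambda u: _smoothstep(u) - c, 0.0, 1.0, xtol=1e-14)


#: phase-warp curvature of the swing x-advance; places the overtake of the
#: planted foot at mid single-support (half-way from initial contact to the
#: opposite heel strike) for the default 40% swing fraction
BETA_X = 0.5333333333333333
#: phase-warp curvature of the heel-height arc; the height peak leads the
#: pitch zero-crossing so toe-off precedes mid-swing
BETA_Z = 0.8


@dataclass
class GaitSimParams:
    """Study conditions for one simulated straight-lane walk.

    Healthy defaults echo typical adult gait (stride ~1.25 m every ~1.35 s,
    5 cm heel lift, 25 deg dorsal heel-strike peak, -15 deg plantar push-off
    trough); the lane length is ``n_strides * stride_length_m``.
    """

    n_strides: int = 8
    stride_length_m: float = 1.25
    stride_time_s: float = 1.35
    swing_peak_height_m: float = 0.05
    pitch_max_deg: tuple[float, float] = (25.0, 25.0)  # (left, right)
    pitch_min_deg: tuple[float, float] = (-15.0, -15.0)
    left_step_share: float = 0.5
    stride_time_asym: float = 0.0
    accel_noise_sd: float = 0.0  # g
    gyro_noise_sd: float = 0.0  # deg/s
    accel_bias: float = 0.005  # g, constant on all body axes
    heading_offset_deg: float = 0.0
    euler_noise_sd: float = 0.0  # deg
    seed: int = 0
    sample_rate_hz: float = 200.0
    swing_fraction: float = 0.4
    dip_fraction: float = 0.15
    fall_fraction: float = 0.25
    start_pad_s: float = 1.0
    end_pad_s: float = 1.0
    lane_half_gap_m: float = 0.05  # each foot's lateral offset from the lane line

    def __post_init__(self) -> None:
        if not 0.0 < self.left_step_share < 1.0:
            raise DataError("left_step_share must be in (0, 1)")
        if min(self.stride_length_m, self.stride_time_s, self.sample_rate_hz) <= 0:
            raise DataError("lengths, times and rates must be positive")
        if self.n_strides < 2:
            raise DataError("need at least 2 strides")
        if (self.n_strides - 1) * self.stride_time_asym >= 0.09:
            raise DataError(
                "stride_time_asym too large: the lagging foot's heel strike "
                "would collide with the opposite foot's pre-swing"
            )
        for side in (0, 1):
            mx, mn = self.pitch_max_deg[side], self.pitch_min_deg[side]
            if mx <= 0 or mn >= 0:
                raise DataError("pitch_max must be > 0 and pitch_min < 0")
        # the mid-swing zero crossing must follow the heel-height peak
        mx, mn = self.pitch_max_deg[1], self.pitch_min_deg[1]
        if -mn / (mx - mn) <= _smoothstep(_solve_warp(0.5, BETA_Z)) + 0.02:
            raise DataError(
                "right-foot pitch trough too shallow: mid-swing would precede "
                "the heel-height peak"
            )

    @property
    def lane_length_m(self) -> float:
        return self.n_strides * self.stride_length_m


@dataclass
class SyntheticSession:
    """A simulated session bundled with its generating truth."""

    session: WalkSession
    truth_left: Trajectory
    truth_right: Trajectory
    truth_events: list[GaitCycle]
    truth_stance_left: list[tuple[int, int]]
    truth_stance_right: list[tuple[int, int]]
    params: GaitSimParams
    severity: float | None = None


def _foot_profile(
    t: np.ndarray,
    strikes: np.ndarray,
    positions: np.ndarray,
    tau: float,
    dip: float,
    fall: float,
    pitch_max: float,
    pitch_min: float,
    height: float,
):
    """Closed-form x, z, pitch and their exact derivatives for one foot.

    ``strikes`` are the heel-strike times; ``positions[k]`` is the landing
    position of strike k and ``positions`` has one leading element for the
    initial standing position.  Returns (x, z, pitch, ax, az, pitch_rate).
    """
    x = np.full_like(t, positions[0])
    z = np.zeros_like(t)
    th = np.zeros_like(t)
    ax = np.zeros_like(t)
    az = np.zeros_like(t)
    thd = np.zeros_like(t)

    for k, s in enumerate(strikes):
        x0, x1 = positions[k], positions[k + 1]
        sw0 = s - tau
        # forward advance and heel lift during the swing
        m = (t >= sw0) & (t < s)
        u = (t[m] - sw0) / tau
        w = _warp(u, BETA_X)
        x[m] = x0 + (x1 - x0) * _step7(w)
        ax[m] = (
            (x1 - x0)
            / tau ** 2
            * (
                _step7_d2(w) * _warp_d1(u, BETA_X) ** 2
                + _step7_d1(w) * _warp_d2(u, BETA_X)
            )
        )
        wz = _warp(u, BETA_Z)
        phi = np.pi * wz
        sin, cos = np.sin(phi), np.cos(phi)
        z[m] = height * sin ** 4
        az[m] = (
            height
            / tau ** 2
            * (
                (12.0 * sin ** 2 * cos ** 2 - 4.0 * sin ** 4)
                * (np.pi * _warp_d1(u, BETA_Z)) ** 2
                + 4.0 * sin ** 3 * cos * np.pi * _warp_d2(u, BETA_Z)
            )
        )
        # pitch: plantar dip into the swing, dorsal rise through it
        md = (t >= sw0 - dip) & (t < sw0)
        v = (t[md] - (sw0 - dip)) / dip
        th[md] = pitch_min * _smoothstep(v)
        thd[md] = pitch_min * _smoothstep_d1(v) / dip
        v = (t[m] - sw0) / tau
        th[m] = pitch_min + (pitch_max - pitch_min) * _smoothstep(v)
        thd[m] = (pitch_max - pitch_min) * _smoothstep_d1(v) / tau
        # after landing: foot settles flat
        mf = (t >= s) & (t < s + fall)
        v = (t[mf] - s) / fall
        th[mf] = pitch_max * (1.0 - _smoothstep(v))
        thd[mf] = -pitch_max * _smoothstep_d1(v) / fall
        # planted until the next swing
        x[t >= s] = x1
    return x, z, th, ax, az, thd


def _truth_events(
    params: GaitSimParams,
    sR: np.ndarray,
    sL: np.ndarray,
    tau: float,
    fs: float,
) -> list[GaitCycle]:
    """Exact construction-time locations of the eight states, right primary."""
    share = params.left_step_share
    # in-swing phases of: the overtake of the planted foot, the heel-height
    # peak, and the right pitch zero crossing
    u_ms = _solve_warp_of_step7(1.0 - share, BETA_X)
    u_z = _solve_warp(0.5, BETA_Z)
    mxR, mnR = params.pitch_max_deg[1], params.pitch_min_deg[1]
    u_msw = _solve_smoothstep(-mnR / (mxR - mnR))

    def ev(state: GaitState, time: float) -> GaitEvent:
        return GaitEvent(state, float(time), int(round(time * fs)))

    cycles: list[GaitCycle] = []
    for k in range(len(sR) - 1):
        left_strike = sL[k + 1] if k + 1 < len(sL) else None
        if left_strike is None or not (sR[k] < left_strike < sR[k + 1]):
            continue
        events = [
            ev(GaitState.INITIAL_CONTACT, sR[k]),
            ev(GaitState.LOADING_RESPONSE, left_strike - tau),
            ev(GaitState.MID_STANCE, left_strike - tau + u_ms * tau),
            ev(GaitState.TERMINAL_STANCE, left_strike),
            ev(GaitState.PRE_SWING, sR[k + 1] - tau),
            ev(GaitState.INITIAL_SWING, sR[k + 1] - tau + u_z * tau),
            ev(GaitState.MID_SWING, sR[k + 1] - tau + u_msw * tau),
            ev(GaitState.TERMINAL_SWING, sR[k + 1]),
        ]
        cycles.append(GaitCycle(events=events, primary_foot="right"))
    return cycles


def _solve_warp_of_step7(c: float, beta: float) -> float:
    """u in [0, 1] with _step7(warp(u)) == c."""
    return brentq(lambda u: _step7(_warp(u, beta)) - c, 0.0, 1.0, xtol=1e-14)


def _stance_intervals(
    t_end: float, strikes: np.ndarray, tau: float, dip: float, fall: float, fs: float
) -> list[tuple[int, int]]:
    """Flat-foot (gyro-quiet) intervals as half-open sample-index windows."""
    spans = [(0.0, strikes[0] - tau - dip)]
    for s0, s1 in zip(strikes, strikes[1:]):
        spans.append((s0 + fall, s1 - tau - dip))
    spans.append((strikes[-1] + fall, t_end))
    out = []
    for a, b in spans:
        ia, ib = int(np.ceil(a * fs)), int(np.floor(b * fs)) + 1
        if ib - ia >= 2:
            out.append((ia, ib))
    return out


def simulate_walk(params: GaitSimParams | None = None, **kwargs) -> SyntheticSession:
    """Simulate one two-foot walking session with ground truth.

    Keyword arguments override fields of :class:`GaitSimParams`.
    """
    if params is None:
        params = GaitSimParams(**kwargs)
    elif kwargs:
        params = replace(params, **kwargs)
    p = params
    rng = np.random.default_rng(p.seed)

    T = p.stride_time_s
    L = p.stride_length_m
    n = p.n_strides
    tau = p.swing_fraction * T
    dip = p.dip_fraction * T
    fall = p.fall_fraction * T
    fs = p.sample_rate_hz
    t0 = p.start_pad_s + dip + tau  # first left swing must fit after the pad

    sR = t0 + T * np.arange(1, n + 1)
    sL = t0 + T * (np.arange(1, n + 1) - 0.5) + T * p.stride_time_asym * np.arange(n)
    # closing step: the subject finishes with both feet together on the end
    # line, so the left foot takes a final half-step to the lane end
    sL = np.append(sL, sR[-1] + 0.5 * T)
    posR = np.concatenate([[0.0], L * np.arange(1, n + 1)])
    posL = np.concatenate(
        [[0.0], L * (np.arange(1, n + 1) - 1 + p.left_step_share), [n * L]]
    )

    t_end = sL[-1] + p.end_pad_s
    m = int(np.floor(t_end * fs)) + 1
    t = np.arange(m) / fs

    g = STANDARD_GRAVITY
    feet = {}
    for side, strikes, positions, y_off, idx in (
        ("left", sL, posL, p.lane_half_gap_m, 0),
        ("right", sR, posR, -p.lane_half_gap_m, 1),
    ):
        x, z, th, ax, az, thd = _foot_profile(
            t, strikes, positions, tau, dip, fall,
            p.pitch_max_deg[idx], p.pitch_min_deg[idx], p.swing_peak_height_m,
        )
        y = np.full_like(t, y_off)
        truth = Trajectory(t=t, x=x, y=y, z=z, pitch=th, calibrated=True)

        # specific force in the body frame (x forward, z up, pitch toe-up)
        rad = np.deg2rad(th)
        c, s = np.cos(rad), np.sin(rad)
        fx, fz = ax, az + g
        body = np.column_stack([c * fx + s * fz, np.zeros_like(t), -s * fx + c * fz])
        body /= g
        body += p.accel_bias
        if p.accel_noise_sd > 0:
            body += rng.normal(0.0, p.accel_noise_sd, body.shape)
        gyro = np.column_stack([np.zeros_like(t), -thd, np.zeros_like(t)])
        if p.gyro_noise_sd > 0:
            gyro += rng.normal(0.0, p.gyro_noise_sd, gyro.shape)
        roll = np.zeros_like(t)
        yaw = np.full_like(t, p.heading_offset_deg)
        pitch_rec = th.copy()
        if p.euler_noise_sd > 0:
            roll = roll + rng.normal(0.0, p.euler_noise_sd, t.shape)
            pitch_rec = pitch_rec + rng.normal(0.0, p.euler_noise_sd, t.shape)
            yaw = yaw + rng.normal(0.0, p.euler_noise_sd, t.shape)
        rec = FootRecording(
            side=side,
            six_axis=SixAxisSeries(t=t, gyro=gyro, acc=body),
            euler=EulerSeries(t=t, roll=roll, pitch=pitch_rec, yaw=yaw),
            sample_rate_hz=fs,
        )
        feet[side] = (rec, truth, strikes)

    session = WalkSession(
        left=feet["left"][0],
        right=feet["right"][0],
        lane_length_m=p.lane_length_m,
        subject_id=f"sim-{p.seed}",
    )
    return SyntheticSession(
        session=session,
        truth_left=feet["left"][1],
        truth_right=feet["right"][1],
        truth_events=_truth_events(p, sR, sL, tau, fs),
        truth_stance_left=_stance_intervals(t_end, sL, tau, dip, fall, fs),
        truth_stance_right=_stance_intervals(t_end, sR, tau, dip, fall, fs),
        params=p,
    )


#: severity grid scaling: a severity s in [0, 1] reduces the affected (left)
#: pitch amplitudes by up to 40% and lengthens its stride time by up to 0.8%
PITCH_ASYM_SCALE = 0.4
TIME_ASYM_SCALE = 0.008


def default_severity_grid(n_points: int = 10) -> list[tuple[float, float]]:
    """(pitch asymmetry, stride-time asymmetry) pairs of increasing severity."""
    s = np.linspace(0.0, 1.0, n_points)
    return [(PITCH_ASYM_SCALE * si, TIME_ASYM_SCALE * si) for si in s]


def simulate_cohort(
    n_subjects: int,
    severity_grid: Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
    vary_gait: bool = True,
    **base_kwargs,
) -> list[SyntheticSession]:
    """Simulate a cohort with graded hemiparetic severity.

    Subject ``i`` takes the ``i % len(grid)``-th (pitch asymmetry, stride-time
    asymmetry) pair; the affected side is the left foot.  With ``vary_gait``
    each subject also draws an individual stride length and stride time from
    realistic adult ranges, which varies walking speed across the cohort.
    Fully deterministic for a given ``seed``.
    """
    if n_subjects < 1:
        raise DataError("n_subjects must be >= 1")
    grid = list(severity_grid) if severity_grid is not None else default_severity_grid()
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    sessions = []
    for i, ss in enumerate(streams):
        pitch_asym, time_asym = grid[i % len(grid)]
        rng = np.random.default_rng(ss)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        kwargs = dict(base_kwargs)
        base = GaitSimParams(seed=sub_seed, **kwargs)
        if vary_gait:
            base = replace(
                base,
                n_strides=int(rng.integers(6, 11)),
                stride_length_m=float(rng.uniform(1.0, 1.5)),
                stride_time_s=float(rng.uniform(1.15, 1.55)),
            )
        mxL, mxR = base.pitch_max_deg
        mnL, mnR = base.pitch_min_deg
        params = replace(
            base,
            pitch_max_deg=(mxL * (1.0 - pitch_asym), mxR),
            pitch_min_deg=(mnL * (1.0 - pitch_asym), mnR),
            stride_time_asym=time_asym,
        )
        sess = simulate_walk(params)
        sess.severity = float(i % len(grid))  # position along the severity grid
        sessions.append(sess)
    return sessions


def simulate_repetition_cohort(
    n_subjects: int = 3,
    sessions_per_subject: int = 40,
    n_strides: int = 4,
    jitter: float = 0.02,
    seed: int = 0,
    **base_kwargs,
) -> list[SyntheticSession]:
    """Repeated short walks by a few subjects, as a lab acquisition produces.

    A small panel of subjects (default 3) each walks a short lane (default 4
    strides) many times; every repetition jitters the subject's stride
    length and period by up to ``jitter`` (fractional, default 2%) — the
    natural trial-to-trial variability of one walker.  The panel is
    stratified across the clinical range, from slow short-stride hemiparetic
    gait (~0.7 m strides every ~1.9 s) to brisk healthy gait (~1.45 m every
    ~1.2 s), the deliberate severity spread a gait study recruits; stride
    length and period are anti-correlated across subjects, as observed
    clinically.  This is the structure regression experiments on lab
    recordings actually see: held-out trials come from the same walkers as
    the training trials.
    """
    if n_subjects < 1 or sessions_per_subject < 1:
        raise DataError("need at least one subject and one session")
    root = np.random.default_rng(np.random.SeedSequence(seed))
    L_LO, L_HI = 0.7, 1.45
    T_LO, T_HI = 1.2, 1.9
    sessions: list[SyntheticSession] = []
    for subj in range(n_subjects):
        # stratified position in the severity range, jittered within stratum
        frac = (subj + 0.5 + float(root.uniform(-0.2, 0.2))) / n_subjects
        subj_L = L_LO + frac * (L_HI - L_LO)
        subj_T = T_HI - frac * (T_HI - T_LO)
        for rep in range(sessions_per_subject):
            sub_seed = int(root.integers(0, 2 ** 31 - 1))
            params = GaitSimParams(
                n_strides=n_strides,
                stride_length_m=subj_L * float(root.uniform(1 - jitter, 1 + jitter)),
                stride_time_s=subj_T * float(root.uniform(1 - jitter, 1 + jitter)),
                seed=sub_seed,
                **base_kwargs,
            )
            sess = simulate_walk(params)
            sess.severity = float(subj)
            sessions.append(sess)
    return sessions
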