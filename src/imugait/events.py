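"""Gait-cycle segmentation and spatiotemporal parameters.

A gait cycle runs from one heel strike of the primary foot to the next and
is divided into eight canonical states (initial contact, loading response,
mid-stance, terminal stance, pre-swing, initial swing, mid-swing, terminal
swing).  With a heel-mounted sensor the states are recoverable from two
calibrated foot tracks and their pitch angles alone:

* heel strikes appear as sharp dorsal (toe-up) pitch maxima,
* pre-swing (push-off) as plantar pitch minima,
* mid-stance as the instant the swinging foot overtakes the planted one,
* initial swing as the peak of the swing-phase foot height,
* mid-swing as the pitch returning through zero (foot parallel to floor).

The terminal swing of one cycle is the initial contact of the next, so a
cycle spans seven segments.  Rules are written for the right foot as the
primary (tested) foot and mirrored by swapping the two trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .calibration import StanceWindows
from .errors import EventError
from .trajectory import Trajectory

__all__ = [
    "GaitState",
    "GaitEvent",
    "GaitCycle",
    "FootParameters",
    "GaitParameters",
    "pitch_extrema",
    "detect_gait_states",
    "gait_parameters",
]

logger = logging.getLogger(__name__)


class GaitState(Enum):
    INITIAL_CONTACT = "initial_contact"
    LOADING_RESPONSE = "loading_response"
    MID_STANCE = "mid_stance"
    TERMINAL_STANCE = "terminal_stance"
    PRE_SWING = "pre_swing"
    INITIAL_SWING = "initial_swing"
    MID_SWING = "mid_swing"
    TERMINAL_SWING = "terminal_swing"


#: canonical cyclic order of the eight states
CANONICAL_ORDER: tuple[GaitState, ...] = tuple(GaitState)


@dataclass(frozen=True)
class GaitEvent:
    state: GaitState
    time: float
    sample_index: int


@dataclass
class GaitCycle:
    """The eight annotated states of one gait cycle, in canonical order."""

    events: list[GaitEvent]
    primary_foot: str = "right"

    def __post_init__(self) -> None:
        if len(self.events) != 8:
            raise EventError(f"a gait cycle has 8 events, got {len(self.events)}")
        states = tuple(e.state for e in self.events)
        if states != CANONICAL_ORDER:
            raise EventError(f"events out of canonical order: {states}")
        times = [e.time for e in self.events]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise EventError("event times must be strictly increasing")

    def __getitem__(self, state: GaitState) -> GaitEvent:
        return self.events[list(CANONICAL_ORDER).index(state)]

    @property
    def start(self) -> float:
        return self.events[0].time

    @property
    def end(self) -> float:
        return self.events[-1].time

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class FootParameters:
    """(std, mean) pairs for one foot's five spatiotemporal parameters."""

    gait_cycle_time: tuple[float, float]
    one_step_move_time: tuple[float, float]
    gait_cycle_length: tuple[float, float]
    one_step_move_length: tuple[float, float]
    angle_at_stop: tuple[float, float]


@dataclass
class GaitParameters:
    left: FootParameters
    right: FootParameters

    def to_rows(self) -> list[tuple[str, tuple[float, float], tuple[float, float]]]:
        """Rows in the conventional report layout: (name, left (std, mean), right)."""
        names = [
            "Gait Cycle Time",
            "One Step Move Time",
            "Gait Cycle Length",
            "One Step Move Length",
            "Angle At Stop",
        ]
        fields = [
            "gait_cycle_time",
            "one_step_move_time",
            "gait_cycle_length",
            "one_step_move_length",
            "angle_at_stop",
        ]
        return [
            (n, getattr(self.left, f), getattr(self.right, f))
            for n, f in zip(names, fields)
        ]


def pitch_extrema(
    pitch: np.ndarray,
    sample_rate_hz: float,
    min_prominence_deg: float = 5.0,
    min_separation_s: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local pitch maxima and minima.

    Peaks must stand out by ``min_prominence_deg`` and be at least
    ``min_separation_s`` apart, which suppresses sensor jitter while keeping
    one dorsal peak per heel strike and one plantar trough per push-off.
    """
    pitch = np.asarray(pitch, dtype=float)
    if pitch.size < 3:
        raise EventError("pitch series too short for extremum detection")
    distance = max(1, int(round(min_separation_s * sample_rate_hz)))
    maxima, _ = find_peaks(pitch, prominence=min_prominence_deg, distance=distance)
    minima, _ = find_peaks(-pitch, prominence=min_prominence_deg, distance=distance)
    return maxima, minima


def _interp_crossing(t: np.ndarray, y: np.ndarray, j: int) -> float:
    """Linear-interpolated time where y crosses zero between samples j-1 and j."""
    y0, y1 = y[j - 1], y[j]
    if y1 == y0:
        return float(t[j])
    frac = -y0 / (y1 - y0)
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def detect_gait_states(
    left: Trajectory,
    right: Trajectory,
    primary: str = "right",
    min_prominence_deg: float = 5.0,
    min_separation_s: float = 0.4,
    slow_x_fraction: float = 0.05,
) -> list[GaitCycle]:
    """Segment a two-foot walk into annotated gait cycles.

    For every pair of consecutive primary-foot pitch maxima (heel strikes)
    the six interior events are located by the rules in the module docstring;
    ties are broken toward the earliest candidate, and a cycle in which some
    rule finds no candidate before the next heel strike is dropped (logged at
    warning level).  The loading-response trough must occur while the
    secondary foot's forward position is almost unchanged, fixed as
    ``|dx/dt|`` below ``slow_x_fraction`` of the session's mean forward speed.
    """
    if primary not in ("left", "right"):
        raise EventError(f"primary must be 'left' or 'right', got {primary!r}")
    P, S = (right, left) if primary == "right" else (left, right)
    if len(P) != len(S) or not np.allclose(P.t, S.t, atol=1e-9, rtol=0):
        raise EventError("both trajectories must share one time base")
    t = P.t
    fs = 1.0 / float(np.mean(np.diff(t)))

    p_max, p_min = pitch_extrema(P.pitch, fs, min_prominence_deg, min_separation_s)
    s_max, s_min = pitch_extrema(S.pitch, fs, min_prominence_deg, min_separation_s)
    if len(p_max) < 2:
        logger.warning("fewer than 2 primary-foot heel strikes; no cycles detected")
        return []

    duration = t[-1] - t[0]
    mean_speed = abs(P.x[-1] - P.x[0]) / duration if duration > 0 else 0.0
    slow = slow_x_fraction * mean_speed
    s_rate = np.gradient(S.x, t)
    stride_samples = int(np.median(np.diff(p_max)))

    def settled_rate(idx: int) -> float:
        # residual integration drift puts a slowly varying offset on the
        # velocity; the secondary foot is planted for the ~0.3 strides
        # preceding its plantar trough, so the median velocity over that
        # window is the drift baseline at the candidate instant.  The trough
        # sits on a flat pitch plateau and is localized only to a few
        # samples, so the rate is evaluated as the minimum over that jitter.
        w0 = max(0, idx - int(0.35 * stride_samples))
        w1 = max(w0 + 1, idx - int(0.08 * stride_samples))
        base = np.median(s_rate[w0:w1])
        half = max(2, int(0.02 * stride_samples))
        lo, hi = max(0, idx - half), min(len(s_rate), idx + half + 1)
        return float(np.min(np.abs(s_rate[lo:hi] - base)))

    def first_in(cands: np.ndarray, lo: int, hi: int) -> int | None:
        inside = cands[(cands > lo) & (cands < hi)]
        return int(inside[0]) if inside.size else None

    cycles: list[GaitCycle] = []
    for i0, i1 in zip(p_max, p_max[1:]):
        labels: list[GaitEvent] = [
            GaitEvent(GaitState.INITIAL_CONTACT, float(t[i0]), int(i0))
        ]

        def fail(state: GaitState) -> None:
            logger.warning(
                "cycle at t=%.3f s dropped: no %s candidate", t[i0], state.value
            )

        # loading response: secondary plantar trough while secondary x is slow
        lr = None
        for cand in s_min[(s_min > i0) & (s_min < i1)]:
            if abs(settled_rate(int(cand))) <= max(slow, 1e-12):
                lr = int(cand)
                break
        if lr is None:
            fail(GaitState.LOADING_RESPONSE)
            continue
        labels.append(GaitEvent(GaitState.LOADING_RESPONSE, float(t[lr]), lr))

        # mid-stance: secondary foot's x overtakes the primary foot's
        d = S.x - P.x
        ms = None
        for j in range(lr + 1, i1):
            if d[j] > 0 >= d[j - 1]:
                ms = j
                break
        if ms is None:
            fail(GaitState.MID_STANCE)
            continue
        labels.append(GaitEvent(GaitState.MID_STANCE, _interp_crossing(t, d, ms), ms))

        ts = first_in(s_max, ms, i1)
        if ts is None:
            fail(GaitState.TERMINAL_STANCE)
            continue
        labels.append(GaitEvent(GaitState.TERMINAL_STANCE, float(t[ts]), ts))

        ps = first_in(p_min, ts, i1)
        if ps is None:
            fail(GaitState.PRE_SWING)
            continue
        labels.append(GaitEvent(GaitState.PRE_SWING, float(t[ps]), ps))

        # initial swing: peak of the primary foot's height
        if i1 - ps < 2:
            fail(GaitState.INITIAL_SWING)
            continue
        isw = ps + 1 + int(np.argmax(P.z[ps + 1 : i1]))
        labels.append(GaitEvent(GaitState.INITIAL_SWING, float(t[isw]), isw))

        # mid-swing: pitch returns through zero (foot parallel to the floor)
        msw = None
        for j in range(isw + 1, i1):
            if (P.pitch[j - 1] < 0.0 <= P.pitch[j]) or (
                P.pitch[j - 1] > 0.0 >= P.pitch[j]
            ):
                msw = j
                break
        if msw is None:
            fail(GaitState.MID_SWING)
            continue
        labels.append(
            GaitEvent(GaitState.MID_SWING, _interp_crossing(t, P.pitch, msw), msw)
        )

        labels.append(GaitEvent(GaitState.TERMINAL_SWING, float(t[i1]), int(i1)))
        try:
            cycles.append(GaitCycle(events=labels, primary_foot=primary))
        except EventError as exc:
            logger.warning("cycle at t=%.3f s dropped: %s", t[i0], exc)
    return cycles


def _std_mean(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    std = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return std, float(np.mean(arr))


def _landings(cycles: list[GaitCycle]) -> tuple[np.ndarray, np.ndarray]:
    """Heel-strike times of (primary, secondary) feet across cycles."""
    prim = [c[GaitState.INITIAL_CONTACT].time for c in cycles]
    prim.append(cycles[-1][GaitState.TERMINAL_SWING].time)
    sec = [c[GaitState.TERMINAL_STANCE].time for c in cycles]
    return np.asarray(prim), np.asarray(sec)


def gait_parameters(
    cycles: list[GaitCycle],
    left: Trajectory,
    right: Trajectory,
    stance_left: StanceWindows | None = None,
    stance_right: StanceWindows | None = None,
) -> GaitParameters:
    """Per-foot (std, mean) of the five spatiotemporal gait parameters.

    A landing is a foot's heel strike (the primary foot's initial contact,
    the secondary foot's terminal stance).  Cycle time/length are measured
    between consecutive landings of the same foot, step time/length between
    alternating landings of opposite feet.  The stop angle is the pitch
    averaged over each flat-foot stance window; when stance windows are not
    supplied they are taken as the central 30-42% of each cycle after the
    foot's landing, which falls inside the foot-flat phase.
    """
    if len(cycles) < 2:
        raise EventError("need >= 2 gait cycles to estimate parameters")
    primary = cycles[0].primary_foot
    prim_t, sec_t = _landings(cycles)
    if primary == "right":
        right_t, left_t = prim_t, sec_t
    else:
        left_t, right_t = prim_t, sec_t

    def foot_params(
        foot: Trajectory,
        own_t: np.ndarray,
        other_t: np.ndarray,
        other: Trajectory,
        stance: StanceWindows | None,
    ) -> FootParameters:
        own_x = np.interp(own_t, foot.t, foot.x)
        other_x = np.interp(other_t, other.t, other.x)
        cycle_times = np.diff(own_t)
        cycle_lengths = np.diff(own_x)
        step_times, step_lengths = [], []
        for i, tl in enumerate(own_t):
            prev = np.nonzero(other_t < tl)[0]
            if prev.size:
                j = prev[-1]
                step_times.append(tl - other_t[j])
                step_lengths.append(own_x[i] - other_x[j])
        if stance is not None:
            mids_t = foot.t[stance.midpoints()]
            keep = (mids_t >= own_t[0]) & (mids_t <= own_t[-1])
            angles = [
                float(np.mean(foot.pitch[a:b]))
                for (a, b), k in zip(stance.windows, keep)
                if k
            ]
        else:
            angles = []
            for t0, t1 in zip(own_t, own_t[1:]):
                lo, hi = t0 + 0.30 * (t1 - t0), t0 + 0.42 * (t1 - t0)
                mask = (foot.t >= lo) & (foot.t <= hi)
                if mask.any():
                    angles.append(float(np.mean(foot.pitch[mask])))
        if not step_times or not angles:
            raise EventError("too few landings to derive step parameters")
        return FootParameters(
            gait_cycle_time=_std_mean(cycle_times),
            one_step_move_time=_std_mean(step_times),
            gait_cycle_length=_std_mean(cycle_lengths),
            one_step_move_length=_std_mean(step_lengths),
            angle_at_stop=_std_mean(angles),
        )

    return GaitParameters(
        left=foot_params(left, left_t, right_t, right, stance_left),
        right=foot_params(right, right_t, left_t, left, stance_right),
    )
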