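"""An IMU-derived gait asymmetry/consistency score and its clinical validation.

The score condenses a walk into one non-negative number built from per-step
pitch statistics of the two feet.  For each gait cycle ``i`` the dorsal pitch
peak and plantar pitch trough of each foot are read at the corresponding
cycle events, giving ``P_L,max,i``, ``P_L,min,i``, ``P_R,max,i``,
``P_R,min,i`` and the per-foot stride times ``T1_i`` (left), ``T2_i``
(right).  Writing ``e, f, g, h`` for the per-foot means of the maxima/minima
and ``c, d, k, m`` for their extreme values over steps, the score is

    score = [a + b + (c - e) + (k - g) + (f - d) + (h - m)]
            / min(ArangeL, ArangeR) * (p / q + 1)

with ``a`` and ``b`` the mean left-right differences of the per-step maxima
and minima (asymmetry), ``c - e``/``k - g``/``f - d``/``h - m`` the spread of
each foot's extremes around its mean (consistency), ``ArangeL = e - f`` and
``ArangeR = g - h`` the per-foot pitch ranges normalizing away amplitude,
``p`` the left-right difference of mean stride times and ``q`` their mean.
A perfectly symmetric, perfectly repeatable gait scores 0; larger values
mean more asymmetric or less consistent walking.  By default ``a``, ``b``
and ``p`` are taken as magnitudes so the score is side-agnostic and
non-negative; ``signed=True`` keeps the raw signed differences.

The module also bundles the published 26-subject comparison of this score
against a physician's 31-item observational gait assessment, and the
Pearson/mid-rank-Spearman correlations used to validate it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CorrelationError, ScoreError
from .events import GaitCycle, GaitState
from .trajectory import Trajectory

__all__ = [
    "StepPitchStats",
    "ScoreComponents",
    "step_pitch_stats",
    "score_components",
    "gait_score",
    "session_score",
    "pearson_correlation",
    "spearman_rho",
    "load_clinical_scores",
    "validate_scores",
]


@dataclass
class StepPitchStats:
    """Per-step pitch extrema [deg] and per-foot stride times [s]."""

    p_l_max: np.ndarray
    p_l_min: np.ndarray
    p_r_max: np.ndarray
    p_r_min: np.ndarray
    t1: np.ndarray  # left stride times
    t2: np.ndarray  # right stride times

    def __post_init__(self) -> None:
        for name in ("p_l_max", "p_l_min", "p_r_max", "p_r_min", "t1", "t2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.p_l_max < self.p_l_min) or np.any(self.p_r_max < self.p_r_min):
            raise ScoreError("per-step pitch maximum below minimum")
        if np.any(self.t1 <= 0) or np.any(self.t2 <= 0):
            raise ScoreError("stride times must be positive")


@dataclass
class ScoreComponents:
    """All intermediate symbols of the score formula plus the final score.

    ``h_pitch`` is the mean per-step minimum of the right foot (kept distinct
    from the stance height anchor used by the Z calibration, which shares the
    letter h in the field's notation).
    """

    e: float
    f: float
    g: float
    h_pitch: float
    c: float
    d: float
    k: float
    m: float
    d_a2: np.ndarray
    d_a1: np.ndarray
    a: float
    b: float
    arange_l: float
    arange_r: float
    p: float
    q: float
    score: float | None = None


def step_pitch_stats(
    cycles: list[GaitCycle], left: Trajectory, right: Trajectory
) -> StepPitchStats:
    """Read per-cycle pitch extrema and stride times off the annotated events.

    The primary foot's dorsal peak is its initial contact, its plantar trough
    the pre-swing; the secondary foot's peak is the terminal stance and its
    trough the loading response.  Stride times are intervals between
    consecutive same-foot heel strikes.
    """
    if len(cycles) < 2:
        raise ScoreError(f"need >= 2 gait cycles for step statistics, got {len(cycles)}")
    primary = cycles[0].primary_foot
    prim, sec = (right, left) if primary == "right" else (left, right)

    def pitch_at(traj: Trajectory, time: float) -> float:
        return float(np.interp(time, traj.t, traj.pitch))

    prim_max = [pitch_at(prim, c[GaitState.INITIAL_CONTACT].time) for c in cycles]
    prim_min = [pitch_at(prim, c[GaitState.PRE_SWING].time) for c in cycles]
    sec_max = [pitch_at(sec, c[GaitState.TERMINAL_STANCE].time) for c in cycles]
    sec_min = [pitch_at(sec, c[GaitState.LOADING_RESPONSE].time) for c in cycles]

    prim_strikes = [c[GaitState.INITIAL_CONTACT].time for c in cycles]
    prim_strikes.append(cycles[-1][GaitState.TERMINAL_SWING].time)
    sec_strikes = [c[GaitState.TERMINAL_STANCE].time for c in cycles]
    prim_t = np.diff(prim_strikes)
    sec_t = np.diff(sec_strikes)

    if primary == "right":
        return StepPitchStats(
            p_l_max=sec_max, p_l_min=sec_min, p_r_max=prim_max, p_r_min=prim_min,
            t1=sec_t, t2=prim_t,
        )
    return StepPitchStats(
        p_l_max=prim_max, p_l_min=prim_min, p_r_max=sec_max, p_r_min=sec_min,
        t1=prim_t, t2=sec_t,
    )


def score_components(stats: StepPitchStats, signed: bool = False) -> ScoreComponents:
    """Reduce per-step statistics to the score's symbols.

    Left-right step pairing for the difference terms is by temporal order,
    truncated to the shorter list (with a warning) when the feet yield
    unequal step counts.
    """
    for arr in (stats.p_l_max, stats.p_r_max):
        if arr.size < 2:
            raise ScoreError("need >= 2 steps per foot")
    e = float(np.mean(stats.p_l_max))
    f = float(np.mean(stats.p_l_min))
    g = float(np.mean(stats.p_r_max))
    h_pitch = float(np.mean(stats.p_r_min))
    c = float(np.max(stats.p_l_max))
    d = float(np.min(stats.p_l_min))
    k = float(np.max(stats.p_r_max))
    m = float(np.min(stats.p_r_min))

    n_pairs = min(stats.p_l_max.size, stats.p_r_max.size)
    if stats.p_l_max.size != stats.p_r_max.size:
        warnings.warn(
            f"unequal step counts ({stats.p_l_max.size} left vs "
            f"{stats.p_r_max.size} right); pairing the first {n_pairs}",
            stacklevel=2,
        )
    d_a2 = stats.p_l_max[:n_pairs] - stats.p_r_max[:n_pairs]
    d_a1 = stats.p_l_min[:n_pairs] - stats.p_r_min[:n_pairs]
    a = float(np.mean(d_a2))
    b = float(np.mean(d_a1))
    p = float(np.mean(stats.t1) - np.mean(stats.t2))
    q = float((np.mean(stats.t1) + np.mean(stats.t2)) / 2.0)
    if not signed:
        a, b, p = abs(a), abs(b), abs(p)
    return ScoreComponents(
        e=e, f=f, g=g, h_pitch=h_pitch, c=c, d=d, k=k, m=m,
        d_a2=d_a2, d_a1=d_a1, a=a, b=b,
        arange_l=e - f, arange_r=g - h_pitch, p=p, q=q,
    )


def gait_score(comp: ScoreComponents) -> float:
    """Evaluate the score from its components (also stored on ``comp.score``)."""
    denom = min(comp.arange_l, comp.arange_r)
    if denom <= 0:
        raise ScoreError(
            "degenerate gait: at least one foot shows no pitch range "
            "(min(ArangeL, ArangeR) <= 0)"
        )
    numer = (
        comp.a
        + comp.b
        + (comp.c - comp.e)
        + (comp.k - comp.g)
        + (comp.f - comp.d)
        + (comp.h_pitch - comp.m)
    )
    comp.score = float(numer / denom * (comp.p / comp.q + 1.0))
    return comp.score


def session_score(
    cycles: list[GaitCycle],
    left: Trajectory,
    right: Trajectory,
    signed: bool = False,
) -> tuple[float, ScoreComponents]:
    """Convenience chain: events -> step statistics -> components -> score."""
    comp = score_components(step_pitch_stats(cycles, left, right), signed=signed)
    return gait_score(comp), comp


def _check_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CorrelationError("inputs must be equal-length 1-D sequences")
    if x.size < min_n:
        raise CorrelationError(f"need >= {min_n} pairs, got {x.size}")
    return x, y


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two score lists."""
    x, y = _check_pair(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise CorrelationError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def spearman_rho(x, y) -> float:
    """Mid-rank Spearman correlation (ties get average ranks)."""
    x, y = _check_pair(x, y)
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise CorrelationError("all values tied: rank correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def load_clinical_scores() -> pd.DataFrame:
    """The packaged 26-subject table of physician vs IMU-derived scores.

    Columns: ``subject`` (1-26), ``doctor_score`` (0-62 observational scale,
    0 = normal gait), ``imu_score`` (dimensionless, 0 = symmetric/consistent).
    """
    with resources.files("imugait.data").joinpath("clinical_scores.csv").open() as fh:
        return pd.read_csv(fh)


def validate_scores(table: pd.DataFrame | None = None, alpha: float = 0.01) -> dict:
    """Summary statistics and correlations of doctor vs IMU scores.

    Returns means/SDs of both columns, the Pearson and mid-rank Spearman
    correlations with two-tailed p-values, and significance flags at
    ``alpha`` (default 0.01, two-tailed).
    """
    if table is None:
        table = load_clinical_scores()
    if not {"doctor_score", "imu_score"} <= set(table.columns):
        raise CorrelationError("table must have doctor_score and imu_score columns")
    doc = table["doctor_score"].to_numpy(dtype=float)
    imu = table["imu_score"].to_numpy(dtype=float)
    r = pearson_correlation(doc, imu)
    rho = spearman_rho(doc, imu)
    n = doc.size
    # two-tailed p-values via the t transform of a correlation coefficient
    def pvalue(corr: float) -> float:
        if 1.0 - corr ** 2 <= 0.0:
            return 0.0
        tstat = corr * np.sqrt((n - 2) / (1.0 - corr ** 2))
        return float(2.0 * stats.t.sf(abs(tstat), df=n - 2))

    return {
        "n": int(n),
        "doctor_mean": float(np.mean(doc)),
        "doctor_sd": float(np.std(doc, ddof=1)),
        "imu_mean": float(np.mean(imu)),
        "imu_sd": float(np.std(imu, ddof=1)),
        "pearson_r": r,
        "pearson_p": pvalue(r),
        "pearson_significant": pvalue(r) < alpha,
        "spearman_rho": rho,
        "spearman_p": pvalue(rho),
        "spearman_significant": pvalue(rho) < alpha,
    }
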