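"""End-to-end analysis pipeline: files in, calibrated results and score out.

Chains the stages — read the four-file session, strapdown reconstruction,
three-axis drift calibration, gait-cycle segmentation, spatiotemporal
parameters, asymmetry/consistency score — writing per-stage CSVs and a run
log.  Any stage failure is re-raised with the stage name and the offending
input attached so batch runs are debuggable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import StanceWindows, calibrate, detect_stance_windows
from .errors import ImuGaitError
from .events import GaitCycle, detect_gait_states, gait_parameters
from .io import WalkSession, load_session
from .score import score_components, session_score, step_pitch_stats
from .trajectory import Trajectory, reconstruct

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "analyze_session"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; serialized into every output header."""

    manifest: str = ""
    lane_length_m: float | None = None  # None: take it from the manifest
    y_mode: str = "linear"
    gyro_thresh_dps: float = 20.0
    stance_min_s: float = 0.2
    primary_foot: str = "right"
    min_prominence_deg: float = 5.0
    min_separation_s: float = 0.4
    signed_score: bool = False
    gravity_included: bool = True
    seed: int = 0
    output_dir: str = "results"

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (paths excluded)."""
        payload = {
            k: v for k, v in asdict(self).items()
            if k not in ("manifest", "output_dir")
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    session: WalkSession
    trajectories: dict[str, Trajectory]
    stance: dict[str, StanceWindows]
    cycles: list[GaitCycle]
    parameters: object
    score: float
    components: object


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except ImuGaitError as exc:
        raise type(exc)(f"[stage: {name}] {exc}") from exc


def analyze_session(session: WalkSession, config: PipelineConfig | None = None) -> PipelineResult:
    """Run reconstruction, calibration, segmentation and scoring in memory."""
    cfg = config or PipelineConfig()
    lane = cfg.lane_length_m or session.lane_length_m
    trajs: dict[str, Trajectory] = {}
    stance: dict[str, StanceWindows] = {}
    for side in ("left", "right"):
        rec = getattr(session, side)
        raw = _stage(f"trajectory/{side}", reconstruct, rec,
                     gravity_included=cfg.gravity_included)
        st = _stage(
            f"stance/{side}", detect_stance_windows, rec,
            gyro_thresh_dps=cfg.gyro_thresh_dps, min_duration_s=cfg.stance_min_s,
        )
        calibrated, _ = _stage(
            f"calibration/{side}", calibrate, raw, lane, st, y_mode=cfg.y_mode
        )
        trajs[side], stance[side] = calibrated, st
    cycles = _stage(
        "events", detect_gait_states, trajs["left"], trajs["right"],
        primary=cfg.primary_foot,
        min_prominence_deg=cfg.min_prominence_deg,
        min_separation_s=cfg.min_separation_s,
    )
    params = _stage(
        "parameters", gait_parameters, cycles, trajs["left"], trajs["right"],
        stance["left"], stance["right"],
    )
    score, comp = _stage(
        "score", session_score, cycles, trajs["left"], trajs["right"],
        signed=cfg.signed_score,
    )
    return PipelineResult(
        session=session, trajectories=trajs, stance=stance, cycles=cycles,
        parameters=params, score=score, components=comp,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-to-file run: load the manifest, analyze, write CSVs and a log."""
    session = _stage("read", load_session, config.manifest)
    result = analyze_session(session, config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# imugait {__version__} config={config.config_hash()} seed={config.seed}\n"

    for side, traj in result.trajectories.items():
        path = outdir / f"trajectory_{side}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            pd.DataFrame(
                {"t": traj.t, "x": traj.x, "y": traj.y, "z": traj.z, "pitch": traj.pitch}
            ).to_csv(fh, index=False)

    with open(outdir / "events.csv", "w") as fh:
        fh.write(header)
        rows = [
            {"cycle": i, "state": e.state.value, "time": e.time, "sample": e.sample_index}
            for i, c in enumerate(result.cycles)
            for e in c.events
        ]
        pd.DataFrame(rows).to_csv(fh, index=False)

    with open(outdir / "parameters.csv", "w") as fh:
        fh.write(header)
        rows = [
            {
                "parameter": name,
                "left_std": l[0], "left_mean": l[1],
                "right_std": r[0], "right_mean": r[1],
            }
            for name, l, r in result.parameters.to_rows()
        ]
        pd.DataFrame(rows).to_csv(fh, index=False)

    comp = result.components
    with open(outdir / "score.csv", "w") as fh:
        fh.write(header)
        pd.DataFrame(
            [
                {
                    "score": result.score,
                    "e": comp.e, "f": comp.f, "g": comp.g, "h": comp.h_pitch,
                    "c": comp.c, "d": comp.d, "k": comp.k, "m": comp.m,
                    "a": comp.a, "b": comp.b,
                    "arange_l": comp.arange_l, "arange_r": comp.arange_r,
                    "p": comp.p, "q": comp.q,
                }
            ]
        ).to_csv(fh, index=False)

    with open(outdir / "run.log", "w") as fh:
        fh.write(header)
        fh.write(json.dumps(asdict(config), indent=2, sort_keys=True))
        fh.write(
            f"\ncycles={len(result.cycles)} score={result.score:.6f}\n"
        )
    logger.info("pipeline finished: %d cycles, score %.4f", len(result.cycles), result.score)
    return result
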