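"""Shared fixtures: simulated sessions analyzed once per test run."""

from __future__ import annotations

import numpy as np
import pytest

from imugait.pipeline import PipelineConfig, analyze_session
from imugait.synthetic import GaitSimParams, SyntheticSession, simulate_walk


def run_analysis(sess: SyntheticSession, **cfg_overrides):
    cfg = PipelineConfig(**cfg_overrides)
    return analyze_session(sess.session, cfg)


@pytest.fixture(scope="session")
def clean_walk() -> SyntheticSession:
    """Six noise-free, bias-free strides: the ideal-sensor reference walk."""
    return simulate_walk(
        GaitSimParams(n_strides=6, accel_bias=0.0, seed=42)
    )


@pytest.fixture(scope="session")
def clean_analysis(clean_walk):
    return run_analysis(clean_walk)


@pytest.fixture(scope="session")
def drifting_walk() -> SyntheticSession:
    """Eight strides with accelerometer bias and a heading offset: drift on."""
    return simulate_walk(
        GaitSimParams(
            n_strides=8, accel_bias=0.005, heading_offset_deg=2.0, seed=7
        )
    )


@pytest.fixture(scope="session")
def drifting_analysis(drifting_walk):
    return run_analysis(drifting_walk)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
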