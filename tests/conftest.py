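"""Shared fixtures: programmatic recordings on the programmed 64-slot schedule."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from abpmkit.recording import ABPMRecording, WindowConfig
from abpmkit.simulate import _schedule

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

START = datetime(2022, 6, 1, 8, 0)


def schedule_times(start: datetime = START, density: int = 1) -> pd.DatetimeIndex:
    """The 48 day-slot + 16 night-slot measurement grid over 24 h."""
    return _schedule(WindowConfig(), start, density)


def make_recording(
    sbp, dbp, times: pd.DatetimeIndex | None = None, valid=None, subject_id: str = "T1"
) -> ABPMRecording:
    """Build a recording from systolic/diastolic arrays on the standard grid."""
    sbp = np.asarray(sbp, dtype=float)
    if times is None:
        times = schedule_times()[: len(sbp)]
    dbp = np.broadcast_to(np.asarray(dbp, dtype=float), sbp.shape)
    frame = pd.DataFrame(
        {
            "timestamp": times[: len(sbp)],
            "sbp": sbp,
            "dbp": dbp,
            "valid": True if valid is None else np.asarray(valid, dtype=bool),
        }
    )
    return ABPMRecording(subject_id, frame, WindowConfig())


def constant_recording(sbp: float, dbp: float, **kwargs) -> ABPMRecording:
    """Full 64-reading recording at a constant pressure."""
    times = schedule_times()
    return make_recording(np.full(len(times), sbp), np.full(len(times), dbp), times, **kwargs)


@pytest.fixture
def full_schedule() -> pd.DatetimeIndex:
    return schedule_times()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220601)
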