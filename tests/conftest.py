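"""Shared fixtures.

The planted-event benchmark involves a full segmented EMD of a 60 s
recording, so it is computed once per session and shared between the
detector tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from hfoscan.hfo import DetectorConfig, detect
from hfoscan.synthgen import benchmark_recording

BENCHMARK_SEED = 1


def event_overlaps(e, tv: dict) -> bool:
    return e.start < tv["onset"] + tv["duration"] and tv["onset"] < e.end


def expected_band(tv: dict) -> str:
    if tv["kind"] == "population_spike":
        return "population_spike"
    return "ripple" if tv["centre_frequency"] <= 200 else "fast_ripple"


@pytest.fixture(scope="session")
def benchmark_detection():
    """(recording, ground-truth events, detections) on the standard
    20-event planted benchmark."""
    rec = benchmark_recording(seed=BENCHMARK_SEED)
    events = detect(rec, DetectorConfig())
    return rec, rec.meta["events"], events


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
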