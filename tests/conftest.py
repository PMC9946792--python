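"""Shared fixtures: tiny deterministic sessions, geometries and volumes.

All fixtures are generated programmatically; nothing is read from disk
except what a test itself writes to tmp_path.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from gammamap import (
    DEFAULT_BANDS,
    EffectSpec,
    ElectrodeTable,
    EventTable,
    Recording,
    SessionPlan,
    make_parcellation,
    make_strips,
)

# low-rate band table for fast tests: same structure, top band under the
# Nyquist of a 600 Hz test rate
FAST_BANDS = tuple(b for b in DEFAULT_BANDS if b.hi_hz < 250)


@pytest.fixture
def rng():
    return np.random.default_rng(20230207)


@pytest.fixture
def two_strips() -> ElectrodeTable:
    return make_strips(2, 4, 10.0, placement=[(0.0, 30.0, 30.0), (0.0, -40.0, 30.0)], seed=11)


@pytest.fixture
def toy_labels():
    affine = np.diag([4.0, 4.0, 4.0, 1.0])
    affine[:3, 3] = [-80.0, -80.0, -80.0]
    return make_parcellation(
        (40, 40, 40), affine,
        [("FPN", (0.0, 30.0, 30.0), 25.0), ("DMN", (0.0, -40.0, 30.0), 25.0)],
    )


@pytest.fixture
def short_plan() -> SessionPlan:
    # compressed schedule: enough structure for segmentation and rotation
    return SessionPlan(
        n_trials={"rest": 1, "count": 3, "switch": 3},
        rest_duration_s=(30.0, 40.0),
    )


@pytest.fixture
def simple_events() -> EventTable:
    return EventTable(pd.DataFrame({
        "onset_s": [2.0, 40.0, 70.0, 105.0, 135.0],
        "offset_s": [36.0, 60.0, 100.0, 125.0, 165.0],
        "condition": ["rest", "count", "switch", "count", "switch"],
    }))


@pytest.fixture
def null_effects() -> EffectSpec:
    return EffectSpec()


def write_minimal_edf(path: Path, data: np.ndarray, fs: float, channel_names: list[str]) -> None:
    """Write a minimal valid EDF file (one data record per second,
    16-bit samples) for testing the EDF ingest path."""
    n_ch, n_samp = data.shape
    record_len = int(fs)
    n_records = n_samp // record_len
    assert n_records * record_len == n_samp, "test data must be whole seconds"
    phys_max = max(1.0, float(np.abs(data).max()))
    dig_min, dig_max = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        return s.encode("ascii")[:n].ljust(n)

    hdr = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 + 256 * n_ch), 8), pad("EDF", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(pad(name, 16) for name in channel_names),
        b"".join(pad("ECoG", 80) for _ in channel_names),
        b"".join(pad("uV", 8) for _ in channel_names),
        b"".join(pad(f"{-phys_max:.3f}", 8) for _ in channel_names),
        b"".join(pad(f"{phys_max:.3f}", 8) for _ in channel_names),
        b"".join(pad(str(dig_min), 8) for _ in channel_names),
        b"".join(pad(str(dig_max), 8) for _ in channel_names),
        b"".join(pad("", 80) for _ in channel_names),
        b"".join(pad(str(record_len), 8) for _ in channel_names),
        b"".join(pad("", 32) for _ in channel_names),
    ])
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.clip(np.round(data * scale), dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for r in range(n_records):
            chunk = digital[:, r * record_len:(r + 1) * record_len]
            fh.write(chunk.tobytes())
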