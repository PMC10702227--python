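"""Shared fixtures: desk-scale synthetic sessions.

Generator structure (band tables, dwell distributions, coupling, noise
levels) matches the default study conditions; sessions are shortened and
dwell bounds scaled proportionally so the suite stays desk-scale.
"""

from __future__ import annotations

import numpy as np
import pytest

import somnoephys as se

SHORT_DWELL = {
    "NREM": (10.0, 25.0), "REM": (3.0, 8.0), "Move": (2.0, 10.0),
    "Rest": (2.0, 10.0), "awakening": (0.5, 2.0), "nap": (2.0, 6.0),
}

MEDIUM_DWELL = {
    "NREM": (14.0, 32.0), "REM": (5.0, 12.0), "Move": (2.0, 12.0),
    "Rest": (2.0, 12.0), "awakening": (0.5, 2.5), "nap": (2.0, 6.0),
}


def short_cfg(seed: int = 11, hours: float = 1.5, n_channels: int = 4,
              units: list | None = None, **kw) -> se.SimConfig:
    night = (0.25, min(1.25, hours - 0.25))
    return se.SimConfig(
        session_hours=hours, n_channels=n_channels, lights_off=night,
        state_dwell=dict(SHORT_DWELL), units=units if units is not None else [],
        seed=seed, **kw)


def medium_cfg(seed: int, hours: float = 6.0, n_channels: int = 4,
               units: list | None = None, **kw) -> se.SimConfig:
    # lights-off covers half the session, mirroring the 12 h / 24 h default
    return se.SimConfig(
        session_hours=hours, n_channels=n_channels, lights_off=(1.5, 4.5),
        state_dwell=dict(MEDIUM_DWELL), units=units if units is not None else [],
        seed=seed, **kw)


def two_units() -> list[se.UnitSpec]:
    return [
        se.UnitSpec(unit_type="RS", isi_peak_ms=50.0, channel=0,
                    base_rate={"Move": 8.0, "Rest": 7.0, "REM": 6.0, "NREM": 4.0},
                    locking=[("NREM", "delta", 1.0, np.pi)]),
        se.UnitSpec(unit_type="FS", isi_peak_ms=6.0, refractory_ms=1.0, channel=1,
                    base_rate={"Move": 15.0, "Rest": 12.0, "REM": 10.0, "NREM": 8.0},
                    locking=[("Move", "beta", 0.7, np.pi)]),
    ]


@pytest.fixture(scope="session")
def small_session() -> se.Session:
    """90-minute 4-channel session with two spike units."""
    return se.generate_session(short_cfg(seed=11, units=two_units()))


@pytest.fixture(scope="session")
def small_result(small_session) -> se.ClassificationResult:
    return se.classify_session(small_session,
                               ae_cfg=se.AutoencoderConfig(seed=11), seed=11)


@pytest.fixture(scope="session")
def nrem_lfp_session():
    """Single-state (NREM) 15-minute one-channel session: convenient for
    coupling and phase-locking recovery tests."""
    cfg = short_cfg(seed=7, hours=1.0, n_channels=1)
    n_bins = int(900 / cfg.bin_s)          # 15 minutes
    states = np.full(n_bins, "NREM")
    lfp = se.synthesize_lfp(states, cfg, seed=7)
    return states, lfp, cfg
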