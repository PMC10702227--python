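"""Configuration dataclasses for simulation and classification.

``SimConfig`` pins down the study conditions a synthetic session emulates:
a ~24 h cage recording with a 12 h lights-off period, nocturnal NREM/REM
cycling with occasional brief awakenings, daytime Move/Rest alternation with
short REM naps, state-specific band power, cross-frequency coupling and
head-acceleration statistics, and a handful of single units with
state-dependent rates and spike-field locking.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .bands import BANDS, STATES


class ConfigurationError(ValueError):
    """Raised when a simulation or analysis configuration is inconsistent."""


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: per-state relative oscillation amplitude for each canonical band.  High
#: delta in NREM, theta/alpha in REM, a beta peak while awake (strongest at
#: rest), and modest gamma everywhere.
DEFAULT_BAND_POWERS: dict[str, dict[str, float]] = {
    "Move": {"delta": 0.7, "theta": 0.8, "alpha": 0.7, "beta": 0.8,
             "low_gamma": 0.9, "high_gamma": 0.8},
    "Rest": {"delta": 0.8, "theta": 0.8, "alpha": 1.2, "beta": 1.8,
             "low_gamma": 0.35, "high_gamma": 0.25},
    "REM": {"delta": 0.7, "theta": 2.0, "alpha": 1.4, "beta": 0.8,
            "low_gamma": 0.4, "high_gamma": 0.3},
    "NREM": {"delta": 2.4, "theta": 0.9, "alpha": 0.7, "beta": 0.45,
             "low_gamma": 0.3, "high_gamma": 0.25},
}

#: dwell-time bounds in minutes for the semi-Markov state sequence
DEFAULT_STATE_DWELL: dict[str, tuple[float, float]] = {
    "NREM": (25.0, 95.0),
    "REM": (8.0, 25.0),
    "Move": (2.0, 15.0),
    "Rest": (2.0, 15.0),
    "awakening": (0.5, 3.0),   # brief nocturnal Rest/Move bouts
    "nap": (2.0, 10.0),        # brief daytime REM bouts
}

#: planted state-dependent phase->amplitude coupling
#: (state, low band, high band, modulation depth, preferred phase rad)
DEFAULT_COUPLING: list[tuple[str, str, str, float, float]] = [
    ("NREM", "delta", "high_gamma", 0.8, math.pi),
    ("Move", "delta", "high_gamma", 0.5, math.pi / 2),
    ("REM", "theta", "beta", 0.6, 0.0),
]

#: per-state accelerometer noise std (arbitrary g-like units) and burst rate
#: (bursts per minute).  Movement is dominated by bursts while awake and
#: moving; REM shows occasional head movements; NREM is near-still.
DEFAULT_ACCEL_STD = {"Move": 1.00, "Rest": 0.10, "REM": 0.20, "NREM": 0.05}
DEFAULT_ACCEL_BURST_RATE = {"Move": 12.0, "Rest": 0.5, "REM": 1.5, "NREM": 0.1}


@dataclass
class UnitSpec:
    """One simulated single unit.

    ``base_rate`` maps state name to mean firing rate (Hz), ``locking`` lists
    (state, band, kappa, preferred_phase) von Mises spike-field locking
    entries, and ``isi_peak_ms`` sets the target mode of the ISI histogram
    (<10 ms for fast-spiking, >=10 ms for regular-spiking units).
    """

    unit_type: str = "RS"
    base_rate: dict[str, float] = field(
        default_factory=lambda: {"Move": 8.0, "Rest": 7.0, "REM": 6.0, "NREM": 4.0})
    refractory_ms: float = 1.5
    isi_peak_ms: float = 50.0
    locking: list[tuple[str, str, float, float]] = field(default_factory=list)
    waveform_template: np.ndarray | None = None
    channel: int = 0

    def validate(self) -> None:
        if self.unit_type not in ("RS", "FS"):
            raise ConfigurationError(f"unit_type must be RS or FS, got {self.unit_type!r}")
        if self.refractory_ms <= 0:
            raise ConfigurationError("refractory_ms must be > 0")
        if self.unit_type == "FS" and not self.isi_peak_ms < 10:
            raise ConfigurationError("FS units require isi_peak_ms < 10")
        if self.unit_type == "RS" and not self.isi_peak_ms >= 10:
            raise ConfigurationError("RS units require isi_peak_ms >= 10")
        for state, band, kappa, _ in self.locking:
            if state not in STATES:
                raise ConfigurationError(f"unknown state {state!r} in locking")
            if band not in BANDS:
                raise ConfigurationError(f"unknown band {band!r} in locking")
            if kappa < 0:
                raise ConfigurationError("locking kappa must be >= 0")
        for state, rate in self.base_rate.items():
            if state not in STATES:
                raise ConfigurationError(f"unknown state {state!r} in base_rate")
            if rate < 0:
                raise ConfigurationError("base_rate must be >= 0")


def default_units() -> list[UnitSpec]:
    """Three default units: two RS (one delta-locked in NREM, one theta-locked
    in REM) and one bursty FS unit locked to beta while awake."""
    return [
        UnitSpec(unit_type="RS", isi_peak_ms=50.0, channel=0,
                 base_rate={"Move": 8.0, "Rest": 7.0, "REM": 6.0, "NREM": 4.0},
                 locking=[("NREM", "delta", 1.0, math.pi)]),
        UnitSpec(unit_type="RS", isi_peak_ms=35.0, channel=1,
                 base_rate={"Move": 10.0, "Rest": 8.0, "REM": 9.0, "NREM": 5.0},
                 locking=[("REM", "theta", 0.8, math.pi / 2)]),
        UnitSpec(unit_type="FS", isi_peak_ms=6.0, refractory_ms=1.0, channel=2,
                 base_rate={"Move": 15.0, "Rest": 12.0, "REM": 10.0, "NREM": 8.0},
                 locking=[("Move", "beta", 0.7, math.pi), ("Rest", "beta", 0.7, math.pi)]),
    ]


@dataclass
class SimConfig:
    """Synthetic-session configuration; defaults are the study conditions."""

    session_hours: float = 24.0
    lfp_rate: float = 1000.0
    n_channels: int = 8
    accel_rate: float = 100.0
    bin_s: float = 8.0
    lights_off: tuple[float, float] = (2.0, 14.0)  # hours from session start
    state_dwell: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STATE_DWELL))
    awakening_prob: float = 0.25
    nap_prob: float = 0.08
    band_powers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(b) for s, b in DEFAULT_BAND_POWERS.items()})
    coupling_spec: list[tuple[str, str, str, float, float]] = field(
        default_factory=lambda: list(DEFAULT_COUPLING))
    shared_fraction: float = 0.5
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    carrier_amp_cv: float = 0.25
    #: optional per-band carrier frequency range, e.g. {"beta": (25, 30)} to
    #: place the beta peak as observed per animal; analysis bands unchanged
    carrier_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    accel_std: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ACCEL_STD))
    accel_burst_rate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACCEL_BURST_RATE))
    accel_burst_s: float = 1.0
    units: list[UnitSpec] = field(default_factory=default_units)
    with_eog: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.lfp_rate <= 0 or self.accel_rate <= 0 or self.bin_s <= 0:
            raise ConfigurationError("rates and bin_s must be > 0")
        if self.session_hours <= 0:
            raise ConfigurationError("session_hours must be > 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigurationError("shared_fraction must be in [0, 1]")
        for state, table in self.band_powers.items():
            if state not in STATES:
                raise ConfigurationError(f"unknown state {state!r} in band_powers")
            for band in table:
                if band not in BANDS:
                    raise ConfigurationError(f"unknown band {band!r} in band_powers")
        for state, low, high, depth, _ in self.coupling_spec:
            if state not in STATES:
                raise ConfigurationError(f"unknown state {state!r} in coupling_spec")
            if low not in BANDS or high not in BANDS:
                raise ConfigurationError("coupling_spec bands must be canonical")
            if not 0.0 <= depth <= 1.0:
                raise ConfigurationError("modulation depth must be in [0, 1]")
        for band, (lo, hi) in self.carrier_ranges.items():
            if band not in BANDS:
                raise ConfigurationError(f"unknown band {band!r} in carrier_ranges")
            if not 0 < lo < hi:
                raise ConfigurationError("carrier_ranges edges must be increasing")
        for key, (lo, hi) in self.state_dwell.items():
            if lo > hi:
                raise ConfigurationError(f"dwell bounds inverted for {key!r}")
            if lo <= 0:
                raise ConfigurationError(f"dwell bounds must be positive for {key!r}")
        lo, hi = self.lights_off
        if not 0 <= lo <= hi <= self.session_hours:
            raise ConfigurationError("lights_off must lie within the session")
        for u in self.units:
            u.validate()
            if not 0 <= u.channel < self.n_channels:
                raise ConfigurationError("unit channel out of range")

    @property
    def n_bins(self) -> int:
        return int(self.session_hours * 3600 // self.bin_s)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for u in d["units"]:
            if u["waveform_template"] is not None:
                u["waveform_template"] = np.asarray(u["waveform_template"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        units = []
        for u in d.pop("units", []):
            u = dict(u)
            if u.get("waveform_template") is not None:
                u["waveform_template"] = np.asarray(u["waveform_template"], float)
            u["locking"] = [tuple(x) for x in u.get("locking", [])]
            units.append(UnitSpec(**u))
        d["units"] = units
        d["lights_off"] = tuple(d.get("lights_off", (2.0, 14.0)))
        d["coupling_spec"] = [tuple(x) for x in d.get("coupling_spec", [])]
        d["state_dwell"] = {k: tuple(v) for k, v in d.get(
            "state_dwell", DEFAULT_STATE_DWELL).items()}
        d["carrier_ranges"] = {k: tuple(v) for k, v in d.get(
            "carrier_ranges", {}).items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class AutoencoderConfig:
    """Stacked sparse autoencoder hyperparameters.

    Encoder: 256/128/64-unit layers with batch norm + ReLU feeding a 32-unit
    latent layer; decoder mirrors the encoder.  Loss is MSE plus an L1
    sparsity penalty on encoder activations (weight ``l1_weight``), optimized
    with Adam.
    """

    encoder_widths: Sequence[int] = (256, 128, 64)
    latent_width: int = 32
    l1_weight: float = 1e-5
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 64
    epochs: int = 300
    bottleneck: str = "bn_relu"      # "bn_relu" | "linear"
    seed: int = 0

    def validate(self) -> None:
        widths = tuple(self.encoder_widths)
        if any(w <= 0 for w in widths) or self.latent_width <= 0:
            raise ConfigurationError("layer widths must be positive")
        if any(a <= b for a, b in zip(widths, widths[1:])):
            raise ConfigurationError("encoder widths must decrease")
        if self.l1_weight < 0 or self.learning_rate <= 0:
            raise ConfigurationError("l1_weight >= 0 and learning_rate > 0 required")
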