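"""The ``Session`` container and its HDF5 serialization.

A session holds multichannel LFP, 3-axis head acceleration, optional EOG,
per-stream sample rates, the lights-off interval and — for synthetic
sessions — ground-truth per-bin state labels and per-unit spike times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np


@dataclass
class Session:
    lfp: np.ndarray                    # channels x samples
    accel: np.ndarray                  # 3 x samples
    lfp_rate: float = 1000.0
    accel_rate: float = 100.0
    bin_s: float = 8.0
    lights_off: tuple[float, float] = (0.0, 0.0)   # hours from session start
    eog: np.ndarray | None = None      # 2 x samples, at lfp_rate
    truth_states: np.ndarray | None = None         # per-bin labels (str)
    spike_times: list[np.ndarray] = field(default_factory=list)  # seconds
    unit_meta: list[dict] = field(default_factory=list)
    config_json: str | None = None
    seed: int | None = None

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[1] / self.lfp_rate

    @property
    def n_bins(self) -> int:
        return int(self.duration_s // self.bin_s)

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    def bin_states(self, states: np.ndarray | None = None) -> np.ndarray:
        """Per-bin labels to use (given sequence, else the ground truth)."""
        out = states if states is not None else self.truth_states
        if out is None:
            raise ValueError("no state sequence available")
        return np.asarray(out)

    def state_sample_mask(self, state: str, rate: float | None = None,
                          states: np.ndarray | None = None) -> np.ndarray:
        """Boolean mask at the given rate (default LFP rate) marking samples
        whose 8-s bin is labeled ``state``."""
        rate = self.lfp_rate if rate is None else rate
        labels = self.bin_states(states)
        per_bin = int(round(self.bin_s * rate))
        n = int(self.lfp.shape[1] * rate / self.lfp_rate)
        mask = np.zeros(n, dtype=bool)
        hits = np.flatnonzero(labels == state)
        for b in hits:
            mask[b * per_bin:(b + 1) * per_bin] = True
        return mask

    def validate(self) -> None:
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be channels x samples")
        if self.accel.shape[0] != 3:
            raise ValueError("accel must be 3 x samples")
        dur = self.duration_s
        if abs(self.accel.shape[1] / self.accel_rate - dur) > self.bin_s:
            raise ValueError("accel length inconsistent with LFP duration")
        for st in self.spike_times:
            if len(st) > 1 and not np.all(np.diff(st) > 0):
                raise ValueError("spike times must be strictly increasing")

    # -- HDF5 ---------------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("lfp", data=self.lfp, compression="gzip", compression_opts=1)
            f.create_dataset("accel", data=self.accel, compression="gzip", compression_opts=1)
            if self.eog is not None:
                f.create_dataset("eog", data=self.eog, compression="gzip", compression_opts=1)
            g = f.create_group("spikes")
            for i, st in enumerate(self.spike_times):
                d = g.create_dataset(f"unit{i:03d}", data=np.asarray(st, float))
                if i < len(self.unit_meta):
                    d.attrs["meta"] = json.dumps(self.unit_meta[i])
            if self.truth_states is not None:
                f.create_dataset(
                    "truth", data=np.asarray(self.truth_states, dtype="S8"))
            f.attrs["lfp_rate"] = self.lfp_rate
            f.attrs["accel_rate"] = self.accel_rate
            f.attrs["bin_s"] = self.bin_s
            f.attrs["lights_off"] = list(self.lights_off)
            if self.config_json is not None:
                f.attrs["config_json"] = self.config_json
            if self.seed is not None:
                f.attrs["seed"] = self.seed

    @classmethod
    def load(cls, path) -> "Session":
        with h5py.File(path, "r") as f:
            spike_times, unit_meta = [], []
            if "spikes" in f:
                for name in sorted(f["spikes"]):
                    d = f["spikes"][name]
                    spike_times.append(d[()])
                    unit_meta.append(json.loads(d.attrs.get("meta", "{}")))
            truth = None
            if "truth" in f:
                truth = f["truth"][()].astype(str)
            return cls(
                lfp=f["lfp"][()],
                accel=f["accel"][()],
                eog=f["eog"][()] if "eog" in f else None,
                lfp_rate=float(f.attrs["lfp_rate"]),
                accel_rate=float(f.attrs["accel_rate"]),
                bin_s=float(f.attrs["bin_s"]),
                lights_off=tuple(f.attrs["lights_off"]),
                truth_states=truth,
                spike_times=spike_times,
                unit_meta=unit_meta,
                config_json=f.attrs.get("config_json"),
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )
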