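"""Spike raster container and plain-text I/O.

The :class:`SpikeRaster` is the interchange object between the simulator,
the synthetic generators and every analysis routine: per-neuron sorted
spike times in ms, an excitatory/inhibitory label per neuron, and a
free-form provenance dict (seeds, conductances, weights).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpikeRaster"]


@dataclass
class SpikeRaster:
    """Per-neuron sorted spike times (ms)."""

    spikes: list
    ei_labels: np.ndarray  # True = excitatory
    duration: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        self.ei_labels = np.asarray(self.ei_labels, dtype=bool)
        if len(self.spikes) != self.ei_labels.size:
            raise ValueError("one spike train per ei label required")
        for i, s in enumerate(self.spikes):
            if s.size and (np.any(np.diff(s) <= 0) or s[0] < 0 or s[-1] > self.duration):
                raise ValueError(
                    f"neuron {i}: spike times must be strictly increasing within "
                    f"[0, {self.duration}] ms"
                )

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    @property
    def excitatory(self) -> np.ndarray:
        return np.flatnonzero(self.ei_labels)

    @property
    def inhibitory(self) -> np.ndarray:
        return np.flatnonzero(~self.ei_labels)

    def window(self, window: tuple[float, float] | None = None) -> tuple[float, float]:
        """Resolve an analysis window, defaulting to the full duration."""
        if window is None:
            return (0.0, self.duration)
        lo, hi = window
        if not (0.0 <= lo < hi <= self.duration):
            raise ValueError(f"window {window} outside raster duration {self.duration}")
        return (float(lo), float(hi))

    def spikes_in(self, i: int, window: tuple[float, float] | None = None) -> np.ndarray:
        lo, hi = self.window(window)
        s = self.spikes[i]
        return s[(s >= lo) & (s < hi)]

    def counts(self, window: tuple[float, float] | None = None) -> np.ndarray:
        lo, hi = self.window(window)
        return np.array(
            [np.count_nonzero((s >= lo) & (s < hi)) for s in self.spikes], dtype=int
        )

    # ------------------------------------------------------------------ I/O
    def to_dataframe(self) -> pd.DataFrame:
        nid = np.concatenate(
            [np.full(s.size, i, dtype=int) for i, s in enumerate(self.spikes)]
        ) if self.n_neurons else np.empty(0, dtype=int)
        t = np.concatenate(self.spikes) if self.n_neurons else np.empty(0)
        df = pd.DataFrame({"neuron_id": nid, "spike_time_ms": t})
        return df.sort_values(["neuron_id", "spike_time_ms"], ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        """Write ``neuron_id,spike_time_ms`` CSV plus a ``.meta.json`` sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        payload = {
            "n_neurons": self.n_neurons,
            "duration": self.duration,
            "ei_labels": self.ei_labels.astype(int).tolist(),
            "meta": self.meta,
        }
        sidecar.write_text(json.dumps(payload, indent=1))

    def to_hdf5(self, path: str | Path) -> None:
        """Compact single-file format for batch runs (ragged trains stored
        as one flat array plus per-neuron offsets)."""
        import h5py

        flat = (np.concatenate(self.spikes) if self.n_neurons else np.empty(0))
        offsets = np.cumsum([0] + [s.size for s in self.spikes])
        with h5py.File(path, "w") as f:
            f.create_dataset("spike_times", data=flat)
            f.create_dataset("offsets", data=offsets)
            f.create_dataset("ei_labels", data=self.ei_labels.astype(np.uint8))
            f.attrs["duration"] = self.duration
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "SpikeRaster":
        import h5py

        with h5py.File(path, "r") as f:
            flat = f["spike_times"][:]
            off = f["offsets"][:]
            labels = f["ei_labels"][:].astype(bool)
            duration = float(f.attrs["duration"])
            meta = json.loads(f.attrs["meta"])
        trains = [flat[a:b] for a, b in zip(off[:-1], off[1:])]
        return cls(spikes=trains, ei_labels=labels, duration=duration, meta=meta)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpikeRaster":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        payload = json.loads(sidecar.read_text())
        n = payload["n_neurons"]
        trains = [np.sort(df.loc[df.neuron_id == i, "spike_time_ms"].to_numpy()) for i in range(n)]
        return cls(
            spikes=trains,
            ei_labels=np.asarray(payload["ei_labels"], dtype=bool),
            duration=payload["duration"],
            meta=payload.get("meta", {}),
        )
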