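"""In-memory containers and file I/O for the four input kinds.

* :class:`BehavioralSession` -- one participant's trial table.
* :class:`SpikeDataset` -- trial-aligned spike times for a population of
  single units with region labels.
* :class:`EEGEpochs` -- channels x samples x trials array with sampling
  rate, epoch start and per-trial condition labels.
* :class:`SourceSeries` -- region-of-interest source time series for
  directed-connectivity analysis.

Tabular data travel as CSV; epoch/source arrays as HDF5 with a JSON
sidecar carrying the metadata (sampling rate, channel names, epoch start,
per-trial condition labels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .design import MORPH_GRID

BEHAVIOR_COLUMNS = [
    "participant_id",
    "trial_index",
    "morph_pct",
    "choice",
    "rt_s",
    "confidence",
    "confidence_rt_s",
    "group_label",
]

SPIKE_COLUMNS = ["neuron_id", "region", "trial_id", "spike_time_s", "ambiguity_level"]


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass
class BehavioralSession:
    """Trial table for one participant of the morph judgment task.

    ``trials`` must contain columns ``morph_pct``, ``choice`` (``"fear"``
    or ``"happy"``), ``rt_s``; optionally ``confidence`` (1-3, 1 = very
    sure) and ``confidence_rt_s``.
    """

    participant_id: str
    trials: pd.DataFrame
    group_label: str | None = None

    def __post_init__(self) -> None:
        t = self.trials
        missing = {"morph_pct", "choice", "rt_s"} - set(t.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}")
        off_grid = set(t["morph_pct"].unique()) - set(MORPH_GRID)
        if off_grid:
            raise ValueError(f"morph levels off the grid: {sorted(off_grid)}")
        bad_choice = set(t["choice"].unique()) - {"fear", "happy"}
        if bad_choice:
            raise ValueError(f"choices must be fear/happy, got {sorted(bad_choice)}")
        rt = t["rt_s"].dropna()
        if (rt <= 0).any():
            raise ValueError("reaction times must be positive")
        if "confidence" in t.columns:
            conf = t["confidence"].dropna()
            if not conf.isin([1, 2, 3]).all():
                raise ValueError("confidence ratings must be in {1, 2, 3}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-trial frame with participant metadata columns."""
        out = self.trials.copy()
        out.insert(0, "participant_id", self.participant_id)
        if "trial_index" not in out.columns:
            out.insert(1, "trial_index", np.arange(len(out)))
        out["group_label"] = self.group_label
        for col in BEHAVIOR_COLUMNS:
            if col not in out.columns:
                out[col] = np.nan
        return out[BEHAVIOR_COLUMNS]


def write_behavior_csv(sessions: "list[BehavioralSession]", path: "str | Path") -> None:
    pd.concat([s.to_frame() for s in sessions], ignore_index=True).to_csv(
        path, index=False
    )


def read_behavior_csv(path: "str | Path") -> "list[BehavioralSession]":
    df = pd.read_csv(path)
    sessions = []
    for pid, sub in df.groupby("participant_id", sort=False):
        group = sub["group_label"].dropna().unique()
        sessions.append(
            BehavioralSession(
                participant_id=str(pid),
                trials=sub.drop(columns=["participant_id", "group_label"]).reset_index(
                    drop=True
                ),
                group_label=str(group[0]) if len(group) else None,
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

@dataclass
class NeuronData:
    """Trial-aligned spike times of one unit.

    ``spike_times[i]`` holds the sorted spike times (seconds relative to
    stimulus onset) of trial ``i``; ``levels[i]`` its ambiguity level.
    """

    neuron_id: str
    region: str
    levels: np.ndarray
    spike_times: "list[np.ndarray]"
    duration: float
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.spike_times):
            raise ValueError("levels and spike_times must align per trial")
        self.levels = np.asarray(self.levels, dtype=object)
        self.spike_times = [np.asarray(s, dtype=float) for s in self.spike_times]
        for s in self.spike_times:
            if s.size and np.any(np.diff(s) < 0):
                raise ValueError("spike times must be sorted ascending within trial")
        if self.trial_ids is None:
            self.trial_ids = np.arange(len(self.levels))

    @property
    def n_trials(self) -> int:
        return len(self.levels)

    @property
    def mean_rate(self) -> float:
        """Whole-task mean firing rate in Hz."""
        n_spikes = sum(s.size for s in self.spike_times)
        return n_spikes / (self.n_trials * self.duration)


@dataclass
class SpikeDataset:
    neurons: "list[NeuronData]"

    def __post_init__(self) -> None:
        if not self.neurons:
            raise ValueError("empty spike dataset")

    def __len__(self) -> int:
        return len(self.neurons)

    def __iter__(self):
        return iter(self.neurons)

    def by_region(self, region: str) -> "SpikeDataset":
        picked = [n for n in self.neurons if n.region == region]
        return SpikeDataset(picked)

    def to_frame(self) -> pd.DataFrame:
        """Long spike table; trials without spikes keep a NaN-time row so
        the trial structure survives the round trip."""
        rows = []
        for nrn in self.neurons:
            for tid, level, times in zip(nrn.trial_ids, nrn.levels, nrn.spike_times):
                if times.size == 0:
                    rows.append((nrn.neuron_id, nrn.region, tid, np.nan, level))
                else:
                    rows.extend(
                        (nrn.neuron_id, nrn.region, tid, t, level) for t in times
                    )
        return pd.DataFrame(rows, columns=SPIKE_COLUMNS)

    def write_csv(self, path: "str | Path", duration: float | None = None) -> None:
        df = self.to_frame()
        df.attrs["duration"] = duration or self.neurons[0].duration
        df.to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, duration: float) -> "SpikeDataset":
        neurons = []
        for nid, sub in df.groupby("neuron_id", sort=False):
            region = str(sub["region"].iloc[0])
            levels, times, tids = [], [], []
            for tid, tsub in sub.groupby("trial_id", sort=True):
                levels.append(str(tsub["ambiguity_level"].iloc[0]))
                st = tsub["spike_time_s"].dropna().to_numpy()
                times.append(np.sort(st))
                tids.append(tid)
            neurons.append(
                NeuronData(
                    neuron_id=str(nid),
                    region=region,
                    levels=np.asarray(levels, dtype=object),
                    spike_times=times,
                    duration=duration,
                    trial_ids=np.asarray(tids),
                )
            )
        return cls(neurons)

    @classmethod
    def read_csv(cls, path: "str | Path", duration: float) -> "SpikeDataset":
        return cls.from_frame(pd.read_csv(path), duration)


# ---------------------------------------------------------------------------
# EEG epochs
# ---------------------------------------------------------------------------

def _sidecar_path(path: "str | Path") -> Path:
    return Path(str(path) + ".json")


@dataclass
class EEGEpochs:
    """Trial-segmented multichannel EEG: ``data[channel, sample, trial]``."""

    data: np.ndarray
    fs: float
    channel_names: "list[str]"
    condition: np.ndarray
    t0: float = -0.5
    participant_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x samples x trials")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names does not match data")
        self.condition = np.asarray(self.condition, dtype=object)
        if self.condition.shape[0] != self.data.shape[2]:
            raise ValueError("condition labels do not match trial count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None

    def select(self, condition: str) -> "EEGEpochs":
        mask = self.condition == condition
        if not mask.any():
            raise ValueError(f"no trials with condition {condition!r}")
        return EEGEpochs(
            self.data[:, :, mask],
            self.fs,
            list(self.channel_names),
            self.condition[mask],
            self.t0,
            self.participant_id,
        )

    def crop(self, tmin: float, tmax: float) -> "EEGEpochs":
        """Keep samples with tmin <= t < tmax (half-open)."""
        t = self.times
        mask = (t >= tmin) & (t < tmax)
        if mask.sum() < 2:
            raise ValueError(f"window ({tmin}, {tmax}) leaves fewer than 2 samples")
        return EEGEpochs(
            self.data[:, mask, :],
            self.fs,
            list(self.channel_names),
            self.condition,
            float(t[mask][0]),
            self.participant_id,
        )

    def save(self, path: "str | Path") -> None:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
        meta = {
            "fs": self.fs,
            "t0": self.t0,
            "channel_names": list(self.channel_names),
            "condition": [str(c) for c in self.condition],
            "participant_id": self.participant_id,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: "str | Path") -> "EEGEpochs":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
        try:
            meta = json.loads(sidecar.read_text())
            fs = float(meta["fs"])
            names = list(meta["channel_names"])
            cond = np.asarray(meta["condition"], dtype=object)
            t0 = float(meta["t0"])
        except (KeyError, ValueError, json.JSONDecodeError) as exc:
            raise ValueError(f"corrupt epoch sidecar {sidecar}: {exc}") from exc
        with h5py.File(path, "r") as f:
            data = f["data"][()]
        return cls(data, fs, names, cond, t0, meta.get("participant_id"))


# ---------------------------------------------------------------------------
# source series
# ---------------------------------------------------------------------------

@dataclass
class SourceSeries:
    """ROI source time series: ``data[source, sample]`` or
    ``data[source, sample, trial]``."""

    data: np.ndarray
    fs: float
    source_names: "list[str]"
    window: tuple[float, float] = (0.3, 0.6)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError("data must be sources x samples (x trials)")
        if self.data.shape[0] != len(self.source_names):
            raise ValueError("source_names does not match data")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 sources")
        if not np.isfinite(self.data).all():
            raise ValueError("source series contains missing/non-finite samples")

    @property
    def n_sources(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[2]

    def save(self, path: "str | Path") -> None:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
        meta = {
            "fs": self.fs,
            "source_names": list(self.source_names),
            "window": list(self.window),
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: "str | Path") -> "SourceSeries":
        meta = json.loads(_sidecar_path(path).read_text())
        with h5py.File(path, "r") as f:
            data = f["data"][()]
        return cls(
            data, float(meta["fs"]), list(meta["source_names"]),
            tuple(meta.get("window", (0.3, 0.6))),
        )

    @classmethod
    def from_csv(cls, path: "str | Path", fs: float) -> "SourceSeries":
        """Wide CSV, one column per source, one row per sample."""
        df = pd.read_csv(path)
        return cls(df.to_numpy().T, fs, [str(c) for c in df.columns])
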