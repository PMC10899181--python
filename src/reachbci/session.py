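"""Session container: continuous EEG/EOG recordings, events, and montage.

A recording session is organised in runs. Each run holds a continuous
multichannel EEG block (microvolts), the four EOG channels, a BIDS-style
event table and the sampling rate. Montages carry 3-D electrode positions
(meters, head coordinates) plus per-channel flags used by the processing
pipeline (anterior-frontal row membership, visually-marked bad channels).

On disk a session is a hierarchical HDF5 file with one group per run;
events round-trip through tab-separated tables and montages through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

#: EOG channel ordering: left / right canthi, superior / inferior.
EOG_LABELS = ("EOGL", "EOGR", "EOGU", "EOGD")

#: Anterior-frontal row, excluded after eye-artifact attenuation.
AF_ROW_LABELS = ("AF7", "AF3", "AFz", "AF4", "AF8")

#: Default 60-channel 10-10 layout (5 AF-row + 55 retained channels).
EEG_LABELS_60 = AF_ROW_LABELS + (
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "TP9", "TP10",
)

EVENT_COLUMNS = ("onset", "duration", "trial_type", "value")


@dataclass
class Montage:
    """Electrode labels, 3-D positions and pipeline flags."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), meters
    is_af_row: np.ndarray  # (n_channels,) bool
    is_bad: np.ndarray     # (n_channels,) bool

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.positions = np.asarray(self.positions, dtype=float)
        self.is_af_row = np.asarray(self.is_af_row, dtype=bool)
        self.is_bad = np.asarray(self.is_bad, dtype=bool)
        n = len(self.labels)
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be ({n}, 3), got {self.positions.shape}")
        if self.is_af_row.shape != (n,) or self.is_bad.shape != (n,):
            raise ValueError("flag arrays must have one entry per channel")
        if not np.isfinite(self.positions).all():
            raise ValueError("electrode positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, keep: np.ndarray) -> "Montage":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return Montage(
            labels=tuple(self.labels[i] for i in keep),
            positions=self.positions[keep],
            is_af_row=self.is_af_row[keep],
            is_bad=self.is_bad[keep],
        )

    def nearest_neighbors(self, idx: int, candidates: np.ndarray, k: int = 4) -> np.ndarray:
        """Indices (into the montage) of the ``k`` nearest candidate channels."""
        d = np.linalg.norm(self.positions[candidates] - self.positions[idx], axis=1)
        order = np.argsort(d, kind="stable")[:k]
        return np.asarray(candidates)[order]

    def to_json(self, path: str | Path) -> None:
        rows = [
            {
                "label": lab,
                "x": float(p[0]), "y": float(p[1]), "z": float(p[2]),
                "is_af_row": bool(a), "is_bad": bool(b),
            }
            for lab, p, a, b in zip(self.labels, self.positions, self.is_af_row, self.is_bad)
        ]
        Path(path).write_text(json.dumps(rows, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        rows = json.loads(Path(path).read_text())
        return cls(
            labels=tuple(r["label"] for r in rows),
            positions=np.array([[r["x"], r["y"], r["z"]] for r in rows]),
            is_af_row=np.array([r["is_af_row"] for r in rows]),
            is_bad=np.array([r["is_bad"] for r in rows]),
        )


@lru_cache(maxsize=1)
def _standard_positions() -> dict[str, np.ndarray]:
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pos = mne.channels.make_standard_montage(
            "standard_1005").get_positions()["ch_pos"]
    return {k: np.asarray(v) for k, v in pos.items()}


def default_montage(bad_channels: tuple[str, ...] = ()) -> Montage:
    """The default 60-channel 10-10 montage with the AF row flagged."""
    pos = _standard_positions()
    labels = EEG_LABELS_60
    return Montage(
        labels=labels,
        positions=np.array([pos[lab] for lab in labels]),
        is_af_row=np.array([lab in AF_ROW_LABELS for lab in labels]),
        is_bad=np.array([lab in bad_channels for lab in labels]),
    )


def empty_events() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=(str if c == "trial_type" else float))
                         for c in EVENT_COLUMNS})


@dataclass
class RawSession:
    """One continuous EEG/EOG run with events and montage (the on-disk unit)."""

    eeg: np.ndarray           # (n_channels, n_samples) µV
    eog: np.ndarray           # (4, n_samples) µV
    fs: float                 # Hz
    events: pd.DataFrame      # onset, duration, trial_type, value
    montage: Montage

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.eog = np.asarray(self.eog, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.eeg.ndim != 2 or self.eeg.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"eeg must have {self.montage.n_channels} rows (one per montage label), "
                f"got shape {self.eeg.shape}"
            )
        if self.eog.shape != (len(EOG_LABELS), self.eeg.shape[1]):
            raise ValueError(f"eog must be (4, {self.eeg.shape[1]})")
        if np.isnan(self.eeg).any() or np.isnan(self.eog).any():
            raise ValueError("NaNs in loaded signals")
        dur = self.duration_s
        onsets = np.asarray(self.events["onset"], dtype=float)
        if onsets.size and (onsets.min() < 0 or onsets.max() > dur):
            raise ValueError("event onsets fall outside the recording")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.eeg.shape[1] / self.fs

    def events_of(self, trial_type: str) -> pd.DataFrame:
        return self.events[self.events["trial_type"] == trial_type].reset_index(drop=True)


@dataclass
class Stream:
    """A continuous multichannel block at a given rate (µV)."""

    data: np.ndarray          # (n_channels, n_samples)
    fs: float
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("stream data must be 2-D (channels x samples)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray, fs: float | None = None) -> "Stream":
        return Stream(data=data, fs=self.fs if fs is None else fs, labels=self.labels)


# ---------------------------------------------------------------------------
# events TSV (BIDS-style) and HDF5 session container
# ---------------------------------------------------------------------------

def write_events(path: str | Path, events: pd.DataFrame) -> None:
    events.loc[:, list(EVENT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(ev.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    return ev


def save_session(path: str | Path, runs: dict[str, RawSession]) -> None:
    """Write runs to a hierarchical file, one group per run."""
    with h5py.File(path, "w") as f:
        for name, run in runs.items():
            g = f.create_group(name)
            g.create_dataset("eeg", data=run.eeg, compression="gzip", compression_opts=1)
            g.create_dataset("eog", data=run.eog, compression="gzip", compression_opts=1)
            g.attrs["fs"] = run.fs
            ev = run.events
            g.create_dataset("event_onset", data=np.asarray(ev["onset"], dtype=float))
            g.create_dataset("event_duration", data=np.asarray(ev["duration"], dtype=float))
            g.create_dataset(
                "event_trial_type",
                data=np.asarray(ev["trial_type"], dtype=object),
                dtype=h5py.string_dtype(),
            )
            g.create_dataset("event_value", data=np.asarray(ev["value"], dtype=float))
            m = run.montage
            g.attrs["montage_labels"] = json.dumps(list(m.labels))
            g.create_dataset("montage_positions", data=m.positions)
            g.create_dataset("montage_is_af_row", data=m.is_af_row)
            g.create_dataset("montage_is_bad", data=m.is_bad)


def load_session(path: str | Path) -> dict[str, RawSession]:
    runs: dict[str, RawSession] = {}
    with h5py.File(path, "r") as f:
        for name in f:
            g = f[name]
            montage = Montage(
                labels=tuple(json.loads(g.attrs["montage_labels"])),
                positions=g["montage_positions"][()],
                is_af_row=g["montage_is_af_row"][()].astype(bool),
                is_bad=g["montage_is_bad"][()].astype(bool),
            )
            events = pd.DataFrame(
                {
                    "onset": g["event_onset"][()],
                    "duration": g["event_duration"][()],
                    "trial_type": [s.decode() if isinstance(s, bytes) else s
                                   for s in g["event_trial_type"][()]],
                    "value": g["event_value"][()],
                }
            )
            runs[name] = RawSession(
                eeg=g["eeg"][()], eog=g["eog"][()], fs=float(g.attrs["fs"]),
                events=events, montage=montage,
            )
    return runs
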