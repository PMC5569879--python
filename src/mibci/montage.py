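"""Montage bookkeeping, recording ingestion and epoching.

The recording setup is a 14-channel sensorimotor EEG montage plus one vertical
EOG (VEOG) channel: six left-hemisphere electrodes (T7, P3, P7, CP3, FC3, C3),
their six right-hemisphere mirrors (T8, P4, P8, CP4, FC4, C4) and two midline
electrodes (FZ, CZ), sampled at 256 Hz. The mirror pairing is what the wCCA
artifact remover exploits: blinks project onto both hemispheres and onto VEOG,
while sensorimotor rhythms do not share that cross-hemisphere structure.

Two on-disk formats are supported: EDF (read, via :mod:`mne`) and a delimited
text dialect (read/write): one header row of channel names, one tab-separated
column per channel, values in microvolt, plus a ``<stem>.events.tsv`` sidecar
of ``onset_s<TAB>label`` rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical class order used everywhere (tables, confusion matrices,
#: tie-breaks): resting state, right foot, left hand, right shoulder.
CLASS_ORDER: tuple[str, ...] = ("R", "RF", "LH", "RS")


class MontageMismatchError(ValueError):
    """A file's channel labels cannot be resolved against the montage."""


class TruncatedEpochError(ValueError):
    """An epoch window extends past the end of the recording."""


@dataclass(frozen=True)
class Montage:
    """Electrode layout with the left/right mirror pairing.

    ``left_group[i]`` and ``right_group[i]`` are homologous electrodes; the
    two midline channels are denoised separately (plain wavelet thresholding)
    because they have no mirror partner.
    """

    left_group: tuple[str, ...] = ("T7", "P3", "P7", "CP3", "FC3", "C3")
    right_group: tuple[str, ...] = ("T8", "P4", "P8", "CP4", "FC4", "C4")
    central_group: tuple[str, ...] = ("FZ", "CZ")
    veog_channel: str = "VEOG"
    fs: float = 256.0
    eeg_channels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.eeg_channels:
            object.__setattr__(
                self,
                "eeg_channels",
                tuple(self.left_group) + tuple(self.right_group) + tuple(self.central_group),
            )
        if len(self.left_group) != len(self.right_group):
            raise ValueError("left/right mirror pairing must be a bijection")
        groups = set(self.left_group) | set(self.right_group) | set(self.central_group)
        if set(self.eeg_channels) != groups or len(self.eeg_channels) != (
            len(self.left_group) + len(self.right_group) + len(self.central_group)
        ):
            raise ValueError("left/right/central groups must partition eeg_channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_eeg(self) -> int:
        return len(self.eeg_channels)

    @property
    def all_channels(self) -> tuple[str, ...]:
        """EEG channels in montage order, VEOG last."""
        return self.eeg_channels + (self.veog_channel,)

    def index(self, name: str) -> int:
        """Row index of an EEG channel in montage order (case-insensitive)."""
        lowered = [c.lower() for c in self.eeg_channels]
        return lowered.index(name.lower())

    def group_indices(self, group: Sequence[str]) -> list[int]:
        return [self.index(name) for name in group]


def default_montage(fs: float = 256.0) -> Montage:
    """The standard 14-channel + VEOG motor-imagery montage at 256 Hz."""
    return Montage(fs=fs)


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording with trial-onset events.

    ``data`` rows follow ``montage.all_channels`` (EEG in montage order, VEOG
    last), in microvolt. ``events`` is a list of ``(onset_sample, label)``
    with strictly increasing onsets.
    """

    data: np.ndarray
    montage: Montage
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.montage.n_eeg + 1:
            raise ValueError(
                f"expected {self.montage.n_eeg + 1} rows (EEG + VEOG), got {self.data.shape}"
            )
        onsets = [int(o) for o, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.data.shape[1]):
            raise ValueError("event onsets must lie within the recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def eeg(self) -> np.ndarray:
        return self.data[: self.montage.n_eeg]

    @property
    def veog(self) -> np.ndarray:
        return self.data[self.montage.n_eeg]


@dataclass
class Trial:
    """One epoched trial: ``data`` is N_eeg x T (microvolt), ``veog`` 1 x T."""

    data: np.ndarray
    veog: np.ndarray
    label: str
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.veog = np.asarray(self.veog, dtype=float).ravel()
        if self.data.ndim != 2 or self.data.shape[1] == 0:
            raise ValueError("trial data must be a non-empty N x T matrix")
        if self.veog.shape[0] != self.data.shape[1]:
            raise ValueError("VEOG length must match trial length")
        if not (np.all(np.isfinite(self.data)) and np.all(np.isfinite(self.veog))):
            raise ValueError("trial contains non-finite values")
        if self.label not in CLASS_ORDER:
            raise ValueError(f"label must be one of {CLASS_ORDER}, got {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "Trial":
        return Trial(data=data, veog=self.veog.copy(), label=self.label, fs=self.fs)


@dataclass
class Dataset:
    """A subject's labeled trials with per-trial train/test split tags."""

    subject_id: str
    trials: list[Trial]
    splits: list[str]

    def __post_init__(self) -> None:
        if len(self.trials) != len(self.splits):
            raise ValueError("one split tag per trial required")
        bad = set(self.splits) - {"train", "test"}
        if bad:
            raise ValueError(f"unknown split tags: {sorted(bad)}")

    def subset(self, split: str) -> list[Trial]:
        return [t for t, s in zip(self.trials, self.splits) if s == split]

    @property
    def train_trials(self) -> list[Trial]:
        return self.subset("train")

    @property
    def test_trials(self) -> list[Trial]:
        return self.subset("test")

    def labels(self, split: str | None = None) -> list[str]:
        if split is None:
            return [t.label for t in self.trials]
        return [t.label for t in self.subset(split)]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def events_path(path: str | Path) -> Path:
    """Sidecar path for the events table of a delimited recording."""
    p = Path(path)
    return p.with_name(p.stem + ".events.tsv")


def write_delimited(recording: ContinuousRecording, path: str | Path) -> None:
    """Write a recording in the delimited dialect (+ events sidecar)."""
    p = Path(path)
    header = "\t".join(recording.montage.all_channels)
    np.savetxt(p, recording.data.T, fmt="%.17g", delimiter="\t", header=header, comments="")
    fs = recording.montage.fs
    with open(events_path(p), "w", encoding="utf-8") as fh:
        fh.write("onset_s\tlabel\n")
        for onset, label in recording.events:
            fh.write(f"{onset / fs:.17g}\t{label}\n")


def _read_events_sidecar(path: Path, fs: float) -> list[tuple[int, str]]:
    if not path.exists():
        return []
    table = pd.read_csv(path, sep="\t")
    return [(int(round(float(r.onset_s) * fs)), str(r.label)) for r in table.itertuples()]


def load_recording(
    path: str | Path,
    fmt: str = "delimited",
    montage: Montage | None = None,
) -> ContinuousRecording:
    """Load a continuous recording, reordering rows to montage order.

    Parameters
    ----------
    path : path to the data file (EDF or delimited text).
    fmt : ``"edf"`` or ``"delimited"``.
    montage : channel layout to resolve labels against (case-insensitive);
        defaults to :func:`default_montage`.

    Raises
    ------
    MontageMismatchError
        If any montage channel is absent from the file.
    """
    montage = montage or default_montage()
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if fmt == "delimited":
        frame = pd.read_csv(p, sep="\t")
        lookup = {c.lower(): c for c in frame.columns}
        missing = [ch for ch in montage.all_channels if ch.lower() not in lookup]
        if missing:
            raise MontageMismatchError(f"montage mismatch: missing channels {missing}")
        data = frame[[lookup[ch.lower()] for ch in montage.all_channels]].to_numpy().T
        events = _read_events_sidecar(events_path(p), montage.fs)
        return ContinuousRecording(data=data, montage=montage, events=events)
    if fmt == "edf":
        return _load_edf(p, montage)
    raise ValueError(f"unknown format {fmt!r}")


def _load_edf(path: Path, montage: Montage) -> ContinuousRecording:
    import mne  # deferred: mne import is slow and only needed for EDF

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if abs(fs - montage.fs) > 1e-6:
        raise ValueError(f"EDF sampling rate {fs} Hz does not match montage ({montage.fs} Hz)")
    lookup = {c.lower(): c for c in raw.ch_names}
    missing = [ch for ch in montage.all_channels if ch.lower() not in lookup]
    if missing:
        raise MontageMismatchError(f"montage mismatch: missing channels {missing}")
    picks = [lookup[ch.lower()] for ch in montage.all_channels]
    data = raw.get_data(picks=picks) * 1e6  # mne returns SI volt; convert to microvolt
    events: list[tuple[int, str]] = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        events.append((int(round(float(onset) * fs)), str(desc)))
    return ContinuousRecording(data=data, montage=montage, events=events)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------


def epoch_trials(
    recording: ContinuousRecording,
    window: tuple[float, float] = (2.0, 7.0),
    on_truncated: str = "raise",
) -> list[Trial]:
    """Cut one trial per event from a continuous recording.

    ``window`` is in seconds relative to the trial onset, half-open
    ``[start, end)`` with 0-based sample indexing: the onset sample is
    included, the end sample excluded, so ``T = round((end - start) * fs)``.

    ``on_truncated`` controls events whose window runs past the record end:
    ``"raise"`` (default) raises :class:`TruncatedEpochError`, ``"skip"``
    drops the event with a warning.
    """
    start, end = window
    fs = recording.montage.fs
    if end <= start:
        raise ValueError("empty epoch window")
    if not recording.events:
        raise ValueError("recording has no events to epoch")
    n = int(round((end - start) * fs))
    n_eeg = recording.montage.n_eeg
    trials: list[Trial] = []
    for onset, label in recording.events:
        s0 = onset + int(round(start * fs))
        s1 = s0 + n
        if s0 < 0 or s1 > recording.n_samples:
            msg = f"truncated epoch for event at sample {onset} (window [{s0}, {s1}))"
            if on_truncated == "skip":
                warnings.warn(msg, stacklevel=2)
                continue
            raise TruncatedEpochError(msg)
        trials.append(
            Trial(
                data=recording.data[:n_eeg, s0:s1].copy(),
                veog=recording.data[n_eeg, s0:s1].copy(),
                label=label,
                fs=fs,
            )
        )
    return trials


def assign_splits(labels: Iterable[str], train_per_class: int) -> list[str]:
    """Tag the first ``train_per_class`` occurrences of each label as train."""
    seen: dict[str, int] = {}
    tags = []
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
        tags.append("train" if seen[lab] <= train_per_class else "test")
    return tags


__all__ = [
    "CLASS_ORDER",
    "Montage",
    "ContinuousRecording",
    "Trial",
    "Dataset",
    "MontageMismatchError",
    "TruncatedEpochError",
    "default_montage",
    "load_recording",
    "write_delimited",
    "events_path",
    "epoch_trials",
    "assign_splits",
]
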