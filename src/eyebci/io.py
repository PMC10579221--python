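"""Containers and file I/O for multichannel EEG recordings and event logs.

A :class:`Recording` holds a microvolt-scaled sample matrix with named
channels on a common sampling grid; :func:`batch_stream` cuts it into the
fixed-width windows the online detector consumes.  Recordings travel as CSV
(header row = channel names, one row per sample; the sampling rate is
supplied by the caller since CSV carries no metadata) or EDF.  Event logs
travel as JSON or CSV.

Conventions: sample indices are 0-based, times are seconds, event intervals
are half-open ``[onset, end)``, and the first sample of a stream sits at
virtual time ``t0`` (0 by default).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_LABELS",
    "Recording",
    "Batch",
    "EventRecord",
    "ChannelMissingError",
    "RecordingFormatError",
    "normalize_channel_label",
    "read_recording",
    "write_recording",
    "select_channels",
    "batch_stream",
    "read_events",
    "write_events",
]

#: Closed set of event labels used throughout the pipeline.
EVENT_LABELS = ("blink", "look_left", "look_right")

#: Channels the detection algorithm runs on, in canonical order.
DETECTION_CHANNELS = ("Fp1", "F7", "F8")


class ChannelMissingError(KeyError):
    """A requested channel is not present in the recording."""


class RecordingFormatError(ValueError):
    """A recording file could not be parsed."""


@dataclass(frozen=True)
class Recording:
    """Multichannel EEG time series in microvolts.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (the study acquires at 500 Hz).
    channels : tuple of str
        Ordered, unique channel names (10/20 labels).
    data : ndarray, shape (n_samples, n_channels)
        Amplitudes in microvolts; one column per channel.
    t0 : float
        Virtual time of the first sample, seconds.
    """

    fs: float
    channels: tuple[str, ...]
    data: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D (samples x channels) array")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"channel names must be unique: {self.channels}")
        if data.shape[1] != len(self.channels):
            raise ValueError(
                f"data has {data.shape[1]} columns but {len(self.channels)} "
                "channel names were given"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise ChannelMissingError(
                f"channel {name!r} missing; available: {list(self.channels)}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return the single-channel series for ``name``."""
        return self.data[:, self.channel_index(name)]


@dataclass(frozen=True)
class Batch:
    """Fixed-width window of the sample stream.

    ``start_time`` is virtual time: for contiguous non-overlapping batches it
    equals ``t0 + index * width / fs``.
    """

    data: np.ndarray
    start_time: float
    index: int

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError("batch data must be 2-D (samples x channels)")
        object.__setattr__(self, "data", data)

    @property
    def width(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True, order=True)
class EventRecord:
    """A labeled artifact interval ``[onset, end)`` in seconds."""

    onset: float
    end: float
    label: str = field(compare=False)
    source: str = field(default="detected", compare=False)

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise ValueError(f"label must be one of {EVENT_LABELS}, got {self.label!r}")
        if self.source not in ("detected", "ground_truth"):
            raise ValueError(f"source must be detected|ground_truth, got {self.source!r}")
        if not self.onset <= self.end:
            raise ValueError(f"onset {self.onset} must not exceed end {self.end}")


_TOKEN_RE = re.compile(r"^[A-Za-z]{1,3}[0-9]{0,2}$")


def normalize_channel_label(label: str) -> str:
    """Map a vendor EDF channel label to its bare 10/20 token.

    ``"EEG Fp1-REF"`` -> ``"Fp1"``; matching is case-insensitive on the
    trailing token, reference suffixes after ``-`` are dropped, and the
    canonical capitalisation (``Fp1``, ``F7``, ``Cz``) is restored.  Labels
    that do not look like 10/20 tokens are returned stripped but unchanged.
    """
    token = label.strip().split()[-1] if label.strip() else label
    token = token.split("-")[0]
    if not _TOKEN_RE.match(token):
        return label.strip()
    up = token.upper()
    if up.startswith("FP"):
        up = "Fp" + up[2:]
    if up.endswith("Z"):
        up = up[:-1] + "z"
    return up


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
) -> Recording:
    """Read a recording from CSV or EDF.

    CSV has no sampling-rate metadata, so ``fs`` is required for CSV input.
    EDF channel labels are normalised by their trailing 10/20 token.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        if fs is None:
            raise RecordingFormatError(
                f"{path}: CSV carries no sampling-rate metadata; pass fs explicitly"
            )
        try:
            frame = pd.read_csv(path, header=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise RecordingFormatError(f"{path}: malformed CSV header or body: {exc}") from exc
        if frame.shape[1] == 0:
            raise RecordingFormatError(f"{path}: no channel columns found in header")
        bad = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
        if bad:
            raise RecordingFormatError(
                f"{path}: non-numeric sample values in column(s) {bad}"
            )
        return Recording(fs=fs, channels=tuple(map(str, frame.columns)), data=frame.to_numpy())
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        channels = tuple(normalize_channel_label(ch) for ch in raw.ch_names)
        data = raw.get_data().T * 1e6  # volts -> microvolts
        return Recording(fs=float(raw.info["sfreq"]), channels=channels, data=data)
    raise RecordingFormatError(f"unknown recording format {format!r}")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV (header = channel names, one row per sample)."""
    frame = pd.DataFrame(rec.data, columns=list(rec.channels))
    frame.to_csv(path, index=False)


def select_channels(rec: Recording, names: Sequence[str]) -> Recording:
    """Restrict a recording to ``names``, in the requested order."""
    idx = [rec.channel_index(n) for n in names]
    return replace(rec, channels=tuple(names), data=rec.data[:, idx])


def batch_stream(rec: Recording, width: int = 100) -> Iterator[Batch]:
    """Cut a recording into contiguous non-overlapping batches.

    The final partial batch is emitted with its true length so that the
    concatenation of all batch data reproduces the recording exactly.
    """
    if width < 1:
        raise ValueError(f"batch width must be >= 1, got {width}")
    for index, start in enumerate(range(0, rec.n_samples, width)):
        yield Batch(
            data=rec.data[start : start + width],
            start_time=rec.t0 + start / rec.fs,
            index=index,
        )


def _event_rows(events: Sequence[EventRecord]) -> list[dict]:
    ordered = sorted(events, key=lambda e: (e.onset, e.end))
    return [
        {"label": e.label, "onset": e.onset, "end": e.end, "source": e.source}
        for e in ordered
    ]


def write_events(events: Sequence[EventRecord], path: str | Path) -> None:
    """Write events sorted by onset as JSON (``.json``) or CSV (``.csv``)."""
    path = Path(path)
    rows = _event_rows(events)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["label", "onset", "end", "source"])
            writer.writeheader()
            writer.writerows(rows)
    else:
        with open(path, "w") as fh:
            json.dump({"events": rows}, fh, indent=2)
            fh.write("\n")


def read_events(path: str | Path) -> list[EventRecord]:
    """Read an event file written by :func:`write_events`."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    else:
        with open(path) as fh:
            rows = json.load(fh)["events"]
    return [
        EventRecord(
            label=row["label"],
            onset=float(row["onset"]),
            end=float(row["end"]),
            source=row.get("source", "detected"),
        )
        for row in rows
    ]
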