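"""Threshold calibration from labeled trials.

The detector compares the filtered signal against fixed microvolt
thresholds.  They are calibrated from labeled trials by the rule

    THR = M - alpha * SD

where M and SD are the mean and (population) standard deviation of the
per-event peak amplitudes and alpha trades sensitivity against false
alarms.  With the study's blink statistics (M = 167 uV, SD = 22 uV) and
alpha = 0.5 this yields the 156 uV strong-blink threshold; a secondary
80 uV threshold arms detection of weak blinks.  Lateral thresholds are
calibrated per channel and per polarity (positive peaks and negative
valleys separately on F7 and F8).

The published defaults are exposed by :func:`default_thresholds`:

========  ==========  =====  =====
Channel   Event       Upper  Lower
========  ==========  =====  =====
Fp1       blink       156    80
F7        look_left   20     -20
F7        look_right  20     -20
F8        look_left   30     -20
F8        look_right  20     -30
========  ==========  =====  =====
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import EventRecord, Recording

__all__ = [
    "CalibStats",
    "LateralBand",
    "ThresholdSet",
    "DistributionSummary",
    "extract_event_peaks",
    "peak_stats",
    "compute_threshold",
    "distribution_summary",
    "default_thresholds",
]


@dataclass(frozen=True)
class CalibStats:
    """Peak-amplitude statistics and the threshold they imply."""

    M: float
    SD: float
    N: int
    alpha: float
    THR: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.SD < 0:
            raise ValueError("SD must be non-negative")


@dataclass(frozen=True)
class LateralBand:
    """Upper/lower amplitude thresholds (uV) for one channel and event."""

    upper: float
    lower: float

    def __post_init__(self) -> None:
        if not self.upper > 0 > self.lower:
            raise ValueError(
                f"lateral thresholds must satisfy upper > 0 > lower, got "
                f"({self.upper}, {self.lower})"
            )


@dataclass(frozen=True)
class ThresholdSet:
    """Per-channel, per-event detection thresholds in microvolts."""

    blink_strong: float = 156.0
    blink_weak: float = 80.0
    f7_look_left: LateralBand = field(default_factory=lambda: LateralBand(20.0, -20.0))
    f7_look_right: LateralBand = field(default_factory=lambda: LateralBand(20.0, -20.0))
    f8_look_left: LateralBand = field(default_factory=lambda: LateralBand(30.0, -20.0))
    f8_look_right: LateralBand = field(default_factory=lambda: LateralBand(20.0, -30.0))

    def __post_init__(self) -> None:
        if not self.blink_weak < self.blink_strong:
            raise ValueError(
                f"blink_weak ({self.blink_weak}) must be below "
                f"blink_strong ({self.blink_strong})"
            )

    def lateral(self, channel: str, event: str) -> LateralBand:
        """Thresholds for ``channel`` in {F7, F8} and ``event`` in {look_left, look_right}."""
        try:
            return getattr(self, f"{channel.lower()}_{event}")
        except AttributeError:
            raise KeyError(f"no lateral thresholds for ({channel!r}, {event!r})") from None

    def to_dict(self) -> dict:
        return {
            "Fp1": {"blink": {"upper": self.blink_strong, "weak": self.blink_weak}},
            "F7": {
                "look_left": {"upper": self.f7_look_left.upper, "lower": self.f7_look_left.lower},
                "look_right": {"upper": self.f7_look_right.upper, "lower": self.f7_look_right.lower},
            },
            "F8": {
                "look_left": {"upper": self.f8_look_left.upper, "lower": self.f8_look_left.lower},
                "look_right": {"upper": self.f8_look_right.upper, "lower": self.f8_look_right.lower},
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        return cls(
            blink_strong=float(d["Fp1"]["blink"]["upper"]),
            blink_weak=float(d["Fp1"]["blink"]["weak"]),
            f7_look_left=LateralBand(**{k: float(v) for k, v in d["F7"]["look_left"].items()}),
            f7_look_right=LateralBand(**{k: float(v) for k, v in d["F7"]["look_right"].items()}),
            f8_look_left=LateralBand(**{k: float(v) for k, v in d["F8"]["look_left"].items()}),
            f8_look_right=LateralBand(**{k: float(v) for k, v in d["F8"]["look_right"].items()}),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class DistributionSummary:
    """Quartiles, Tukey fences and outliers of a peak-amplitude sample."""

    q1: float
    q2: float
    q3: float
    iqr: float
    outliers: tuple[float, ...]
    first_percentile: float


def extract_event_peaks(
    rec: Recording,
    labels: Sequence[EventRecord],
    channel: str,
    polarity: str = "positive",
) -> np.ndarray:
    """One extremum per labeled event on ``channel``.

    For ``positive`` polarity the maximum sample within ``[onset, end)`` is
    taken, for ``negative`` the minimum.  Label windows must lie inside the
    recording.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError(f"polarity must be positive|negative, got {polarity!r}")
    series = rec.channel(channel)
    peaks = []
    for ev in labels:
        start = int(round((ev.onset - rec.t0) * rec.fs))
        stop = int(round((ev.end - rec.t0) * rec.fs))
        if start < 0 or stop > rec.n_samples or start >= stop:
            raise ValueError(
                f"label {ev.label} [{ev.onset}, {ev.end}) s falls outside the "
                f"recording (duration {rec.duration} s)"
            )
        window = series[start:stop]
        peaks.append(window.max() if polarity == "positive" else window.min())
    return np.asarray(peaks)


def peak_stats(values: Sequence[float]) -> tuple[float, float, int]:
    """Arithmetic mean, population standard deviation and count of peaks."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("peak_stats requires at least one value")
    return float(values.mean()), float(values.std(ddof=0)), int(values.size)


def compute_threshold(M: float, SD: float, alpha: float) -> float:
    """Threshold rule ``THR = M - alpha * SD`` (all in microvolts)."""
    if SD < 0:
        raise ValueError("SD must be non-negative")
    return M - alpha * SD


def distribution_summary(values: Sequence[float]) -> DistributionSummary:
    """Quartiles (linear interpolation), Tukey 1.5*IQR outliers, 1st percentile."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 4:
        raise ValueError(f"need at least 4 values for quartiles, got {values.size}")
    q1, q2, q3 = np.percentile(values, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(float(v) for v in values[(values < lo) | (values > hi)])
    p1 = float(np.percentile(values, 1, method="linear"))
    return DistributionSummary(
        q1=float(q1), q2=float(q2), q3=float(q3), iqr=float(iqr),
        outliers=outliers, first_percentile=p1,
    )


def default_thresholds() -> ThresholdSet:
    """The published per-channel threshold table (see module docstring)."""
    return ThresholdSet()


def calibrate_stats(values: Sequence[float], alpha: float) -> CalibStats:
    """Full calibration record for one channel/polarity peak sample."""
    M, SD, N = peak_stats(values)
    return CalibStats(M=M, SD=SD, N=N, alpha=alpha, THR=compute_threshold(M, SD, alpha))
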