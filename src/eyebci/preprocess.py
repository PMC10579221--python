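"""Band-pass filtering and spectral analysis for the eye-artifact pipeline.

Eye artifacts carry their energy below ~15 Hz, so the detection front-end is
a causal Butterworth band-pass between 1 and 13 Hz (prototype order 2).  The
same filter runs in two modes:

* offline — the whole recording is filtered in one pass;
* streaming — each fixed-width batch is filtered with the delay-line state
  carried over, which makes the concatenated streaming output *exactly* equal
  to the offline causal output for any batch partition.

That equivalence is deliberate: it removes the offline/online mismatch that
arises when stream chunks are filtered independently, a known cause of
accuracy loss in real-time thresholding systems.  A zero-phase mode
(forward-backward filtering) is provided for offline exploration only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .io import Batch, Recording

__all__ = [
    "FilterSpec",
    "FilterState",
    "Spectrogram",
    "design_bandpass",
    "initial_state",
    "filter_offline",
    "filter_streaming",
    "stft",
    "band_spectrum",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass design.

    ``order`` is the analog prototype order; the resulting discrete transfer
    function has ``2 * order`` poles (band-pass transformation doubles the
    order).  Coefficients come from the bilinear transform with frequency
    prewarping (scipy's ``butter``).
    """

    low_hz: float
    high_hz: float
    order: int
    fs: float
    b: np.ndarray
    a: np.ndarray


@dataclass
class FilterState:
    """Per-channel delay-line state carried between streaming batches.

    ``zi`` has shape ``(n_taps - 1, n_channels)``; zeros mean cold start.
    """

    zi: np.ndarray


def design_bandpass(
    low_hz: float = 1.0,
    high_hz: float = 13.0,
    order: int = 2,
    fs: float = 500.0,
) -> FilterSpec:
    """Design the detection band-pass (default 1-13 Hz, order 2, 500 Hz)."""
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )
    if order < 1:
        raise ValueError(f"filter order must be >= 1, got {order}")
    b, a = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs)
    return FilterSpec(low_hz=low_hz, high_hz=high_hz, order=order, fs=fs, b=b, a=a)


def initial_state(spec: FilterSpec, n_channels: int) -> FilterState:
    """Zero (cold-start) delay-line state for ``n_channels`` channels."""
    return FilterState(zi=np.zeros((len(spec.a) - 1, n_channels)))


def filter_offline(rec: Recording, spec: FilterSpec, mode: str = "causal") -> Recording:
    """Filter a whole recording.

    ``causal`` is a single forward pass from zero initial state (identical to
    what the streaming path produces); ``zero_phase`` is forward-backward
    filtering with no group delay, for offline exploration.
    """
    if rec.fs != spec.fs:
        raise ValueError(f"recording fs {rec.fs} != filter design fs {spec.fs}")
    if mode == "causal":
        filtered = signal.lfilter(spec.b, spec.a, rec.data, axis=0)
    elif mode == "zero_phase":
        filtered = signal.filtfilt(spec.b, spec.a, rec.data, axis=0)
    else:
        raise ValueError(f"mode must be causal|zero_phase, got {mode!r}")
    return Recording(fs=rec.fs, channels=rec.channels, data=filtered, t0=rec.t0)


def filter_streaming(
    batch: Batch, spec: FilterSpec, state: FilterState
) -> tuple[Batch, FilterState]:
    """Causally filter one batch, carrying the delay line across calls.

    Feeding consecutive batches through this function reproduces, sample for
    sample, the single-pass causal filtering of the concatenated stream.
    """
    zi = state.zi
    if zi.shape != (len(spec.a) - 1, batch.data.shape[1]):
        raise ValueError(
            f"filter state shape {zi.shape} does not match "
            f"(n_taps-1={len(spec.a) - 1}, n_channels={batch.data.shape[1]})"
        )
    filtered, zf = signal.lfilter(spec.b, spec.a, batch.data, axis=0, zi=zi)
    return (
        Batch(data=filtered, start_time=batch.start_time, index=batch.index),
        FilterState(zi=zf),
    )


@dataclass(frozen=True)
class Spectrogram:
    """Hanning-tapered magnitude spectrogram (window 100, overlap 50)."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray  # (n_frames, n_freqs) magnitude
    window: int
    overlap: int
    taper: str = "hann"


def stft(
    series: np.ndarray, fs: float, window: int = 100, overlap: int = 50
) -> Spectrogram:
    """Short-time Fourier magnitude of a single-channel series.

    Frames are ``window`` samples with hop ``window - overlap``; the frame
    count is ``floor((N - window) / hop) + 1`` (no padding).
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1:
        raise ValueError("stft expects a single-channel 1-D series")
    if overlap >= window:
        raise ValueError(f"overlap {overlap} must be smaller than window {window}")
    if series.size < window:
        raise ValueError(f"series length {series.size} shorter than window {window}")
    hop = window - overlap
    frames = sliding_window_view(series, window)[::hop]
    taper = signal.windows.hann(window, sym=False)
    magnitude = np.abs(np.fft.rfft(frames * taper, axis=1))
    n_frames = frames.shape[0]
    times = (np.arange(n_frames) * hop + window / 2) / fs
    freqs = np.fft.rfftfreq(window, d=1 / fs)
    return Spectrogram(
        times=times, freqs=freqs, power=magnitude, window=window, overlap=overlap
    )


def band_spectrum(
    segment: np.ndarray, fs: float, fmin: float = 0.5, fmax: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """FFT magnitude of a segment restricted to ``[fmin, fmax]`` Hz."""
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 1 or segment.size == 0:
        raise ValueError("band_spectrum expects a non-empty 1-D segment")
    freqs = np.fft.rfftfreq(segment.size, d=1 / fs)
    magnitude = np.abs(np.fft.rfft(segment))
    mask = (freqs >= fmin) & (freqs <= fmax)
    return freqs[mask], magnitude[mask]
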