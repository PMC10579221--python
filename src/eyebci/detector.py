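"""Batch-driven state machine detecting blinks and lateral eye movements.

The detector consumes consecutive fixed-width batches of the band-passed
Fp1/F7/F8 stream and classifies the large ocular deflections that
contaminate these frontal channels:

* **Blinks** (double threshold on Fp1).  A sample above the strong
  threshold (156 uV) opens a blink immediately; a sample above the weak
  threshold (80 uV) merely raises the blink flag so that the *next* batch
  opens the event — this second threshold is what catches low-amplitude
  blinks that single-threshold detectors miss.
* **Lateral eye movements** (antiphase peak/valley on F7 and F8).  A gaze
  shift deflects the two inferior frontal channels in opposite directions
  near-simultaneously; the order of peak vs. valley encodes the direction.
  A look-right opens when F7 exceeds its upper threshold while F8 drops
  below its lower one in the same batch (look-left mirrored), then batches
  are concatenated until the window shows the full biphasic antiphase shape
  and its tail has settled back into the idle band.

Branches are tested in priority order blink > look-right > look-left each
batch; a strong Fp1 crossing aborts an in-progress lateral accumulation
into the blink branch.  One idle batch is always kept as ``previous`` and
prepended when an event opens, so onsets are not clipped at batch edges.

The same ``process_batch`` step serves offline and streaming use; combined
with state-carrying streaming filtering the two modes emit identical event
lists by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .calibration import ThresholdSet, default_thresholds
from .io import Batch, EventRecord, Recording, batch_stream, select_channels
from .preprocess import FilterSpec, design_bandpass, filter_offline, filter_streaming, initial_state

__all__ = [
    "DetectorConfig",
    "DetectorState",
    "DetectedEvent",
    "init_state",
    "process_batch",
    "lateral_shape_satisfied",
    "tail_settled",
    "detect_offline",
    "detect_streaming",
]

logger = logging.getLogger(__name__)

# Column order the detector expects in every batch.
CH_FP1, CH_F7, CH_F8 = 0, 1, 2


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable detection parameters.

    settle_band : dict
        Per-channel idle-state amplitude bound (uV); an event is complete
        only once the trailing ``settle_samples`` samples of its monitored
        channels all lie inside this band.  Defaults follow the threshold
        table magnitudes: +-80 uV on Fp1, +-20 uV on F7/F8.
    settle_samples : int
        Trailing samples that must sit in the idle band (25 = 50 ms at 500 Hz).
    max_event_batches : int
        Accumulation cap; a candidate that has not completed after this many
        batches (default 10 = 2 s) is abandoned so the stream cannot stall.
    min_blink_s : float
        Minimum blink span before completion is allowed (blinks last
        200-400 ms).
    warmup_s : float
        Initial virtual-time span with detection suppressed, covering the
        cold-start transient of the causal filter.
    antiphase_tol_s : float
        Maximum lag between the F7 and F8 leading extrema of a lateral event
        (the peak on one channel and the valley on the other occur nearly
        simultaneously).
    antiphase_min : float
        Lower bound on the antiphase index
        ``(var(F7-F8) - var(F7+F8)) / (var(F7-F8) + var(F7+F8))`` over the
        event core.  The index is +1 for perfectly opposed channels, -1 for
        common-mode activity, and is insensitive to rhythms (such as alpha)
        that ride on both channels together.
    """

    thresholds: ThresholdSet = field(default_factory=default_thresholds)
    batch_width: int = 100
    fs: float = 500.0
    settle_band: dict = field(
        default_factory=lambda: {"Fp1": 80.0, "F7": 20.0, "F8": 20.0}
    )
    settle_samples: int = 25
    max_event_batches: int = 10
    min_blink_s: float = 0.2
    warmup_s: float = 1.0
    antiphase_tol_s: float = 0.1
    antiphase_min: float = 0.3

    def __post_init__(self) -> None:
        if not self.settle_samples < self.batch_width:
            raise ValueError("settle_samples must be smaller than batch_width")
        if self.max_event_batches < 2:
            raise ValueError("max_event_batches must be >= 2")


@dataclass
class DetectorState:
    """Mutable state carried between batches.

    At most one of the three flags is raised at any time; ``accum`` holds the
    concatenated samples of the event in progress (non-empty iff a flag is
    raised); ``previous`` is the last idle batch, kept so it can be prepended
    when an event opens.
    """

    blink_flag: bool = False
    look_left_flag: bool = False
    look_right_flag: bool = False
    previous: Batch | None = None
    accum: np.ndarray | None = None
    accum_start: float = 0.0
    accum_batches: int = 0

    def flags(self) -> tuple[bool, bool, bool]:
        return (self.blink_flag, self.look_left_flag, self.look_right_flag)

    def _clear(self) -> None:
        self.blink_flag = self.look_left_flag = self.look_right_flag = False
        self.accum = None
        self.accum_batches = 0


@dataclass(frozen=True)
class DetectedEvent:
    """A classified artifact with virtual onset/end times and its samples."""

    label: str
    onset: float
    end: float
    window: np.ndarray

    def to_record(self) -> EventRecord:
        return EventRecord(label=self.label, onset=self.onset, end=self.end, source="detected")


def init_state(config: DetectorConfig) -> DetectorState:
    """Fresh state: all flags down, nothing stored."""
    return DetectorState()


def tail_settled(
    window: np.ndarray, config: DetectorConfig, channels: Sequence[str] = ("Fp1", "F7", "F8")
) -> bool:
    """True iff the last ``settle_samples`` on each monitored channel lie
    within that channel's idle band."""
    n = config.settle_samples
    if window.shape[0] < n:
        return False
    tail = window[-n:]
    col = {"Fp1": CH_FP1, "F7": CH_F7, "F8": CH_F8}
    return all(
        np.all(np.abs(tail[:, col[ch]]) <= config.settle_band[ch]) for ch in channels
    )


def lateral_shape_satisfied(
    window: np.ndarray,
    direction: str,
    thresholds: ThresholdSet,
    fs: float = 500.0,
    antiphase_tol_s: float = 0.1,
    antiphase_min: float = 0.3,
) -> bool:
    """Does the accumulated window show the ordered antiphase peak/valley
    signature of a lateral eye movement?

    Four conditions, all required:

    1. the antiphase difference F7 - F8 is biphasic and suprathreshold in
       both polarities, at the combined per-channel threshold values for
       this direction (for a look-right the leading F7-peak/F8-valley pair
       must clear the F7 upper plus F8 lower magnitudes, the rebound pair
       the opposite sides).  The difference trace carries the same evidence
       as the two channels but cancels rhythms and drifts common to both,
       which otherwise mask the weaker channel's crossing;
    2. the *leading* dominant deflection of the difference has the
       direction's polarity: positive for a look-right (F7 peak with
       simultaneous F8 valley), negative for a look-left.  The leading
       deflection — not the global extremum — carries the direction,
       because a causal band-pass makes each lobe ring;
    3. F7 and F8 are in phase opposition around the leading deflection
       (antiphase index above ``antiphase_min``); in-phase excursions, such
       as blink leakage reaching both channels, fail here;
    4. near the leading deflection the F7 extremum and the F8 extremum are
       near-simultaneous (within ``antiphase_tol_s``).
    """
    if direction not in ("left", "right"):
        raise ValueError(f"direction must be left|right, got {direction!r}")
    f7 = np.asarray(window)[:, CH_F7]
    f8 = np.asarray(window)[:, CH_F8]
    if f7.size == 0:
        return False
    event = f"look_{direction}"
    b7 = thresholds.lateral("F7", event)
    b8 = thresholds.lateral("F8", event)
    # 1. biphasic suprathreshold excursions of the antiphase difference
    d = f7 - f8
    if direction == "right":
        lead_thr = b7.upper - b8.lower  # F7 above upper while F8 below lower
        rebound_thr = b7.lower - b8.upper  # mirrored pair on the way back
        if not (np.max(d) > lead_thr and np.min(d) < rebound_thr):
            return False
    else:
        lead_thr = b7.lower - b8.upper
        rebound_thr = b7.upper - b8.lower
        if not (np.min(d) < lead_thr and np.max(d) > rebound_thr):
            return False
    # 2. leading dominant deflection of the difference trace
    # The causal filter boosts trailing lobes relative to the leading one,
    # so the bar for "dominant" is deliberately low: 30% of the window
    # maximum, but at least 25 uV (~3 sigma of idle-background difference).
    bar = max(0.3 * np.max(np.abs(d)), 25.0)
    dominant = np.abs(d) >= bar
    if not np.any(dominant):
        return False
    i_lead = int(np.argmax(dominant))
    want = 1.0 if direction == "right" else -1.0
    if np.sign(d[i_lead]) != want:
        return False
    # 3. phase opposition around the event core.  The index is computed
    # locally (the accumulated window may carry seconds of appended
    # background) and from the difference/sum variances, which cancels
    # rhythms common to both channels.
    tol = int(round(antiphase_tol_s * fs))
    core = slice(max(0, i_lead - tol), i_lead + 4 * tol)
    var_d = float(np.var(d[core]))
    var_s = float(np.var(f7[core] + f8[core]))
    if var_d + var_s == 0:
        return False
    if (var_d - var_s) / (var_d + var_s) < antiphase_min:
        return False
    # 4. near-simultaneous leading extrema (span kept tight so the ringing
    # that follows the rebound lobe cannot masquerade as the leading pair)
    span = slice(max(0, i_lead - tol), i_lead + tol)
    if direction == "right":
        i7 = int(np.argmax(f7[span]))
        i8 = int(np.argmin(f8[span]))
    else:
        i7 = int(np.argmin(f7[span]))
        i8 = int(np.argmax(f8[span]))
    return abs(i7 - i8) <= tol


def _open_accum(state: DetectorState, batch: Batch) -> None:
    """Start an accumulation window from ``previous`` (if unused) + batch."""
    if state.previous is not None:
        state.accum = np.concatenate([state.previous.data, batch.data], axis=0)
        state.accum_start = state.previous.start_time
        state.accum_batches = 2
        state.previous = None
    else:
        state.accum = batch.data.copy()
        state.accum_start = batch.start_time
        state.accum_batches = 1


def _append_accum(state: DetectorState, batch: Batch) -> None:
    state.accum = np.concatenate([state.accum, batch.data], axis=0)
    state.accum_batches += 1


def _onset_index(accum: np.ndarray, label: str, th: ThresholdSet) -> int:
    """First sample of the accumulated window carrying the event's own
    evidence: the weak-threshold crossing for a blink, the samplewise
    initiation conjunction (or first dominant opposed deflection) for a
    lateral movement.  This anchors the reported onset to the artifact
    rather than to a batch boundary."""
    if label == "blink":
        hits = accum[:, CH_FP1] > th.blink_weak
    elif label == "look_right":
        hits = (accum[:, CH_F7] > th.f7_look_right.upper) & (
            accum[:, CH_F8] < th.f8_look_right.lower
        )
    else:
        hits = (accum[:, CH_F7] < th.f7_look_left.lower) & (
            accum[:, CH_F8] > th.f8_look_left.upper
        )
    if not np.any(hits):
        d = accum[:, CH_F7] - accum[:, CH_F8]
        hits = np.abs(d) >= max(0.3 * np.max(np.abs(d)), 25.0)
    if not np.any(hits):
        return 0
    return int(np.argmax(hits))


def _emit(state: DetectorState, label: str, config: DetectorConfig) -> DetectedEvent:
    onset_idx = _onset_index(state.accum, label, config.thresholds)
    event = DetectedEvent(
        label=label,
        onset=state.accum_start + onset_idx / config.fs,
        end=state.accum_start + state.accum.shape[0] / config.fs,
        window=state.accum,
    )
    logger.debug("emit %s [%0.3f, %0.3f)", label, event.onset, event.end)
    state._clear()
    # "the last batch of data is not kept": nothing is carried as previous.
    state.previous = None
    return event


def _abandon(state: DetectorState, label: str) -> None:
    logger.debug(
        "abandon %s candidate at %0.3f s after %d batches",
        label, state.accum_start, state.accum_batches,
    )
    state._clear()
    state.previous = None


def process_batch(
    state: DetectorState, batch: Batch, config: DetectorConfig
) -> list[DetectedEvent]:
    """Advance the state machine by one band-passed Fp1/F7/F8 batch.

    Mutates ``state`` in place and returns the events completed by this
    batch (usually none or one).
    """
    data = batch.data
    if data.shape[1] != 3:
        raise ValueError("detector batches must carry exactly (Fp1, F7, F8)")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite samples in batch {batch.index}")

    th = config.thresholds
    fp1, f7, f8 = data[:, CH_FP1], data[:, CH_F7], data[:, CH_F8]
    events: list[DetectedEvent] = []

    # Warm-up: suppress detection while the causal filter's cold-start
    # transient rings through.
    if batch.start_time + batch.width / config.fs <= config.warmup_s:
        state.previous = batch
        return events

    blink_trigger = bool(np.max(fp1) > th.blink_strong)
    weak_evidence = bool(np.max(fp1) > th.blink_weak)
    # Lateral initiation demands the two opposed threshold crossings on the
    # *same* sample: the gaze dipole deflects F7 and F8 simultaneously.
    # (Checking the two channels' extrema independently over the batch would
    # let the alpha rhythm — which swings both ways within one 200 ms batch —
    # fake the conjunction.)  Batches with weak-blink-level Fp1 activity
    # cannot open a lateral event: the blink's frontal leakage crosses the
    # lateral thresholds, and blinks have branch priority.
    right_trigger = bool(
        np.any((f7 > th.f7_look_right.upper) & (f8 < th.f8_look_right.lower))
    ) and not weak_evidence
    left_trigger = bool(
        np.any((f7 < th.f7_look_left.lower) & (f8 > th.f8_look_left.upper))
    ) and not weak_evidence

    if state.blink_flag or blink_trigger:
        # Blink branch; a strong Fp1 crossing aborts any lateral accumulation
        # into this branch, keeping the samples gathered so far.
        state.look_left_flag = state.look_right_flag = False
        state.blink_flag = True
        if state.accum is None:
            _open_accum(state, batch)
        else:
            _append_accum(state, batch)
        span = state.accum.shape[0] / config.fs
        if span >= config.min_blink_s and tail_settled(state.accum, config, ("Fp1",)):
            events.append(_emit(state, "blink", config))
        elif state.accum_batches >= config.max_event_batches:
            _abandon(state, "blink")
    elif (
        state.look_right_flag
        or state.look_left_flag
        or right_trigger
        or left_trigger
    ):
        # Lateral branch: an in-progress accumulation keeps its flag (new
        # triggers cannot re-route it — the trailing lobe of a look-left
        # resembles the leading lobe of a look-right).
        if not (state.look_right_flag or state.look_left_flag):
            state.look_right_flag = right_trigger
            state.look_left_flag = left_trigger and not right_trigger
        if state.accum is None:
            _open_accum(state, batch)
        else:
            _append_accum(state, batch)
        flagged = "right" if state.look_right_flag else "left"
        emitted = False
        if tail_settled(state.accum, config, ("F7", "F8")):
            # The flagged direction is tried first; the mirrored one is a
            # fallback for the case where the opening trigger caught the
            # trailing lobe of the opposite movement.
            for direction in (flagged, "left" if flagged == "right" else "right"):
                if lateral_shape_satisfied(
                    state.accum, direction, th, config.fs,
                    config.antiphase_tol_s, config.antiphase_min,
                ):
                    if direction != flagged:
                        logger.debug(
                            "lateral candidate at %0.3f s reclassified %s -> %s",
                            state.accum_start, flagged, direction,
                        )
                    events.append(_emit(state, f"look_{direction}", config))
                    emitted = True
                    break
        if not emitted and state.accum is not None and (
            state.accum_batches >= config.max_event_batches
        ):
            _abandon(state, f"look_{flagged}")
    elif weak_evidence:
        # Weak-blink arm: keep this batch so the next one opens the event
        # with the weak peak included.
        state.blink_flag = True
        state.previous = batch
    else:
        state.previous = batch
    return events


def _detection_filter(config: DetectorConfig) -> FilterSpec:
    return design_bandpass(fs=config.fs)


def detect_offline(
    rec: Recording,
    config: DetectorConfig | None = None,
    spec: FilterSpec | None = None,
) -> list[DetectedEvent]:
    """Whole-recording detection: causal filter, batch, fold the state machine.

    The causal offline filter matches the streaming filter exactly, so this
    returns the same events as :func:`detect_streaming` on the same data.
    """
    config = config or DetectorConfig()
    spec = spec or _detection_filter(config)
    rec = select_channels(rec, ["Fp1", "F7", "F8"])
    filtered = filter_offline(rec, spec, mode="causal")
    state = init_state(config)
    events: list[DetectedEvent] = []
    for batch in batch_stream(filtered, config.batch_width):
        events.extend(process_batch(state, batch, config))
    return events


def detect_streaming(
    batches: Iterable[Batch],
    config: DetectorConfig | None = None,
    spec: FilterSpec | None = None,
) -> list[DetectedEvent]:
    """Streamed detection: per-batch stateful filtering + the state machine.

    ``batches`` carry raw (unfiltered) Fp1/F7/F8 samples, as cut by
    :func:`eyebci.io.batch_stream` or delivered by an acquisition loop.
    """
    config = config or DetectorConfig()
    spec = spec or _detection_filter(config)
    fstate = None
    dstate = init_state(config)
    events: list[DetectedEvent] = []
    for batch in batches:
        if fstate is None:
            fstate = initial_state(spec, batch.data.shape[1])
        filtered, fstate = filter_streaming(batch, spec, fstate)
        events.extend(process_batch(dstate, filtered, config))
    return events
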