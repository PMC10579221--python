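"""State-machine behavior: blink double threshold, antiphase lateral shape,
tail settling, offline/streaming agreement."""

import numpy as np
import pytest

from eyebci import (
    Batch,
    DetectorConfig,
    ThresholdSet,
    blink_waveform,
    default_thresholds,
    detect_offline,
    detect_streaming,
    init_state,
    lateral_shape_satisfied,
    lateral_waveforms,
    process_batch,
    tail_settled,
)
from eyebci.io import Recording, batch_stream, select_channels
from eyebci.evaluation import match_events


def zero_batches(n, width=100, channels=3, fs=500.0):
    return [
        Batch(np.zeros((width, channels)), start_time=i * width / fs, index=i)
        for i in range(n)
    ]


def pair_to_window(f7, f8):
    return np.stack([np.zeros_like(f7), f7, f8], axis=1)


class TestStateBasics:
    def test_init_flags_down(self, config):
        state = init_state(config)
        assert state.flags() == (False, False, False)
        assert state.previous is None and state.accum is None

    def test_zero_stream_no_events(self, config):
        state = init_state(config)
        for batch in zero_batches(50):
            assert process_batch(state, batch, config) == []
        assert state.flags() == (False, False, False)

    def test_states_independent(self, config):
        a, b = init_state(config), init_state(config)
        process_batch(a, zero_batches(20)[10], config)
        assert a.previous is not None and b.previous is None

    def test_nan_rejected(self, config):
        state = init_state(config)
        bad = Batch(np.full((100, 3), np.nan), 2.0, 10)
        with pytest.raises(ValueError):
            process_batch(state, bad, config)


class TestTailSettled:
    def test_zero_tail_settles(self, config):
        assert tail_settled(np.zeros((100, 3)), config)

    def test_mid_excursion_not_settled(self, config):
        window = np.zeros((100, 3))
        window[-10:, 1] = 60.0  # F7 still at 60 uV, band is +-20
        assert not tail_settled(window, config)
        assert tail_settled(window, config, channels=("Fp1",))  # Fp1 band +-80

    def test_short_window_not_settled(self, config):
        assert not tail_settled(np.zeros((10, 3)), config)


class TestLateralShape:
    def lobes(self, amp=40.0, n=150):
        lobe = amp * np.sin(np.pi * np.arange(n) / n) ** 2
        return np.concatenate([lobe, -lobe]), np.concatenate([-lobe, lobe])

    def test_antiphase_pair_right_not_left(self):
        f7, f8 = self.lobes()
        window = pair_to_window(f7, f8)
        th = default_thresholds()
        assert lateral_shape_satisfied(window, "right", th)
        assert not lateral_shape_satisfied(window, "left", th)

    def test_mirrored_pair_left_not_right(self):
        f7, f8 = self.lobes()
        window = pair_to_window(-f7, -f8)
        th = default_thresholds()
        assert lateral_shape_satisfied(window, "left", th)
        assert not lateral_shape_satisfied(window, "right", th)

    def test_monophasic_single_channel_fails(self):
        n = 150
        f7 = 40.0 * np.sin(np.pi * np.arange(n) / n) ** 2
        window = pair_to_window(f7, np.zeros(n))
        th = default_thresholds()
        assert not lateral_shape_satisfied(window, "right", th)
        assert not lateral_shape_satisfied(window, "left", th)

    def test_in_phase_excursions_fail(self):
        f7, _ = self.lobes()
        window = pair_to_window(f7, f7.copy())  # same sign on both channels
        th = default_thresholds()
        assert not lateral_shape_satisfied(window, "right", th)
        assert not lateral_shape_satisfied(window, "left", th)

    def test_generated_waveforms_pass_own_direction_only(self):
        th = default_thresholds()
        for direction in ("left", "right"):
            f7, f8 = lateral_waveforms(direction)
            window = pair_to_window(f7, f8)
            other = "right" if direction == "left" else "left"
            assert lateral_shape_satisfied(window, direction, th)
            assert not lateral_shape_satisfied(window, other, th)

    def test_misaligned_extrema_fail(self):
        n = 150
        lobe = 40.0 * np.sin(np.pi * np.arange(n) / n) ** 2
        f7 = np.concatenate([lobe, -lobe, np.zeros(2 * n)])
        f8 = np.concatenate([np.zeros(2 * n), -lobe, lobe])  # 0.6 s late
        window = pair_to_window(f7, f8)
        assert not lateral_shape_satisfied(window, "right", default_thresholds())


def inject(label, onset, duration=0.3, peak=170.0, seconds=6.0, noise=1.0, seed=0):
    """Low-noise recording with one injected artifact."""
    rng = np.random.default_rng(seed)
    n = int(seconds * 500)
    data = rng.normal(0, noise, size=(n, 3))
    start = int(onset * 500)
    if label == "blink":
        wave = blink_waveform(duration, peak)
        data[start : start + wave.size, 0] += wave
        data[start : start + wave.size, 1] += 0.3 * wave
        data[start : start + wave.size, 2] += 0.3 * wave
    else:
        f7, f8 = lateral_waveforms(label.removeprefix("look_"))
        data[start : start + f7.size, 1] += f7
        data[start : start + f8.size, 2] += f8
    return Recording(fs=500.0, channels=("Fp1", "F7", "F8"), data=data)


class TestDetection:
    def test_single_blink_detected_with_onset(self):
        rec = inject("blink", onset=3.0, peak=170.0)
        events = detect_offline(rec)
        assert [e.label for e in events] == ["blink"]
        assert abs(events[0].onset - 3.0) <= 0.3
        assert events[0].end - events[0].onset >= 0.2

    def test_weak_blink_needs_second_threshold(self):
        # 140 uV injected -> ~95-100 uV after the causal band-pass: between
        # the 80 uV weak and 156 uV strong thresholds.
        rec = inject("blink", onset=3.0, duration=0.22, peak=140.0)
        assert [e.label for e in detect_offline(rec)] == ["blink"]
        no_weak = DetectorConfig(
            thresholds=ThresholdSet(blink_strong=300.0, blink_weak=156.0)
        )
        assert detect_offline(rec, no_weak) == []

    @pytest.mark.parametrize("label", ["look_left", "look_right"])
    def test_lateral_detected_with_correct_direction(self, label):
        rec = inject(label, onset=3.0)
        events = detect_offline(rec)
        assert [e.label for e in events] == [label]
        assert abs(events[0].onset - 3.0) <= 0.3

    def test_empty_recording(self):
        rec = Recording(fs=500.0, channels=("Fp1", "F7", "F8"), data=np.zeros((0, 3)))
        assert detect_offline(rec) == []

    def test_blink_threshold_monotonicity(self, mixed_session):
        """Raising both blink thresholds can only lose blink events."""
        base = sum(
            e.label == "blink" for e in detect_offline(mixed_session.recording)
        )
        raised = DetectorConfig(
            thresholds=ThresholdSet(blink_strong=400.0, blink_weak=130.0)
        )
        fewer = sum(
            e.label == "blink"
            for e in detect_offline(mixed_session.recording, raised)
        )
        assert fewer <= base

    def test_event_windows_disjoint(self, mixed_session):
        events = detect_offline(mixed_session.recording)
        spans = sorted((e.onset, e.end) for e in events)
        for (_, end_a), (onset_b, _) in zip(spans, spans[1:]):
            assert end_a <= onset_b

    def test_flag_exclusivity_throughout(self, mixed_session, config, bandpass):
        from eyebci.preprocess import filter_offline

        rec = select_channels(mixed_session.recording, ["Fp1", "F7", "F8"])
        state = init_state(config)
        for batch in batch_stream(filter_offline(rec, bandpass), 100):
            process_batch(state, batch, config)
            assert sum(state.flags()) <= 1
            # accumulation implies a raised flag (the converse does not hold
            # during the weak-blink arm, which raises the flag one batch
            # before accumulation opens)
            if state.accum is not None:
                assert any(state.flags())


class TestOfflineStreamingAgreement:
    def test_identical_event_lists(self, mixed_session):
        offline = detect_offline(mixed_session.recording)
        rec3 = select_channels(mixed_session.recording, ["Fp1", "F7", "F8"])
        streamed = detect_streaming(batch_stream(rec3, 100))
        assert [(e.label, e.onset, e.end) for e in offline] == [
            (e.label, e.onset, e.end) for e in streamed
        ]

    def test_high_snr_recovery(self, mixed_session, background_session):
        detected = [e.to_record() for e in detect_offline(mixed_session.recording)]
        match = match_events(detected, list(mixed_session.truth), tolerance_s=0.3)
        correct = sum(t.label == d.label for t, d in match.pairs)
        assert correct / len(mixed_session.truth) >= 0.9
        assert detect_offline(background_session.recording) == []
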