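"""Synthetic session generator: determinism, waveform morphology, injection."""

import numpy as np
import pytest
from scipy import signal

from eyebci import (
    BackgroundSpec,
    SessionSpec,
    band_spectrum,
    blink_waveform,
    generate_session,
    lateral_waveforms,
    make_background,
)


class TestBackground:
    def test_seed_determinism(self):
        a = make_background(5.0, seed=3)
        b = make_background(5.0, seed=3)
        np.testing.assert_array_equal(a.data, b.data)
        c = make_background(5.0, seed=4)
        assert not np.array_equal(a.data, c.data)

    def test_rms_close_to_requested(self):
        spec = BackgroundSpec(noise_rms_uv=10.0, alpha_amp_uv=15.0)
        rec = make_background(30.0, spec=spec, seed=0)
        # expected RMS: noise (10) + alpha (15/sqrt(2)) in quadrature
        expected = np.hypot(10.0, 15.0 / np.sqrt(2))
        measured = np.sqrt(np.mean(rec.data[:, 0] ** 2))
        assert abs(measured - expected) / expected < 0.2

    def test_alpha_peak_visible(self):
        rec = make_background(20.0, seed=1)
        freqs, mags = band_spectrum(rec.channel("Fp1"), 500.0, fmin=2, fmax=30)
        assert abs(freqs[np.argmax(mags)] - 10.0) < 0.5

    def test_alpha_coherent_across_channels(self):
        """The alpha rhythm rides on all channels in phase (common mode)."""
        spec = BackgroundSpec(noise_rms_uv=0.5, alpha_amp_uv=15.0)
        rec = make_background(10.0, spec=spec, seed=2)
        r = np.corrcoef(rec.channel("F7"), rec.channel("F8"))[0, 1]
        assert r > 0.9


class TestBlinkWaveform:
    @pytest.mark.parametrize("duration", [0.2, 0.3, 0.4])
    def test_peak_exact_and_endpoints_zero(self, duration):
        wave = blink_waveform(duration, 170.0)
        assert wave.max() == pytest.approx(170.0)
        assert wave[0] == 0.0 and abs(wave[-1]) < 1.0
        assert wave.min() < 0  # negative rebound as the eyelid reopens

    def test_bandpass_retention(self, bandpass):
        """The blink's energy is low-frequency; the causal 1-13 Hz filter
        keeps >= 60% of the peak (the 1 Hz high-pass droops the slow lobe)."""
        for duration in (0.2, 0.3, 0.4):
            wave = blink_waveform(duration, 167.0)
            x = np.concatenate([np.zeros(500), wave, np.zeros(500)])
            y = signal.lfilter(bandpass.b, bandpass.a, x)
            assert y.max() >= 0.6 * 167.0


class TestLateralWaveforms:
    def test_right_leads_positive_on_f7(self):
        f7, f8 = lateral_waveforms("right")
        assert f7[np.argmax(np.abs(f7[:100]))] > 0
        assert f8[np.argmax(np.abs(f8[:100]))] < 0

    def test_antiphase(self):
        f7, f8 = lateral_waveforms("left")
        assert np.corrcoef(f7, f8)[0, 1] < -0.99

    def test_filtered_leading_deflection_matches_requested_amplitude(self, bandpass):
        """Amplitudes are detection-domain: after the causal band-pass the
        leading lobe reaches the requested 40 uV (so it exceeds the +-20/30
        thresholds it was calibrated above)."""
        f7, _ = lateral_waveforms("right")
        y = signal.lfilter(bandpass.b, bandpass.a, np.concatenate([f7, np.zeros(500)]))
        assert y[:100].max() == pytest.approx(40.0, rel=0.02)

    def test_tail_decays_slower_than_blink(self):
        f7, _ = lateral_waveforms("right")
        blink = blink_waveform(0.3, 167.0)
        # amplitude 200 ms after the last main lobe, relative to peak
        lat_tail = np.abs(f7[2 * 50 + 100 :]).max() / np.abs(f7).max()
        blink_tail = 0.0  # blink template ends at its nominal duration
        assert lat_tail > blink_tail and lat_tail > 0.01

    def test_unknown_direction(self):
        with pytest.raises(ValueError):
            lateral_waveforms("up")


class TestGenerateSession:
    def test_zero_events_is_background(self):
        spec = SessionSpec(duration_s=5.0, seed=8)
        sess = generate_session(spec)
        bg = make_background(5.0, spec=spec.background, seed=np.random.SeedSequence(8).spawn(2)[0])
        assert sess.truth == ()
        np.testing.assert_array_equal(sess.recording.data, bg.data)

    def test_seed_determinism_bit_identical(self):
        spec = SessionSpec(
            duration_s=20.0, seed=5, counts={"blink": 3, "look_left": 2}
        )
        a, b = generate_session(spec), generate_session(spec)
        np.testing.assert_array_equal(a.recording.data, b.recording.data)
        assert a.truth == b.truth

    def test_injection_linearity(self):
        spec = SessionSpec(
            duration_s=20.0, seed=5, counts={"blink": 2, "look_right": 2}
        )
        sess = generate_session(spec)
        bg = make_background(
            20.0, spec=spec.background, seed=np.random.SeedSequence(5).spawn(2)[0]
        )
        residual = sess.recording.data - bg.data
        # the residual is exactly the injected templates: zero outside events
        outside = np.ones(len(residual), dtype=bool)
        for t in sess.truth:
            s = int(t.onset * 500) - 1
            outside[max(s, 0) : s + 800] = False
        assert np.all(residual[outside] == 0)
        assert np.abs(residual[~outside]).max() > 30.0

    def test_blink_peak_moments(self):
        spec = SessionSpec(
            duration_s=200.0, seed=13, counts={"blink": 100}, min_separation_s=1.5
        )
        sess = generate_session(spec)
        bg = make_background(
            200.0, spec=spec.background, seed=np.random.SeedSequence(13).spawn(2)[0]
        )
        residual = sess.recording.data[:, 0] - bg.data[:, 0]
        peaks = []
        for t in sess.truth:
            s, e = int(t.onset * 500), int(t.end * 500) + 10
            peaks.append(residual[s:e].max())
        assert abs(np.mean(peaks) - 167.0) < 3.0 * (22.0 / 10.0 + 1)
        assert abs(np.std(peaks) - 22.0) < 3.0 + 2.0

    def test_scripted_events_and_overlap_error(self):
        spec = SessionSpec(
            duration_s=10.0, seed=0, events=(("blink", 2.0), ("look_left", 5.0))
        )
        sess = generate_session(spec)
        assert [t.label for t in sess.truth] == ["blink", "look_left"]
        bad = SessionSpec(
            duration_s=10.0, seed=0, events=(("blink", 2.0), ("blink", 2.1))
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_session(bad)

    def test_event_outside_duration_rejected(self):
        spec = SessionSpec(duration_s=3.0, seed=0, events=(("blink", 2.9),))
        with pytest.raises(ValueError, match="fit"):
            generate_session(spec)

    def test_min_separation_respected(self):
        spec = SessionSpec(
            duration_s=60.0, seed=3,
            counts={"blink": 8, "look_left": 6, "look_right": 6},
            min_separation_s=1.5,
        )
        sess = generate_session(spec)
        onsets = np.array([t.onset for t in sess.truth])
        assert np.all(np.diff(np.sort(onsets)) >= 1.5)
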