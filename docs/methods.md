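# Methods

## Signal model and assumptions

The detector operates on three 10/20 scalp-EEG channels sampled at 500 Hz:
Fp1 (left prefrontal, maximal blink deflection) and F7/F8 (left/right
inferior frontal, maximal and phase-opposed lateral-gaze deflections).
Amplitudes are in microvolts.  The corneo-retinal potential (cornea
positive, ~0.4–1 mV) acts as a dipole: eyelid closure swings it toward Fp1
(sharp positive deflection, 200–400 ms, followed by a smaller negative
rebound on reopening); horizontal gaze rotation deflects F7 and F8 in
opposite directions near-simultaneously, and these eye-movement potentials
settle more slowly than blinks.  Background EEG (tens of µV, including the
8–13 Hz alpha rhythm) is treated as noise to be rejected, not removed:
the artifacts *are* the signal.

All detection amplitudes — thresholds, settle bands, waveform morphology —
refer to the **band-passed** signal: a causal Butterworth band-pass,
analog-prototype order 2 (4 poles after the band transformation), 1–13 Hz,
designed by bilinear transform with prewarping.  Ocular artifacts carry
their energy below ~15 Hz; the 1 Hz high-pass removes drift and the DC
component of the monophasic blink.

### Offline ≡ streaming

The same causal filter runs in two modes: one pass over the whole
recording, or per-batch with the filter's delay-line state carried between
batches.  The two are exactly equivalent (the streaming output is
bit-for-bit the causal offline output for any batch partition), and the
detector state machine is a pure fold over batches — so offline and online
detection emit identical event lists by construction.  This is a deliberate
corrective design: real-time thresholding systems lose accuracy when
stream chunks are filtered independently of each other, because each chunk
restarts the filter transient.  A zero-phase (forward–backward) mode exists
for offline exploration only; detection never uses it.

## Detection state machine

Input: consecutive 100-sample (200 ms) batches of the filtered Fp1/F7/F8
stream, timestamped in *virtual time* (first sample = 0 s).  One idle batch
is always retained (`previous`) and prepended when an event opens, so event
windows are not clipped at batch boundaries; `previous` is replaced by each
newer idle batch and cleared when consumed or when an event completes.

Per batch, in priority order:

1. **Blink branch** — entered when Fp1 exceeds the strong threshold
   (156 µV) or the blink flag is raised.  Batches accumulate until the
   window spans ≥ 200 ms and its Fp1 tail has settled (last 50 ms within
   ±80 µV); then a blink event is emitted.  A strong Fp1 crossing aborts an
   in-progress lateral accumulation into this branch (blink priority).
2. **Lateral branch** — entered when, on the *same sample*, F7 > +20 µV
   while F8 < −30 µV (look-right) or F7 < −20 µV while F8 > +30 µV
   (look-left), and Fp1 shows no weak-blink-level activity.  An in-progress
   accumulation keeps its flag; new triggers cannot re-route it.  Batches
   accumulate until the window passes the antiphase shape test (below) and
   its F7/F8 tails have settled (last 50 ms within ±20 µV).
3. **Weak-blink arm** — if nothing else fired and Fp1 > 80 µV, the blink
   flag is raised and the batch stored, so the next batch opens the blink
   event with the weak peak included.  This second, lower threshold is what
   catches weak blinks that a single 156 µV threshold misses.
4. Otherwise the batch becomes `previous`.

An accumulation that has not completed after 10 batches (2 s) is abandoned
and the machine resets — a real-time system must not stall on malformed
input.  Detection is suppressed for the first 1 s of the stream while the
causal filter's cold-start transient rings through (state starts at zero).

### Antiphase shape test

Four conditions on the accumulated window, all required:

1. the difference trace `d = F7 − F8` is biphasic and suprathreshold in
   both polarities at the combined per-channel threshold values (for
   look-right: `max d` above 20+30 µV and `min d` below −(20+20) µV;
   mirrored for look-left);
2. the *leading* dominant deflection of `d` — the first sample whose
   magnitude reaches max(30 % of the window maximum, 25 µV) — has the
   direction's polarity (positive = look-right);
3. an antiphase index `(var(F7−F8) − var(F7+F8))/(var(F7−F8) + var(F7+F8))`
   over the 0.5 s core around the leading deflection exceeds 0.3
   (+1 = perfectly opposed channels, −1 = common-mode);
4. the F7 and F8 extrema near the leading deflection are simultaneous
   within 100 ms.

Two numerical facts drove this formulation, both measured on the filter
itself.  First, the causal band-pass attenuates the leading lobe of a
biphasic deflection to ~0.74 of its input peak while ringing *boosts* the
trailing lobe to ~1.0–1.4 — so the global extremum usually sits on the
trailing lobe and, read naively, encodes the *opposite* direction; only
the leading deflection is trustworthy.  Second, background rhythms (alpha
in particular) ride largely in phase on neighbouring frontal channels;
working on the difference trace and on the difference/sum variance ratio
cancels this common mode, whereas per-channel conditions are masked by it.
For the same reason the lateral *triggers* require their two threshold
crossings on the same sample: evaluated independently over a 200 ms batch,
the alpha rhythm (period 100 ms) satisfies both sides of the conjunction
at different instants several percent of idle batches.

Because triggers frequently first fire on the trailing lobe (whose
amplitudes are boosted), the flagged direction at completion is tried
first and the mirrored direction as fallback; the emitted label always
comes from the shape test, i.e. from the leading deflection.

### Event timestamps

The emitted onset is the time of the first sample carrying the event's own
evidence inside the accumulated window (first Fp1 weak-threshold crossing
for blinks; first initiation conjunction, else first dominant opposed
deflection, for laterals).  Anchoring the onset to a batch boundary
instead would quantize it 0.2–0.4 s early (window start = trigger batch
minus the prepended batch), which measurement showed pushes ~20 % of
lateral onsets outside a ±0.3 s matching tolerance.  The event `end` is
the end of the accumulated window, so `end − onset` includes the settle
wait and overestimates the physiological artifact duration.

## Calibration

`THR = M − α·SD`, with `M` the arithmetic mean and `SD` the *population*
standard deviation (`sqrt(Σ(y−M)²/N)`) of per-event peak amplitudes
(maximum or minimum sample within each labeled window, per polarity).
α trades sensitivity against false alarms: α = 0.5 on blink peaks
(167 ± 22 µV) gives the 156 µV strong threshold; the 80 µV weak threshold
is the published value chosen below all observed blink peaks (α = 4 would
give 79 µV arithmetically; the published table wins).  Lateral thresholds
are calibrated per channel and per polarity (4 values per direction).
Quartiles in the distribution summary use linear interpolation (NumPy
default, "type 7"), with Tukey 1.5·IQR outlier fences.

The max-sample peak estimator is biased high on noisy data: the maximum of
signal-plus-background over a window exceeds the template peak by roughly
the background's local maximum (order +10 µV at the default background).
Calibration recovery tests therefore bound the recovered threshold rather
than expecting exact reproduction; with the default background the
recovered strong threshold lands several µV above 156.

## Command distributor

Blink groups: a blink joins the open group iff its onset follows the
previous member's onset by ≤ 0.5 s (inclusive); a group is judged 1.5 s
after its first onset (single/double/triple by count), except that a
fourth member closes the group immediately (quadruple, dispatched early —
in the target application it maps to "go back").  Gaps are measured
onset-to-onset; a clock exactly at the horizon flushes; a fifth blink
after a quadruple starts a new group; only the newest group accepts joins,
older pending groups only await their horizon.  Lateral events pass
through one-to-one and never join blink groups.  Triple-blink groups are
emitted as their own kind (information is preserved; the application layer
may ignore them).

## Synthetic sessions

The generator emulates the *band-passed* appearance of the study
conditions — the domain in which every published amplitude lives:

* **Background**: per-channel 1/f-shaped Gaussian noise (RMS 10 µV,
  spectrum flattened below 1 Hz) plus a single 10 Hz alpha oscillation
  (amplitude 15 µV, seed-random phase) added *coherently* to all three
  channels — posterior alpha reaches frontal sites through volume
  conduction and a common reference roughly in phase.
* **Blinks**: raised-cosine spike (55 % of the duration) with a 15 %
  negative rebound; peak ~ Normal(167, 22) µV realized exactly on the
  recording; duration ~ Uniform(0.2, 0.4) s; an attenuated copy (×0.3)
  leaks onto F7/F8 in phase on both channels, the way a frontal source
  projects laterally.
* **Lateral movements**: two opposite-sign raised-cosine lobes of 100 ms
  each (saccade-fast — eyeball rotations are much quicker than eyelid
  closures) with a low-amplitude oscillatory tail (τ = 150 ms, slower than
  the blink's settle), antiphase on F7/F8; event span 0.6 s.  Lobe
  amplitudes (default 40 µV) are specified in the *detection domain*: the
  published thresholds are `M − α·SD` of deflections observed on filtered
  signals and hence sit below them by construction, so the raw template is
  scaled up by the measured leading-lobe attenuation (×1/0.74) so that the
  filtered leading deflection reaches the requested amplitude.  Blink
  amplitudes are *not* pre-compensated (their realized distribution on the
  recording is the specified one); consequently nearly all synthetic
  blinks are caught via the 80 µV weak path, and the low-amplitude,
  long-duration tail of the distribution (~2 %) falls below 80 µV after
  filtering and is missed — an honest property of these conditions, not a
  bug.

Sessions are bit-reproducible from a single seed (background and event
draws use independent seed-sequence children).  Scripted onsets or drawn
onsets with a minimum separation are supported; test sessions space events
2.5 s apart, matching the intended interface use in which the operator
pauses between commands (detector windows can span ~1.6 s including the
settle wait).

What the generator does **not** model: spontaneous (unscripted) blinks,
vertical eye movements, EMG and line-noise artifacts, electrode drift or
impedance changes, inter-subject variability, and any realistic volume-
conduction head geometry beyond the fixed 0.3 leakage factor.  Passing
tests therefore demonstrate the pipeline's correctness and its behavior
under the stated statistical structure — not clinical performance on real
recordings.

## Evaluation

Detections are matched one-to-one to truth by onset proximity: truth
events visited in time order, each taking the nearest unmatched detection
within the tolerance (default 0.5 s; the end-to-end tests use 0.3 s).
When one detection could serve two truth events, the earlier truth wins
and the later counts as a miss (the accounting used for merged events).
Reports: 3×3 predicted-by-actual confusion matrix with missed/false-alarm
margins, and per-label `detected/actual` accuracy rows (one decimal; three
on request); labels with no truth events render as "–".

## Problem sizes

The test suite runs end-to-end detection on 60 s sessions (20 events
each), streaming/offline identity on thirty 12 s sessions, calibration
recovery on 200 labeled blinks (~5.5 min of signal), and the exhaustive
distributor check on all ≤5-blink trains over a 0.1 s grid spanning 3 s
(~207 000 cases against an independent brute-force reference).  The whole
suite completes in well under a minute on one CPU.

## Known limitations

* Filtered-domain fidelity is approximate: re-filtering the generator's
  band-limited-by-design templates still attenuates them (blink peaks
  retain 63–74 % through the causal band-pass), which is why the weak
  blink path dominates on synthetic data while the study's strong
  threshold presumably fired on most real blinks.
* Look-up/look-down events are out of scope, as is the F7−F8 subtraction
  variant (noted as promising, not adopted) and any learned second-stage
  corrector.
* The EDF reader maps vendor channel labels by their trailing 10/20 token;
  unusual montage labels may need manual renaming.  EDF writing is not
  supported (CSV is the interchange format).
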