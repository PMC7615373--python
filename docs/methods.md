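# Methods

This note documents the models and procedures `seizmon` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Signal chain

The monitor thresholds an amplitude envelope computed causally from the raw
LFP (μV) at 625 Hz:

1. **Highpass**, 6.8 Hz — removes drift and large low-frequency transients
   before band filtering.
2. **Bandpass**, patient-specific (default 9–14 Hz, centered 11.5 Hz) — the
   seizure band chosen from the PSD contrast between annotated seizure and
   background segments. The center frequency is design metadata; only the
   two cutoffs determine the realized filter.
3. **Full-wave rectifier** `|·|`.
4. **Smoothing lowpass**, 1 Hz — turns the rectified band signal into a
   slowly varying amplitude envelope.

All stages are Butterworth IIR, order 2 per stage by default, run with
`scipy.signal.sosfilt` in direct streaming form. Zero-phase filtering is
deliberately not used in the chain: an implantable device cannot look
ahead, and causality is part of the test contract (truncating the input
does not change earlier envelope samples). Stage order (highpass before
bandpass, rectify before smooth) is a choice; the device literature names
the filters but not their arrangement, and the rectify-then-smooth envelope
detector is the minimal structure consistent with a threshold quoted in μV.
The smoothing stage can undershoot slightly after sharp amplitude drops, so
the envelope is clamped at zero.

For a unit-amplitude in-band sine, the rectified mean is 2/π, so the
steady-state envelope of an A-μV sine is ≈ 2A/π (attenuated a few percent
by the highpass and bandpass skirts at the tone frequency); this closed
form anchors the calibration tests. Band-limited RMS measurements
(default band 7–15 Hz) use a zero-phase 4th-order bandpass because they are
analysis metrics, not part of the streaming chain, and must not be biased
by filter delay. PSDs are averaged modified periodograms: 2 s Hann
segments, 50 % overlap — a standard choice; nothing in the device pipeline
depends on it.

## Classifier and event log

The state machine starts in the non-event program P0 with the debounce
timer treated as elapsed (a device must be able to respond immediately
after boot). The threshold comparison is `≥` for entering and `<` for
leaving — a single threshold, no hysteresis gap. The debounce (default 2 s)
gates **both** transition directions, which also guarantees a minimum
stimulation duration once a program is entered. The per-sample label is the
post-update state, so labels are exactly reconstructible from the
transition sequence.

The implementation jumps between threshold crossings with
`numpy.searchsorted` instead of looping over samples; its exact equivalence
to a literal per-sample state machine is asserted over 1000 randomized
streams in the acceptance suite. The debounce is converted to samples as
`ceil(debounce · f_s)` so that the sample-gap criterion `(i − i_last)/f_s ≥
debounce` is reproduced exactly.

Transitions carry two timestamps: the exact sample time, used for event
matching, and a quantized time `floor(t / r) · r` with resolution
`r ∈ [1, 2] s` (default 1 s), which is what the device's log stores. The
log is a rolling memory (default 1200 entries) evicting oldest first;
trigger counts report all transitions ever recorded, in both directions,
so they survive eviction.

## Evaluation

* **Sample-wise**: annotations rasterized on the envelope grid with
  half-open `[start, end)` intervals (sample *i* covers time *i/f_s*);
  TPR/FPR per threshold. The default ROC grid is 100 log-spaced thresholds
  spanning the [1st, 99.9th] envelope percentiles, with (0,0)/(1,1)
  endpoints at +∞ and 0. The default ROC applies each threshold directly to
  the envelope samples, which makes TPR and FPR non-decreasing in
  decreasing threshold *by construction*; running the full debounced state
  machine per threshold (`debounce=True`) is available, but debounce
  hold-times can break strict monotonicity (a lower threshold can enter an
  excursion earlier and therefore also leave it earlier), so the monotone
  sample view is the default for threshold selection.
* **Event-wise**: a P0→P1 transition at time *t* is a true positive iff an
  annotated seizure satisfies `start ≤ t ≤ end + 3 s` (closed window: a tie
  at exactly 3 s counts), attributed to the most recent such event;
  repeated detections of one event count once toward recall and are never
  false positives, so `tp + fn` always equals the number of annotated
  events. Undefined rates (no positives, no classifications) are reported
  as NaN with a warning, never silently zero.
* Percentages are rounded half-away-from-zero to one decimal; F1 is
  computed from the rounded precision/recall, matching how such tables are
  reported.
* Threshold selection maximizes TPR among grid thresholds with
  FPR ≤ `max_fpr` (default 0.05), ties broken toward the higher (more
  conservative) threshold. Note this rule intentionally operates at the
  FPR budget: on data whose background envelope is continuous it will sit
  near 5 % sample-FPR and therefore admits background false alarms. A
  zero-false-alarm operating point requires a threshold above the entire
  background envelope, which a budget-constrained TPR maximizer does not
  target; when the goal is a clean seizure diary, pick the threshold
  mid-way between the background and seizure envelope levels instead (the
  worked example in the README does exactly that).

## Preprocessing

Recordings are resampled to 625 Hz by polyphase rational resampling
(anti-alias lowpass included when downsampling); resampling to the same
rate is an exact identity. Around every annotated seizure a ±30 s window is
kept; overlapping windows are merged as a set union before extraction so no
sample is duplicated, then concatenated with all annotations remapped onto
the new time base. Seizures always survive with identical duration;
interictal intervals are carried along when they fall inside a kept window
and are ignored by event metrics. Epileptiform intervals are relabeled
purely by duration: > 3 s ⇒ seizure, otherwise interictal.

EDF input is read through MNE; a minimal single-channel EDF writer (1 s
records, 16-bit, symmetric physical range) is included so synthetic
recordings can be exported in the field's exchange format. The writer
zero-pads the final partial second; quantization error is bounded by
`phys_max / 32767`.

## Synthetic data

The generator produces what the detector actually relies on, not seizure
morphology:

| parameter | default | meaning |
|---|---|---|
| `background_rms_uv` | 10 μV | whole-recording background RMS |
| `spectral_exponent` | 1 | background power ∝ 1/f^α |
| `bump_band_hz` | (9, 14) | band of the seizure "bump" component |
| `bump_gain` | 10 | see below |
| `broadband_band_hz` | (0, 22) | broadband seizure component |
| `broadband_gain` | 2 | see below |
| `seizure_rate_per_hour` | 60 | rate-based event placement |
| `event_duration_s` | (8, 15) | uniform event durations |

A gain *g* adds an independent noise component whose RMS is `(g − 1)` times
its reference (the background's in-band RMS for the bump, the whole
background RMS for the broadband part), so `g = 1` adds nothing and the
in-band RMS during an event is `sqrt(1 + (g − 1)²)` × background — a gain-10
bump gives a ≈ 9× in-band amplitude contrast. Events get 1 s raised-cosine
on/off ramps so their edges do not leak broadband energy that would make
detection artificially easy, and rate-based placement keeps ≥ 60 s between
events so ±30 s windows do not merge unless a test constructs that case
explicitly. Everything is deterministic per seed.

Background amplitude and the gain defaults are calibration choices: no
public amplitude figures exist for this data class, so 10 μV RMS background
with a ~10× in-band seizure contrast was fixed once as a plausible
operating regime. What passing synthetic tests show is that the *pipeline*
is correct (filters, state machine, matching, bookkeeping) and that events
with a strong band-limited contrast are recovered perfectly at a mid-range
threshold. What they do not show is performance on real LFP —
non-stationarity, artifacts, sleep-stage band shifts and morphology are all
absent by design.

## Problem sizes

The randomized experiments run at sizes chosen to exercise every code path
while keeping the whole suite fast: 60–120 s streams at 125 Hz for
state-machine and ROC properties (1000 and 100 replicates), 600 s at
625 Hz with 10 events for the end-to-end synthetic runs (10 seeds), 100
random configurations for the YAML round trip.

## Known limitations

* The on-device envelope detector (rectifier type, any decimation) and the
  fixed-point arithmetic of the real firmware are not emulated; filters run
  in double precision.
* Single-channel only; no montage or re-referencing.
* The event log stores absolute quantized seconds; the real device's
  timestamp encoding is unknown.
* ROC-based threshold selection under an FPR budget is a preliminary
  estimate; the debounced device will realize slightly different rates.
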