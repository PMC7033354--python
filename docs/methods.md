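# Methods

## The procedure

Back-averaging correlates cortical with muscular activity by averaging EEG
epochs time-locked to EMG-defined movement onsets.  The pipeline is:

1. **Load** a multi-channel plain-text recording (one column per channel,
   one row per sample) with a user-supplied sampling rate `fs`.
2. **Envelope.** The selected EMG channel is full-wave rectified and
   min–max rescaled to [0, 1] so detection thresholds are unitless
   fractions of the strongest burst, independent of amplifier gain.
3. **Detect** burst onsets with the six-parameter rule (threshold crossing,
   quiet pre-window, active post-window, refractory period).
4. **Epoch & average.** Cut `window_s`-long segments with the onset at
   `onset_s`, subtract each EEG segment's mean over its first `baseline_s`
   seconds, and average across segments.
5. **Split-half check.** Randomly partition the epochs, average each half,
   and compare the pre-onset waveforms.

## Detection conventions

The detector marks the first threshold-crossing sample (the onset), since
time 0 of every epoch is defined as the burst onset.  The pre-window
excludes the crossing sample and the post-window includes it (half-open on
the right), so the two conditions test a pure "quiet baseline" and a pure
"sustained activity" with no double counting; inequalities are strict in the
direction of the parameter names ("lower than" / "higher than").  Window
lengths are `round(seconds × fs)` with a minimum of one sample; the
refractory gap is measured marker-to-candidate; candidates whose windows run
off a record edge are skipped.  The scan is greedy left-to-right, so results
are deterministic.  A deliberately naive loop-based reference implementation
(`detect_bursts_oracle`) is kept in the library and the test suite asserts
exact index-level agreement on randomised inputs.

## Envelope conditioning

Two optional steps sit between rectification and thresholding, both exposed
as config keys and both used by the high-level pipeline defaults:

- **Smoothing** (`smooth_s`, pipeline default 0.03 s): a centred moving
  average.  Raw rectified EMG is heavy-tailed — its typical in-burst level
  is ~0.8 of the burst RMS while the single largest excursion (which sets
  the min–max scale) is 3.5–4× the burst RMS — so without integration the
  unitless amplitude thresholds compare windows against an extreme-value
  statistic rather than the burst level, and a default like
  `amp_after = 0.3` becomes unreachable.  A window comparable to the
  physiological EMG rise time minimises threshold-crossing jitter
  (approximately ∝ (w + rise)/√w) while biasing onset latency by well under
  10 ms.
- **Percentile clipping** (`clip_percentile`, pipeline default 99.5): clips
  the rectified trace before rescaling so one artifact or noise spike does
  not compress the whole scale.  Rescaling always uses the global extrema of
  the full (conditioned) trace, matching the single-pass description of the
  procedure; the documented limitation that a huge artifact dominates the
  scale is exactly what the clip blunts.

`rectify_rescale` itself defaults to no smoothing and no clipping; the
pipeline defaults live in `backaverage.model` and every CLI command exposes
`--smooth` / `--clip-percentile`.

## Filtering

Software band-passing is optional and off by default, since clinical traces
normally arrive hardware-filtered.  The presets are Butterworth order 4
applied forward–backward (`sosfiltfilt`), chosen because onset timing must
not be biased by group delay; corners are 0.01–50 Hz for slow-potential
work, 1–70 Hz for standard myoclonus recordings, 10–250 Hz for EMG.  The
half-cycle rule `f = 1/(2d)` connects a monophasic deflection of duration
`d` to its fundamental frequency; `check_highpass_for_slow_wave` warns when
a high-pass corner would remove a slow pre-movement potential (a 2 s
potential ↔ 0.25 Hz, destroyed by a 1 Hz corner).  The very low 0.01 Hz
corner has a multi-minute impulse response, so gain measurements in the
tests use signals several minutes long and read the middle third.

## Epoching and averaging

Defaults: 3 s window, onset at 2 s, 0.5 s baseline — the segment spans the
full ~2 s lead time of a readiness potential.  Baseline correction is
per-segment (not on the grand average): it removes slow inter-trial drift,
which is the standard choice for slow-potential averaging.  It applies to
EEG only; rectified EMG keeps its raw baseline because the resting level is
physiologically meaningful.  Markers whose epoch crosses a record edge are
dropped and counted.  The average carries a per-sample standard error
(`σ̂(t)/√N`) used as the noise floor in reports.

For the split-half check the permutation comes from NumPy's PCG64
(`default_rng(seed)`); with odd N, group A receives the extra epoch.
Consistency is traditionally judged by eye; the Pearson correlation between
the two half-averages over the pre-onset samples is this package's own
quantitative stand-in, and is labelled as such in summaries.  Correction is
applied before splitting, so both halves share the same baseline treatment.

Trough measurement (`measure_trough`) smooths the average with a 50 ms
moving window before taking the minimum over the pre-onset interval
(through +100 ms), so a single-sample noise excursion is not reported as
the potential's peak; the same smoothed trace is used when checking a null
recording for spurious deflections.

## The synthetic generator

`backaverage.synth` stands in for clinical recordings; its defaults *are*
the study conditions the rest of the package is validated on: 1000 Hz
sampling, 300 s records, 40 movements at least 5 s apart, EMG bursts of
0.2 s at burst-RMS/baseline-RMS = 10, EEG background of 10 µV SD low-passed
at 50 Hz, and (in `bp` mode) a linear ramp from 0 at −2 s to −8 µV at the
onset returning to zero over 0.5 s.  `myoclonus` mode instead injects one
Hann-windowed 15 Hz cycle centred 20 ms before the onset (the 20 ms default
is a generator convenience of the right order, not a measured constant);
`null` mode injects nothing and serves as the negative control.

Implementation choices worth knowing:

- **Event placement.** Onset times are uniform conditioned on all gaps
  ≥ `min_iei_s`, drawn by the spacing construction (n uniform points in the
  slack interval, sorted, plus `i·min_iei_s`).  This is equivalent in
  distribution to rejection sampling but O(n) and feasible at any density —
  whole-set rejection has vanishing acceptance probability at the default
  packing.
- **Burst envelope.** Bursts multiply the continuous baseline noise by a
  raised-cosine-tapered (Tukey) gain with 10 ms cosine ramps.  A taper over
  the whole burst would make "the onset" a physically ill-defined instant
  tens of ms wide; the short ramp reproduces the sharp rise of real EMG
  bursts while keeping the ground-truth onset a single sample (the first
  sample of the ramp).
- **Stream separation.** Event times, EMG noise, EEG noise and the two
  auxiliary channels each draw from generators spawned from one
  `SeedSequence(seed)`, so changing `mode` changes only the EEG column:
  the EMG is bit-identical across modes at the same seed, which isolates
  the template injection in every differential test.
- **Layout.** Four columns with EMG in column 3 and EEG in column 4
  (1-based), matching the downstream defaults.  EEG is in µV; EMG units are
  arbitrary because detection operates on the normalised envelope.

What the generator does **not** emulate: 1/f EEG spectra, alpha rhythm, eye
blinks and movement artifacts, electrode drift, multi-muscle cross-talk,
variable burst morphology, and BP shape details (early/late slope
components) beyond a linear ramp.  Passing tests therefore demonstrate that
the pipeline recovers known, well-behaved embedded signals at clinically
realistic SNR — not that detection parameters transfer to any given
patient recording, where they are expected to need per-recording adjustment
(which is why the detector reports its marker count and the CLI makes
re-running cheap).

## Problem sizes

Validation uses the generator's default session (40 events, 300 s) for
detection, recovery and split-half checks, a 560 s / 100-event null record
for the √N study, and ≤ 3000-sample envelopes for the 200 randomised
detector/oracle equivalence trials; the whole suite and the acceptance
script each complete in well under a minute on one core.

## Known limitations

- The split-half Pearson correlation is a biased-down estimate of waveform
  reproducibility: with N epochs of noise σ and a planted signal of
  variance S over the pre-onset window, its expectation is approximately
  S/(S + 2σ²/N).  At the default conditions (−8 µV ramp, σ = 10 µV,
  N = 40) that is ≈ 0.5, so moderate correlations are expected even for a
  clearly present potential; the diagnostic is best read comparatively
  (signal vs null) rather than against a fixed bar.
- Onset markers inherit a few ms of jitter from envelope smoothing and
  noise; sub-millisecond latency claims are out of scope.
- No artifact rejection: epochs containing blinks or movement artifact are
  averaged like any other and must be excluded upstream.
- The text reader loads the full recording into memory; multi-hour
  recordings at high channel counts may need chunking upstream.
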