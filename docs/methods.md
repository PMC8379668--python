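# Methods

## Signal model and preprocessing

Recordings are 4-channel bipolar ECoG snippets (two hippocampal, two
inferior-temporal-gyrus pairs) at 250 Hz, either 180-s scheduled captures or
up to 15-min streamed segments. Within-recording times are seconds from
recording start, sample indices 0-based, intervals half-open `[start, end)`.

The sensing device blanks its amplifier for ~40 ms while delivering its own
stimulation; these gaps appear as simultaneous flat runs on every channel.
`detect_blanking` flags maximal all-channel constant runs (sample-to-sample
difference within 1e-6 of the recording's dynamic range — robust to 16-bit
EDF quantization) with duration between 20 and 200 ms, plus an 8-ms guard on
each side. The lower bound excludes chance equal-sample pairs, the upper
bound excludes genuinely flat physiological or railed stretches.
Single-channel flat runs are physiological and never flagged.

Masked samples are linearly interpolated in the working signal so IIR
filters stay well-conditioned, but they are excluded from every statistic
via the per-sample validity mask — a global audit test verifies that
corrupting invalid samples changes no downstream number.

All filters are 4th-order Butterworth run forward-backward (`sosfiltfilt`),
so group delay is zero (verified by impulse-peak alignment). The filter
family is a conventional choice; nothing downstream depends on it beyond a
flat passband. The volume-conduction artifact is notched out at 105 Hz
(4 Hz-wide band-stop) before band analyses, and each recording is z-scored
per channel over valid samples.

"Analytic amplitude" is implemented as the modulus of the analytic signal
(bandpass, then Hilbert transform), and phase as its argument. The envelope
at the edges of a filtered segment carries the filtfilt startup transient;
the first and last six cycles of the band's low edge are flagged invalid
(at six cycles the residual envelope error on a pure in-band sinusoid is
below 1%).

## Stimulation segmentation from the aliased artifact

Stimulation at 145 Hz sampled at 250 Hz folds to
`f' = |f − fs·round(f/fs)| = 105 Hz`. Segmentation extracts the analytic
amplitude in a 4 Hz band around the alias, averages it across channels (the
artifact is volume-conducted and present on all of them), z-scores it over
the recording, and keeps supra-zero runs longer than 10 s. Two parameters
are this package's choices where no published value exists:

- **Envelope bandwidth 4 Hz** — narrow enough to exclude the 70–90 Hz
  analysis band and broad enough for ~0.25 s envelope response, which keeps
  detected boundaries within ~0.1 s of truth at the default artifact
  amplitude.
- **Merge gap 2 s with 80% occupancy** — sub-threshold dips shorter than
  2 s (typically blanking excisions) are bridged, but a merged run is kept
  only if supra-threshold samples occupy ≥ 80% of its span. Occupancy
  matters: an artifact-free z-scored envelope wanders across zero roughly
  half the time, and gap-merging alone would chain its brief excursions
  into spuriously long false detections. With the occupancy gate, 50
  artifact-free simulations produce zero false detections while true
  on-intervals (occupancy ≥ 99%) are untouched.

The threshold itself stays at z > 0 and the 10-s minimum is kept as stated
settings; both are exposed in the config for sensitivity analyses.

Recordings are classified by on-interval position: `middle` requires a
single interval starting ≥ 20 s after recording start (enough baseline) and
ending ≥ 2 s before the end; clipped intervals give `begin`/`end`. QC
replaces manual review: `always_off` when nothing is detected and the alias
band is spectrally unremarkable; `always_on` when detections cover ≥ 90% of
the recording, or when nothing is detected *but* the raw alias-band envelope
exceeds twice its spectral flanks (a full-coverage artifact has no on/off
contrast for the z-scored envelope, yet remains narrowband-prominent);
`ambiguous` when detections outnumber what the duty cycle allows. Non-`ok`
recordings are excluded from paired analyses.

Duration-matched off controls are placed uniformly at random within
stimulation-off time, with a 10-s guard after each on-interval offset to
avoid carry-over (the acute effects concentrate at onset; the guard is a
design choice, not an asserted fact). Placement is seeded and reproducible.

## Band response analysis

Trials are middle-position recordings aligned at stimulation onset on a
−20..+70 s window. Each trial's band envelope is z-referenced to its own
−20..−10 s baseline (mean 0, SD 1 over valid baseline samples); referencing
is idempotent. Trials are rejected when baseline valid coverage falls below
90% — strict full coverage would discard ~20% of trials to harmless 56-ms
blanking excisions. The windowed test compares the −10..0 s per-trial mean
against fourteen consecutive non-overlapping 5-s windows tiling [0, 70) s —
the only tiling consistent with fourteen tests at 5 s starting at onset —
with Bonferroni α = 0.05/14 = 0.0036. The window count is configurable; the
final four windows fall after stimulation offset at the default duty cycle.

The suppression index is the mean band envelope over the 5 s before onset
minus the 5 s after (positive = suppression), computed on the z-scored
recording; it requires ≥ 80% valid samples in each half-window.

## Connectivity

Phase-locking value is the modulus of the mean unit phasor of the phase
difference over jointly valid samples (≥ 250 required). Cross-frequency
coupling is n:m phase-phase locking, `|mean exp(i(n·φ_a − m·φ_b))|`, with
(n, m) the best rational approximation of the band-center ratio capped at
12 — theta (7.5 Hz) to beta (20 Hz) gives (8, 3). A phase-amplitude variant
exists behind a flag, off by default, because the metric of record here is
phase-to-phase. Amplitude correlation is the Pearson correlation of the two
envelopes. Paired on/off values per recording are tested with Wilcoxon
signed-rank (zeros dropped and counted, classic procedure) at
α = 0.05/4 = 0.0125; the four comparisons are the 2×2 hippocampus×ITG
bipolar channel pairs.

## Epileptiform rates and longitudinal trends

Detection timestamps are consumed as event lists; the on-device detector is
not re-implemented (a labelled threshold picker exists for synthetic
fixtures only). Rates are events/min over half-open intervals; the paired
off side uses the duration-matched control by default (a full-off-time
variant is a config switch). Latency uniformity pools onset latencies across
intervals — and, in the pipeline, across recordings with each recording
matched only to its own intervals — into 10-s bins over 60 s and applies a
one-sample KS test against uniform.

Trends are OLS slopes per day since device implant (day resolution matches
the slope units), with two-sided p, Pearson r, and a 95% CI from the slope
standard error. Voltage-group analysis uses one-way ANOVA plus Tukey–Kramer
pairwise comparisons (studentized range with the unequal-n harmonic
correction, via statsmodels). CI overlap between per-voltage slopes is
reported descriptively; suppression values enter per recording.

## The synthetic generator

`simulate_recording` composes, per channel: unit-variance 1/f^α Gaussian
background (α = 1) with a 30% shared component across channels (nonzero
baseline connectivity); phase-diffusion oscillators (delta 3 Hz and high
gamma 80 Hz on hippocampal channels, beta 20 Hz on ITG, amplitudes 0.5–1.2
z-units, ~1.5–4 Hz linewidth); a coupled theta pair at 7.5 Hz in which ITG
channels follow the hippocampal phase with von Mises jitter whose
concentration is solved from the target phase-locking value
(I₁(κ)/I₀(κ) = PLV), refreshed every 0.5 s, switching between 0.30 (off) and
0.45 (on); biphasic ~70 ms hippocampal discharge transients at
inhomogeneous-Poisson times (2.0/min off, 0.5/min on); the stimulation
artifact; and 40-ms blanking holds every 47 s.

**Artifact.** Injected directly as a 105-Hz sinusoid during on-intervals —
downstream analysis only ever sees the sampled signal, and alias-domain
injection is exactly controllable. A physical validation mode synthesizes a
charge-balanced biphasic pulse train at 145 Hz on a 20× oversampled grid,
applies a front-end-style low-pass (cutoff above the recording Nyquist, so
folding still occurs but the fundamental dominates the harmonics), and
decimates without anti-aliasing; its spectral peak lands at the folded
frequency within one bin. The default amplitude, 0.5 z-units, is a tunable:
no published value exists (the artifact is invisible in raw traces), so it
was set low enough to be invisible against a unit-variance background yet
give an unambiguous narrowband elevation.

**Envelope effects in z-units.** A `BandEffect` multiplies the band-filtered
component of the composed signal by a gain
`g(t) = 1 + κ·(s + (1−s)·e^(−t/τ))` during on-intervals, with κ calibrated
against the envelope mean and SD of the generator's own stimulation-off
signal so that the envelope change at onset equals `effect_z` baseline-SDs.
This makes injected effects recoverable by the baseline-referenced trial
analysis without assuming any envelope distribution. Defaults mirror the
qualitative physiology the analysis targets: phasic theta (−1.5 z, τ = 5 s)
and high-gamma (−0.8 z) hippocampal suppression, partially sustained delta
suppression (−1.0 z, 60% sustained), transient ITG beta activation (+1.0 z).
Recovery tests compare against the decay-integrated expectation (e.g.
−1.5·(1−e⁻¹) ≈ −0.95 for the first 5-s window), not the onset value.

**Longitudinal series.** `simulate_longitudinal` emits per-recording summary
values (suppression index, PLV enhancement, rate difference) as linear
trends plus Gaussian noise over a contiguous voltage schedule (default
2 V → 3 V → 4.5 V → 5 V over 540 days, four scheduled captures/day). Trend
magnitudes default to 0.0033 z/day, 1.15e-4/day and 4.46e-5/day — realistic
scales for this kind of chronic data — and the suppression noise SD (0.32)
is calibrated so that ~80 recordings over 180 days give a weak correlation
(r ≈ 0.47); PLV (0.10) and rate (0.05) noise SDs similarly put their
correlations in the 0.1–0.2 range.

**What the generator does not emulate.** No ictal waveforms (events are
point processes; Long Episodes are daily counts), no electrode drift,
impedance changes, or recording dropouts, no circadian structure, no
non-stationary background, and oscillator/effect parameters are homogeneous
within a region. Passing recovery tests therefore demonstrates that the
estimators are unbiased and calibrated under the assumed statistical
structure — not that real recordings satisfy that structure.

## Problem sizes and numerical choices

Test suites use sizes chosen to make their statistical assertions stable:
30-recording cohorts for envelope-effect recovery, 50 seeded simulations for
segmentation sensitivity and false-positive checks, 100-run CI-coverage
suites (coverage asserted ≥ 88% where 95% is expected; binomial SD at
n = 100 is ~2.2%), and 300–500-rep type-I-error calibrations at the summary
level. Degenerate inputs raise typed errors: zero-variance channels name the
channel, all-masked recordings raise insufficient-data, all-zero Wilcoxon
differences return p = 1 with a warning, empty voltage epochs are flagged.
Bessel-ratio inversion for von Mises concentrations uses exponentially
scaled I₀/I₁ with Brent root-finding on [1e-9, 1e4].

EDF files are written by a minimal built-in codec (16-bit, 1-s records,
per-channel physical scaling; round-trip exact to one quantization step) and
cross-checked in the tests against an independent EDF reader. Delimited text
with a comment header is accepted for fixtures.
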