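# stimecog

Analysis of duty-cycled deep-brain-stimulation (DBS) effects in chronic
intracranial EEG recorded by a second, independent sensing device — with a
synthetic dual-device recording generator providing ground truth.

## The problem

A patient can carry two implanted neurostimulation devices at once: an
open-loop DBS system stimulating the anterior nucleus of the thalamus (ANT)
on a fixed duty cycle (1 min on / 5 min off, 145 Hz), and a responsive
neurostimulation (RNS) system that senses 4-channel bipolar ECoG from
hippocampal and inferior-temporal-gyrus (ITG) electrodes at 250 Hz. The two
devices do not communicate, so nothing in the recordings says when DBS was
on — except a volume-conducted stimulation artifact. Because 145 Hz exceeds
the 125 Hz Nyquist limit of the recordings, the artifact folds to

```
f' = |f_stim − f_s · round(f_stim / f_s)| = |145 − 250| = 105 Hz,
```

and a narrowband envelope at 105 Hz segments every recording into
stimulation-on and stimulation-off intervals. On top of that segmentation the
package quantifies:

- **Band responses** — Hilbert envelopes in delta (1–5 Hz), theta (5–10),
  alpha (10–15), beta (15–25), low gamma (30–40) and high gamma (70–90 Hz),
  aligned to stimulation onset, z-referenced to each trial's −20..−10 s
  baseline, and tested with paired t-tests over fourteen 5-s post-onset
  windows (Bonferroni-adjusted α = 0.05/14 = 0.0036).
- **Connectivity** — phase-locking value, n:m cross-frequency phase locking,
  and envelope (amplitude) correlation between hippocampal and ITG channels,
  compared between each on-interval and a duration-matched random off
  control via Wilcoxon signed-rank tests (α = 0.05/4 = 0.0125).
- **Epileptiform activity** — device-detected discharge rates on vs off
  (rank-sum), uniformity of discharge latencies across the 60-s on-interval
  (Kolmogorov–Smirnov), and the per-recording off-minus-on rate difference.
- **Longitudinal trends** — OLS slopes (per day) of suppression indices,
  phase-locking enhancement and rate differences, per-voltage-group trends
  with CI overlap, and one-way ANOVA with Tukey–Kramer post-hoc comparisons
  across stimulation voltages.

Since no patient data are public, the `synth` module generates recordings
with every statistical structure the analysis assumes — 1/f background,
band-limited oscillators, the aliased artifact, ~40 ms amplifier-blanking
gaps, stimulation-locked envelope effects, a state-dependent Poisson
discharge process, state-dependent theta phase coupling, and multi-month
linear drifts — all with known ground truth, so every stage is tested as a
parameter-recovery problem.

## Worked example

```python
import stimecog as se

cfg = se.SimConfig(duration_s=900.0, seed=1)     # 15-min streamed recording
rec, truth = se.simulate_recording(cfg)
intervals, qc = se.segment_recording(rec)
for iv in intervals:
    print(f"[{iv.start_s:7.2f}, {iv.end_s:7.2f}) s   ({iv.duration_s:.1f} s)")
print(qc.status)
```

prints

```
[  29.91,   90.03) s   (60.1 s)
[ 389.97,  450.02) s   (60.1 s)
[ 749.94,  810.08) s   (60.1 s)
ok
```

i.e. the three injected 60-s on-intervals (truth: [30, 90), [390, 450),
[750, 810) s) recovered to within ~0.1 s from the aliased artifact alone.
Aligning theta envelopes across 30 simulated scheduled recordings that carry
an injected onset suppression of −1.5 z (decaying with τ = 5 s):

```python
from tests.conftest import simulate_cohort
recs, ivs, _ = simulate_cohort(30, seed=7)
trials = se.align_trials(recs, ivs, "HPC1-HPC2", se.DEFAULT_BANDS[1])
res = se.windowed_paired_test(trials)[0]
print(res.t_statistic, res.p_value, res.alpha_adjusted, res.significant)
```

gives `t = -31.9, p = 3.9e-24, adjusted alpha = 0.0036, significant = True`,
and the trial-averaged z-envelope over the first 5 s is −0.93 — matching the
decay-integrated expectation −1.5·(1−e⁻¹) ≈ −0.95.

## Command-line pipeline

```sh
stimecog --config my.yaml simulate      # synthetic dataset + ground truth
stimecog --config my.yaml segment      # on/off intervals + QC report
stimecog --config my.yaml band-response
stimecog --config my.yaml connectivity
stimecog --config my.yaml epileptiform
stimecog --config my.yaml longitudinal
stimecog --config my.yaml report       # run manifest
```

The YAML config overrides a default profile that ships the device settings
(250 Hz, 145 Hz, 1/5-min duty cycle, band table, test windows, alphas);
unknown keys are rejected by name. Exit codes: 0 success, 2 config error,
3 data error, 1 otherwise.

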