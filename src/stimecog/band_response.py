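"""Time-locked band-envelope analysis around stimulation onset.

Trials are the stimulation-on intervals of position-class ``middle``
recordings, aligned at onset (t = 0) on a common window (default -20 to
+70 s). Each trial's band envelope is z-referenced to its own -20..-10 s
baseline, so effects are in baseline-SD units. Windowed paired t-tests
compare the -10..0 s pre-onset mean against consecutive 5-s post-onset
windows with Bonferroni correction across the 14 windows (adjusted alpha
0.05/14 = 0.0036). The per-trial suppression index is the mean envelope in
the 5 s before onset minus the 5 s after (positive = suppression).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .errors import ConfigError, InsufficientDataError
from .io import BandDef, Recording
from .preprocess import band_signal
from .segment import StimInterval, classify_position

__all__ = [
    "AlignedTrial",
    "WindowTestResult",
    "SuppressionIndex",
    "align_trials",
    "trial_average",
    "time_locked_spectrogram",
    "windowed_paired_test",
    "suppression_index",
]


@dataclass
class AlignedTrial:
    """One trial's baseline-referenced band envelope on the common axis."""

    recording_id: str
    channel: str
    band: BandDef
    time_axis_s: np.ndarray  # seconds relative to stimulation onset
    z_envelope: np.ndarray
    valid_mask: np.ndarray
    baseline_window_s: tuple[float, float] = (-20.0, -10.0)

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(self.time_axis_s[1] - self.time_axis_s[0])

    def window_mean(self, start_s: float, end_s: float, min_coverage: float = 0.8):
        """Mean z-envelope over [start_s, end_s) valid samples, or None if
        valid coverage is below ``min_coverage``."""
        sel = (self.time_axis_s >= start_s) & (self.time_axis_s < end_s)
        if not sel.any():
            return None
        ok = sel & self.valid_mask
        if ok.sum() < min_coverage * sel.sum():
            return None
        return float(self.z_envelope[ok].mean())


@dataclass(frozen=True)
class WindowTestResult:
    channel: str
    band: str
    window_s: tuple[float, float]
    t_statistic: float
    p_value: float
    significant: bool
    n_trials: int
    n_tests: int
    alpha_adjusted: float


@dataclass
class SuppressionIndex:
    """Pre-minus-post onset envelope difference; positive = suppression."""

    recording_id: str
    band: str
    value_z: float
    dbs_voltage_V: float = float("nan")
    days_since_implant: float = float("nan")


def _reference_to_baseline(
    env: np.ndarray,
    time_axis: np.ndarray,
    valid: np.ndarray,
    baseline: tuple[float, float],
) -> np.ndarray | None:
    sel = (time_axis >= baseline[0]) & (time_axis < baseline[1]) & valid
    if sel.sum() < 2:
        return None
    mu = env[sel].mean()
    sd = env[sel].std(ddof=0)
    if sd <= 0:
        return None
    return (env - mu) / sd


def align_trials(
    recordings: Mapping[str, Recording],
    intervals: Sequence[StimInterval],
    channel: str,
    band: BandDef,
    window: tuple[float, float] = (-20.0, 70.0),
    baseline: tuple[float, float] = (-20.0, -10.0),
    min_baseline_coverage: float = 0.9,
    require_full_window: bool = True,
) -> list[AlignedTrial]:
    """Extract baseline-referenced trials from middle-position recordings.

    ``recordings`` maps recording_id to *preprocessed* recordings (blanking
    excised, notched, z-scored). Only recordings whose single on-interval
    classifies as ``middle`` contribute; each trial is z-referenced to its
    own baseline window. Raises with per-reason rejection counts if nothing
    qualifies.
    """
    if not (window[0] <= baseline[0] < baseline[1] <= 0):
        raise ConfigError("baseline window must precede onset and lie in the window")
    by_rec: dict[str, list[StimInterval]] = {}
    for iv in intervals:
        by_rec.setdefault(iv.recording_id, []).append(iv)

    trials: list[AlignedTrial] = []
    reasons: Counter = Counter()
    for rid, ivs in sorted(by_rec.items()):
        rec = recordings.get(rid)
        if rec is None:
            reasons["recording_missing"] += 1
            continue
        pos = classify_position(ivs, rec.duration_s, recording_id=rid)
        if pos.label != "middle":
            reasons[f"position_{pos.label}"] += 1
            continue
        onset = ivs[0].start_s
        fs = rec.sampling_rate_hz
        i0 = int(round((onset + window[0]) * fs))
        i1 = int(round((onset + window[1]) * fs))
        if require_full_window and (i0 < 0 or i1 > rec.n_samples):
            reasons["window_exceeds_recording"] += 1
            continue
        i0c, i1c = max(0, i0), min(rec.n_samples, i1)
        bs = band_signal(rec, band)
        ch = rec.channel_index(channel)
        env = bs.envelope[ch, i0c:i1c]
        valid = bs.valid_mask[i0c:i1c]
        time_axis = (np.arange(i0c, i1c) - onset * fs) / fs

        base_sel = (time_axis >= baseline[0]) & (time_axis < baseline[1])
        if (base_sel & valid).sum() < min_baseline_coverage * base_sel.sum():
            reasons["baseline_coverage"] += 1
            continue
        z = _reference_to_baseline(env, time_axis, valid, baseline)
        if z is None:
            reasons["baseline_degenerate"] += 1
            continue
        trials.append(
            AlignedTrial(
                recording_id=rid,
                channel=channel,
                band=band,
                time_axis_s=time_axis,
                z_envelope=z,
                valid_mask=valid,
                baseline_window_s=baseline,
            )
        )
    if not trials:
        raise InsufficientDataError(
            f"no qualifying trials for channel {channel!r}, band {band.name!r}; "
            f"rejections: {dict(reasons)}"
        )
    return trials


def trial_average(
    trials: Sequence[AlignedTrial],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and SEM of the z-envelope over valid samples.

    Returns (time_axis, mean, sem, n_valid). Trials must share an axis
    (same window and sampling rate).
    """
    if len(trials) < 2:
        raise InsufficientDataError("need at least 2 trials to average")
    n = min(len(t.time_axis_s) for t in trials)
    axis = trials[0].time_axis_s[:n]
    data = np.stack([t.z_envelope[:n] for t in trials])
    valid = np.stack([t.valid_mask[:n] for t in trials])
    masked = np.ma.masked_array(data, mask=~valid)
    n_valid = valid.sum(axis=0)
    mean = np.asarray(masked.mean(axis=0))
    sd = np.asarray(masked.std(axis=0, ddof=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        sem = np.where(n_valid > 1, sd / np.sqrt(np.maximum(n_valid, 1)), np.nan)
    return axis, mean, sem, n_valid


def time_locked_spectrogram(
    recordings: Mapping[str, Recording],
    intervals: Sequence[StimInterval],
    channel: str,
    window: tuple[float, float] = (-20.0, 70.0),
    nperseg: int = 250,
    noverlap: int | None = None,
    max_freq_hz: float = 50.0,
):
    """Mean short-time power across trials, time-locked to onset.

    Returns (freqs_hz, times_rel_s, mean_power[freq, time]).
    """
    by_rec: dict[str, list[StimInterval]] = {}
    for iv in intervals:
        by_rec.setdefault(iv.recording_id, []).append(iv)
    specs = []
    freqs = times_rel = None
    for rid, ivs in sorted(by_rec.items()):
        rec = recordings.get(rid)
        if rec is None:
            continue
        if classify_position(ivs, rec.duration_s, recording_id=rid).label != "middle":
            continue
        fs = rec.sampling_rate_hz
        onset = ivs[0].start_s
        i0 = int(round((onset + window[0]) * fs))
        i1 = int(round((onset + window[1]) * fs))
        if i0 < 0 or i1 > rec.n_samples:
            continue
        ch = rec.channel_index(channel)
        f, t, sxx = sps.spectrogram(
            rec.signal[ch, i0:i1], fs=fs, nperseg=nperseg, noverlap=noverlap
        )
        keep = f <= max_freq_hz
        specs.append(sxx[keep])
        freqs, times_rel = f[keep], t + window[0]
    if len(specs) < 2:
        raise InsufficientDataError("need at least 2 middle trials for a spectrogram")
    return freqs, times_rel, np.mean(specs, axis=0)


def windowed_paired_test(
    trials: Sequence[AlignedTrial],
    baseline: tuple[float, float] = (-10.0, 0.0),
    window_length_s: float = 5.0,
    n_windows: int = 14,
    alpha: float = 0.05,
    min_coverage: float = 0.8,
) -> list[WindowTestResult]:
    """Paired t-tests of per-trial means: pre-onset baseline vs each 5-s
    post-onset window, Bonferroni-corrected across windows.

    The 14 default windows tile [0, 70) s. Trials lacking valid coverage in
    a given window are dropped from that window's pairs.
    """
    if len(trials) < 3:
        raise InsufficientDataError(
            f"need at least 3 trials for the paired test, got {len(trials)}"
        )
    alpha_adj = alpha / n_windows
    results = []
    for k in range(n_windows):
        w = (k * window_length_s, (k + 1) * window_length_s)
        pairs = []
        for t in trials:
            b = t.window_mean(*baseline, min_coverage=min_coverage)
            v = t.window_mean(*w, min_coverage=min_coverage)
            if b is not None and v is not None:
                pairs.append((b, v))
        if len(pairs) < 3:
            raise InsufficientDataError(
                f"fewer than 3 trials cover window [{w[0]}, {w[1]}) s"
            )
        b_arr, v_arr = np.array(pairs).T
        if np.allclose(b_arr, v_arr):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_rel(v_arr, b_arr)
        results.append(
            WindowTestResult(
                channel=trials[0].channel,
                band=trials[0].band.name,
                window_s=w,
                t_statistic=float(t_stat),
                p_value=float(p),
                significant=bool(p < alpha_adj),
                n_trials=len(pairs),
                n_tests=n_windows,
                alpha_adjusted=alpha_adj,
            )
        )
    return results


def suppression_index(
    recording: Recording,
    interval: StimInterval,
    band: BandDef,
    channel: str | None = None,
    half_window_s: float = 5.0,
    min_coverage: float = 0.8,
) -> SuppressionIndex:
    """Mean band envelope in the 5 s before onset minus the 5 s after.

    Positive values mean the envelope decreased after stimulation onset.
    Computed on the (z-scored) recording's band envelope; ``channel``
    defaults to the first channel.
    """
    fs = recording.sampling_rate_hz
    onset = interval.start_s
    ch = recording.channel_index(channel) if channel else 0
    bs = band_signal(recording, band)
    env = bs.envelope[ch]
    valid = bs.valid_mask
    t = np.arange(recording.n_samples) / fs - onset

    means = []
    for lo, hi in ((-half_window_s, 0.0), (0.0, half_window_s)):
        sel = (t >= lo) & (t < hi)
        ok = sel & valid
        if sel.sum() == 0 or ok.sum() < min_coverage * sel.sum():
            raise InsufficientDataError(
                f"{recording.recording_id}: insufficient valid envelope in "
                f"[{lo:+.0f}, {hi:+.0f}) s around onset"
            )
        means.append(float(env[ok].mean()))
    return SuppressionIndex(
        recording_id=recording.recording_id or interval.recording_id,
        band=band.name,
        value_z=means[0] - means[1],
    )
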