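"""Stimulation on/off segmentation from the aliased volume-conduction artifact.

The DBS pulse generator stimulates at 145 Hz while the sensing device samples
at 250 Hz, so the volume-conducted artifact folds across the 125 Hz Nyquist
limit and appears at 105 Hz in the recordings. Stimulation-on intervals are
recovered by extracting a narrowband envelope at the alias frequency,
z-scoring it over the recording, and keeping supra-zero runs longer than
10 s. Each recording is then classified by where the on-interval falls
(beginning / middle / end), and duration-matched stimulation-off control
intervals are drawn at random for paired comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError, InsufficientDataError
from .io import BandDef, Recording
from .preprocess import band_signal

__all__ = [
    "StimInterval",
    "PositionClass",
    "alias_frequency",
    "artifact_envelope",
    "detect_on_intervals",
    "classify_position",
    "match_control_interval",
    "segment_recording",
    "SegmentationQC",
]


@dataclass(frozen=True)
class StimInterval:
    """A labeled half-open [start_s, end_s) interval within one recording."""

    recording_id: str
    start_s: float
    end_s: float
    state: str = "on"  # on | off_control | truth_on
    method: str = "alias_detected"  # alias_detected | simulated | manual

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ConfigError(
                f"invalid interval [{self.start_s}, {self.end_s}) in "
                f"{self.recording_id!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass(frozen=True)
class PositionClass:
    """Where the stimulation-on interval falls within a recording."""

    recording_id: str
    label: str  # begin | middle | end | none | multiple


def alias_frequency(stim_freq_hz: float, sampling_rate_hz: float) -> float:
    """Frequency at which a component above Nyquist folds into the spectrum.

    f' = |f - fs * round(f / fs)|, always in [0, fs/2]. E.g. a 145 Hz
    stimulation frequency sampled at 250 Hz appears at 105 Hz; 80 Hz is below
    Nyquist and maps to itself.
    """
    if stim_freq_hz <= 0 or sampling_rate_hz <= 0:
        raise ConfigError("stimulation and sampling frequencies must be positive")
    return abs(
        stim_freq_hz - sampling_rate_hz * np.round(stim_freq_hz / sampling_rate_hz)
    )


def artifact_envelope(
    recording: Recording,
    alias_hz: float,
    bandwidth_hz: float = 4.0,
) -> np.ndarray:
    """Z-scored narrowband amplitude at the alias frequency.

    The analytic amplitude in ``alias_hz +/- bandwidth/2`` is averaged across
    channels (the artifact is volume-conducted, hence present on all of them)
    and z-scored over the recording's valid samples. Returns a 1-D per-sample
    array; invalid samples carry the interpolated value but should be read
    through the recording's mask.
    """
    nyq = recording.sampling_rate_hz / 2.0
    low = alias_hz - bandwidth_hz / 2.0
    high = alias_hz + bandwidth_hz / 2.0
    if not (0 < low < high < nyq):
        raise ConfigError(
            f"alias detection band ({low:.1f}, {high:.1f}) Hz outside (0, {nyq}) Hz; "
            "an alias at or beyond Nyquist needs a different detection band"
        )
    bs = band_signal(
        recording,
        BandDef("alias", low, high),
        edge_margin_s=4.0 / bandwidth_hz,
    )
    env = bs.envelope.mean(axis=0)
    valid = recording.valid_mask
    mu = env[valid].mean()
    sd = env[valid].std(ddof=0)
    if sd <= 0:
        raise DataError("artifact envelope has zero variance")
    return (env - mu) / sd


def detect_on_intervals(
    z_envelope: np.ndarray,
    sampling_rate_hz: float,
    recording_id: str = "",
    threshold_z: float = 0.0,
    min_duration_s: float = 10.0,
    merge_gap_s: float = 2.0,
    min_occupancy: float = 0.8,
) -> list[StimInterval]:
    """Stimulation-on intervals: supra-threshold runs of the alias envelope.

    Maximal runs with z-envelope above ``threshold_z`` are found and runs
    separated by sub-threshold gaps shorter than ``merge_gap_s`` (e.g.
    blanking excisions) are merged. A merged run is kept only if its
    supra-threshold time exceeds ``min_duration_s`` *and* supra-threshold
    samples occupy at least ``min_occupancy`` of its span — an artifact-free
    envelope wanders across the threshold about half the time, so gap
    merging alone would chain its brief excursions into spuriously long
    runs. Returns sorted, non-overlapping intervals; an empty list is a
    valid outcome.
    """
    z = np.asarray(z_envelope, dtype=float)
    above = z > threshold_z
    padded = np.concatenate(([False], above, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:]).astype(float)
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]).astype(float)

    merged: list[list[float]] = []  # [start, end, supra-sample count]
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) / sampling_rate_hz < merge_gap_s:
            merged[-1][1] = e
            merged[-1][2] += e - s
        else:
            merged.append([s, e, e - s])

    out = []
    for s, e, supra in merged:
        span = e - s
        if (
            supra / sampling_rate_hz > min_duration_s
            and supra >= min_occupancy * span
        ):
            out.append(
                StimInterval(
                    recording_id=recording_id,
                    start_s=s / sampling_rate_hz,
                    end_s=e / sampling_rate_hz,
                    state="on",
                    method="alias_detected",
                )
            )
    return out


def classify_position(
    intervals: list[StimInterval],
    recording_duration_s: float,
    edge_margin_s: float = 2.0,
    baseline_requirement_s: float = 20.0,
    recording_id: str | None = None,
) -> PositionClass:
    """Classify a recording by where its stimulation-on interval falls.

    ``middle``: exactly one interval starting at least
    ``baseline_requirement_s`` after recording start (enough pre-stimulation
    baseline) and ending at least ``edge_margin_s`` before the recording
    ends. ``begin``/``end``: the single interval is clipped by the
    respective edge. ``none`` / ``multiple`` as the names say.
    """
    rid = recording_id if recording_id is not None else (
        intervals[0].recording_id if intervals else ""
    )
    if len(intervals) == 0:
        return PositionClass(rid, "none")
    if len(intervals) > 1:
        return PositionClass(rid, "multiple")
    iv = intervals[0]
    touches_start = iv.start_s < baseline_requirement_s
    touches_end = iv.end_s > recording_duration_s - edge_margin_s
    if touches_start:
        # an interval clipped at both edges also lands here; the QC layer
        # flags such recordings always_on separately
        return PositionClass(rid, "begin")
    if touches_end:
        return PositionClass(rid, "end")
    return PositionClass(rid, "middle")


def match_control_interval(
    on_interval: StimInterval,
    recording: Recording,
    detected_on_intervals: list[StimInterval],
    seed: int,
    guard_after_s: float = 10.0,
) -> StimInterval:
    """Draw a duration-matched stimulation-off control interval.

    The control has the same duration as ``on_interval`` and is placed
    uniformly at random wholly inside stimulation-off time, with a
    ``guard_after_s`` buffer after each detected on-interval to avoid
    carry-over effects. Deterministic for a given seed.
    """
    dur = on_interval.duration_s
    total = recording.duration_s
    # forbidden regions: every on interval extended by the guard
    forbidden = sorted(
        (iv.start_s, min(total, iv.end_s + guard_after_s))
        for iv in detected_on_intervals
    )
    free: list[tuple[float, float]] = []
    cursor = 0.0
    for s, e in forbidden:
        if s > cursor:
            free.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < total:
        free.append((cursor, total))

    feasible = [(s, e) for s, e in free if e - s >= dur]
    if not feasible:
        raise InsufficientDataError(
            f"{recording.recording_id or on_interval.recording_id}: no "
            f"stimulation-off region of at least {dur:.1f} s for a matched control"
        )
    rng = np.random.default_rng(seed)
    slack = np.array([e - s - dur for s, e in feasible])
    region = rng.choice(len(feasible), p=(slack + 1e-12) / (slack + 1e-12).sum())
    s, e = feasible[region]
    start = s if slack[region] == 0 else s + rng.uniform(0.0, slack[region])
    return StimInterval(
        recording_id=on_interval.recording_id,
        start_s=float(start),
        end_s=float(start + dur),
        state="off_control",
        method=on_interval.method,
    )


@dataclass
class SegmentationQC:
    """Automated stand-in for manual review of detected intervals."""

    recording_id: str
    status: str  # ok | always_on | always_off | ambiguous
    n_intervals: int
    on_fraction: float
    alias_prominence: float = float("nan")
    notes: str = ""


def _alias_prominence(
    recording: Recording, alias_hz: float, bandwidth_hz: float
) -> float:
    """Mean alias-band envelope relative to its spectral flanks.

    The z-scored envelope loses absolute level, so a recording covered
    end-to-end by artifact looks identical to one with none. The raw
    narrowband envelope compared against the bands just above and below the
    alias disambiguates: a volume-conducted sinusoid is narrowband, the 1/f
    background is not.
    """
    nyq = recording.sampling_rate_hz / 2.0
    center = band_signal(
        recording,
        BandDef("alias", alias_hz - bandwidth_hz / 2, alias_hz + bandwidth_hz / 2),
        edge_margin_s=4.0 / bandwidth_hz,
    )
    flanks = []
    for offset in (-2.0 * bandwidth_hz, 2.0 * bandwidth_hz):
        lo = alias_hz + offset - bandwidth_hz / 2
        hi = alias_hz + offset + bandwidth_hz / 2
        if 0 < lo < hi < nyq:
            flanks.append(
                band_signal(
                    recording,
                    BandDef("flank", lo, hi),
                    edge_margin_s=4.0 / bandwidth_hz,
                )
            )
    if not flanks:
        return float("nan")
    valid = center.valid_mask
    flank_mean = np.mean([f.envelope[:, valid].mean() for f in flanks])
    return float(center.envelope[:, valid].mean() / flank_mean)


def segment_recording(
    recording: Recording,
    stim_freq_hz: float = 145.0,
    bandwidth_hz: float = 4.0,
    threshold_z: float = 0.0,
    min_duration_s: float = 10.0,
    merge_gap_s: float = 2.0,
    max_on_fraction: float = 0.9,
    prominence_threshold: float = 2.0,
) -> tuple[list[StimInterval], SegmentationQC]:
    """Full alias-based segmentation of one recording, with QC status.

    Recordings covered almost entirely by artifact (``always_on``, including
    the no-contrast case where the z-scored envelope cannot segment but the
    alias band is spectrally prominent), with no detected interval
    (``always_off``), or with implausibly fragmented detections
    (``ambiguous``) are flagged so paired analyses can exclude them.
    """
    alias = alias_frequency(stim_freq_hz, recording.sampling_rate_hz)
    z = artifact_envelope(recording, alias, bandwidth_hz)
    intervals = detect_on_intervals(
        z,
        recording.sampling_rate_hz,
        recording_id=recording.recording_id,
        threshold_z=threshold_z,
        min_duration_s=min_duration_s,
        merge_gap_s=merge_gap_s,
    )
    prominence = _alias_prominence(recording, alias, bandwidth_hz)
    on_time = sum(iv.duration_s for iv in intervals)
    frac = on_time / recording.duration_s
    if frac >= max_on_fraction:
        status, notes = "always_on", "artifact covers nearly the whole recording"
    elif not intervals and prominence > prominence_threshold:
        status, notes = (
            "always_on",
            "no on/off contrast but the alias band is spectrally prominent",
        )
    elif not intervals:
        status, notes = "always_off", "no supra-threshold run longer than minimum"
    elif len(intervals) > np.ceil(recording.duration_s / 300.0) + 1:
        status, notes = "ambiguous", "more intervals than the duty cycle allows"
    else:
        status, notes = "ok", ""
    if status != "ok":
        warnings.warn(
            f"segmentation QC for {recording.recording_id!r}: {status} ({notes})",
            stacklevel=2,
        )
    return intervals, SegmentationQC(
        recording_id=recording.recording_id,
        status=status,
        n_intervals=len(intervals),
        on_fraction=float(frac),
        alias_prominence=prominence,
        notes=notes,
    )
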