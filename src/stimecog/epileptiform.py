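"""Epileptiform-discharge rate analysis around duty-cycled stimulation.

Device detection timestamps are consumed as event lists (the on-device
detector is not re-implemented). Rates are events per minute over half-open
intervals; stimulation-on rates are compared against duration-matched
off-control rates with a rank-sum test, within-interval latencies are tested
against uniformity (Kolmogorov-Smirnov), and the per-recording off-minus-on
rate difference forms the series for longitudinal trend analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InsufficientDataError
from .segment import StimInterval

__all__ = [
    "RateSample",
    "EpileptiformDifference",
    "interval_rates",
    "rate_comparison",
    "within_interval_uniformity",
    "pooled_within_interval_uniformity",
    "difference_series",
    "threshold_spike_detector",
]


@dataclass(frozen=True)
class RateSample:
    recording_id: str
    interval_state: str  # on | off_control | ...
    n_events: int
    duration_min: float

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ConfigError("interval duration must be positive")

    @property
    def rate_per_min(self) -> float:
        return self.n_events / self.duration_min


@dataclass(frozen=True)
class EpileptiformDifference:
    """Off-minus-on event rate for one recording (positive = suppression)."""

    recording_id: str
    diff_per_min: float
    days_since_implant: float = float("nan")
    dbs_voltage_V: float = float("nan")


def interval_rates(
    events: np.ndarray, intervals: Sequence[StimInterval]
) -> list[RateSample]:
    """Events per minute in each half-open interval [start, end)."""
    ev = np.sort(np.asarray(events, dtype=float))
    out = []
    for iv in intervals:
        n = int(
            np.searchsorted(ev, iv.end_s, side="left")
            - np.searchsorted(ev, iv.start_s, side="left")
        )
        out.append(
            RateSample(
                recording_id=iv.recording_id,
                interval_state=iv.state,
                n_events=n,
                duration_min=iv.duration_s / 60.0,
            )
        )
    return out


def rate_comparison(
    on_samples: Sequence[RateSample], off_samples: Sequence[RateSample]
) -> dict:
    """Rank-sum comparison of per-interval rates, on vs off.

    Returns the test statistic, p-value and group descriptives. Degenerate
    all-zero data yields p = 1 with a warning.
    """
    if len(on_samples) < 5 or len(off_samples) < 5:
        raise InsufficientDataError(
            f"need >= 5 rate samples per group, got {len(on_samples)} on / "
            f"{len(off_samples)} off"
        )
    on = np.array([s.rate_per_min for s in on_samples])
    off = np.array([s.rate_per_min for s in off_samples])
    if np.all(on == on[0]) and np.all(off == off[0]) and on[0] == off[0]:
        warnings.warn("identical constant rates in both groups; p set to 1",
                      stacklevel=2)
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.mannwhitneyu(on, off, alternative="two-sided")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "n_on": len(on),
        "n_off": len(off),
        "mean_on_per_min": float(on.mean()),
        "mean_off_per_min": float(off.mean()),
        "median_on_per_min": float(np.median(on)),
        "median_off_per_min": float(np.median(off)),
    }


def _onset_latencies(
    events: np.ndarray,
    on_intervals: Sequence[StimInterval],
    interval_length_s: float,
) -> np.ndarray:
    ev = np.sort(np.asarray(events, dtype=float))
    latencies = [np.array([])]
    for iv in on_intervals:
        inside = ev[(ev >= iv.start_s) & (ev < iv.end_s)]
        lat = inside - iv.start_s
        latencies.append(lat[lat < interval_length_s])
    return np.concatenate(latencies)


def within_interval_uniformity(
    events: np.ndarray,
    on_intervals: Sequence[StimInterval],
    bin_s: float = 10.0,
    interval_length_s: float = 60.0,
) -> dict:
    """Are event latencies uniform across the stimulation-on interval?

    Latencies from each interval's onset are pooled across intervals, binned
    (default 10-s bins over 60 s), and tested one-sample KS against
    uniform[0, interval_length_s]. Events beyond ``interval_length_s`` from
    onset (from truncated intervals) are excluded.
    """
    lat = _onset_latencies(events, on_intervals, interval_length_s)
    return _uniformity_from_latencies(lat, bin_s, interval_length_s)


def pooled_within_interval_uniformity(
    events_by_recording: dict[str, np.ndarray],
    intervals_by_recording: dict[str, Sequence[StimInterval]],
    bin_s: float = 10.0,
    interval_length_s: float = 60.0,
) -> dict:
    """Uniformity test with latencies pooled across recordings.

    Each recording's events are matched only against its own stimulation-on
    intervals, so overlapping per-recording time axes cannot cross-count.
    """
    lats = [
        _onset_latencies(ev, intervals_by_recording.get(rid, []), interval_length_s)
        for rid, ev in events_by_recording.items()
    ]
    lat = np.concatenate(lats) if lats else np.array([])
    return _uniformity_from_latencies(lat, bin_s, interval_length_s)


def _uniformity_from_latencies(
    lat: np.ndarray, bin_s: float, interval_length_s: float
) -> dict:
    if len(lat) < 10:
        raise InsufficientDataError(
            f"need >= 10 events inside on-intervals for the KS test, got {len(lat)}"
        )
    edges = np.arange(0.0, interval_length_s + bin_s / 2, bin_s)
    hist, _ = np.histogram(lat, bins=edges)
    ks = stats.kstest(lat, stats.uniform(loc=0, scale=interval_length_s).cdf)
    return {
        "bin_edges_s": edges,
        "histogram": hist,
        "n_events": int(len(lat)),
        "ks_statistic": float(ks.statistic),
        "p_value": float(ks.pvalue),
    }


def difference_series(
    events_by_recording: dict[str, np.ndarray],
    paired_intervals: Sequence[tuple[StimInterval, StimInterval]],
    catalog: pd.DataFrame | None = None,
) -> list[EpileptiformDifference]:
    """Per-recording off-minus-on rate difference with date and voltage.

    ``paired_intervals`` holds (on, off_control) pairs; recordings with no
    event list are skipped with a warning.
    """
    meta = {}
    if catalog is not None:
        for row in catalog.itertuples():
            meta[str(row.recording_id)] = (
                float(getattr(row, "days_since_implant", float("nan"))),
                float(getattr(row, "dbs_voltage", float("nan"))),
            )
    out = []
    for on_iv, off_iv in paired_intervals:
        rid = on_iv.recording_id
        if rid not in events_by_recording:
            warnings.warn(f"no event list for recording {rid}; skipped", stacklevel=2)
            continue
        ev = events_by_recording[rid]
        on_rate, off_rate = (
            s.rate_per_min for s in interval_rates(ev, [on_iv, off_iv])
        )
        days, volt = meta.get(rid, (float("nan"), float("nan")))
        out.append(
            EpileptiformDifference(
                recording_id=rid,
                diff_per_min=off_rate - on_rate,
                days_since_implant=days,
                dbs_voltage_V=volt,
            )
        )
    return out


def threshold_spike_detector(
    signal: np.ndarray,
    sampling_rate_hz: float,
    threshold_z: float = 4.0,
    refractory_s: float = 0.2,
) -> np.ndarray:
    """Simple amplitude-threshold spike picker, for synthetic fixtures only.

    This is *not* the clinical device's detection algorithm; it exists so
    fixture pipelines can derive event lists from raw synthetic traces.
    Returns event times where |z| crosses the threshold, with a refractory
    period between events.
    """
    x = np.asarray(signal, dtype=float)
    z = (x - x.mean()) / (x.std() or 1.0)
    above = np.abs(z) > threshold_z
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    times = crossings / sampling_rate_hz
    keep = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_s:
            keep.append(t)
            last = t
    return np.array(keep)
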