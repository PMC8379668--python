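"""Pre-processing of chronic ECoG recordings.

The sensing device blanks its amplifier for ~40 ms while delivering its own
stimulation, which shows up as simultaneous flat segments on every channel.
These are detected and excised, the volume-conducted DBS artifact is notched
out at its aliased frequency, and each recording is z-scored per channel
before band-limited envelopes and phases are extracted via the analytic
signal.

All filters are 4th-order Butterworth applied forward-backward (zero phase).
Invalid samples are linearly interpolated in the working signal so filters
stay well-behaved, but they are permanently excluded from every downstream
statistic via the recording's ``valid_mask``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

from .errors import ConfigError, DataError, InsufficientDataError
from .io import BandDef, Recording

__all__ = [
    "BandSignal",
    "interpolated_signal",
    "detect_blanking",
    "apply_mask",
    "notch",
    "zscore_recording",
    "band_signal",
    "standard_preprocess",
]


@dataclass
class BandSignal:
    """Analytic amplitude and phase of a band-filtered recording.

    ``envelope`` and ``phase`` are (channels x samples); ``valid_mask``
    combines the source recording's mask with filter edge exclusion.
    """

    band: BandDef
    envelope: np.ndarray
    phase: np.ndarray
    valid_mask: np.ndarray
    sampling_rate_hz: float

    @property
    def n_samples(self) -> int:
        return self.envelope.shape[1]


def interpolated_signal(recording: Recording) -> np.ndarray:
    """Working copy of the signal with invalid samples linearly interpolated.

    Used only for filter continuity; statistics must go through the mask.
    """
    x = recording.signal.copy()
    mask = recording.valid_mask
    if mask.all():
        return x
    if not mask.any():
        raise InsufficientDataError("recording has no valid samples")
    idx = np.arange(recording.n_samples)
    for c in range(recording.n_channels):
        x[c, ~mask] = np.interp(idx[~mask], idx[mask], x[c, mask])
    return x


def detect_blanking(
    recording: Recording,
    min_flat_ms: float = 20.0,
    max_flat_ms: float = 200.0,
    guard_ms: float = 8.0,
    tol_fraction: float = 1e-6,
) -> np.ndarray:
    """Find amplifier-blanking gaps: runs flat on *all* channels at once.

    A run is flagged when every channel's sample-to-sample difference stays
    within ``tol_fraction`` of the recording's dynamic range for a duration
    in ``[min_flat_ms, max_flat_ms]``. A guard margin of ``guard_ms`` is
    added on each side. Single-channel flat stretches are physiological and
    are not flagged. Returns a boolean per-sample mask (True = blanked).
    """
    if min_flat_ms > max_flat_ms:
        raise ConfigError(
            f"min_flat_ms ({min_flat_ms}) > max_flat_ms ({max_flat_ms})"
        )
    fs = recording.sampling_rate_hz
    x = recording.signal
    dyn = float(np.ptp(x)) or 1.0
    tol = tol_fraction * dyn
    flat_step = (np.abs(np.diff(x, axis=1)) <= tol).all(axis=0)

    mask = np.zeros(recording.n_samples, dtype=bool)
    guard = int(round(guard_ms * fs / 1000.0))
    # maximal runs of consecutive flat steps; a run of L steps spans L+1 samples
    padded = np.concatenate(([False], flat_step, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    for s, e in zip(starts, ends):
        n_flat = e - s + 1
        dur_ms = n_flat / fs * 1000.0
        if min_flat_ms <= dur_ms <= max_flat_ms:
            lo = max(0, s - guard)
            hi = min(recording.n_samples, e + 1 + guard)
            mask[lo:hi] = True
    return mask


def apply_mask(
    recording: Recording, mask: np.ndarray, mode: str = "exclude"
) -> Recording:
    """AND an exclusion mask into the recording's valid_mask.

    ``mode='exclude'`` leaves sample values untouched (interpolation is done
    lazily where filters need it); ``mode='interpolate'`` additionally
    rewrites masked samples with linear interpolation in the stored signal.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (recording.n_samples,):
        raise ConfigError(
            f"mask length {mask.shape} does not match {recording.n_samples} samples"
        )
    if mode not in ("exclude", "interpolate"):
        raise ConfigError(f"unknown mask mode {mode!r}")
    out = recording.copy_with(valid_mask=recording.valid_mask & ~mask)
    if not out.valid_mask.any():
        raise InsufficientDataError("mask excludes every sample in the recording")
    if mode == "interpolate":
        out.signal = interpolated_signal(out)
    return out


def _validate_band_edges(low: float, high: float, fs: float) -> None:
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ConfigError(
            f"band edges ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )


def notch(
    recording: Recording, center_hz: float, bandwidth_hz: float = 4.0
) -> Recording:
    """Zero-phase band-stop around ``center_hz`` (default 4 Hz wide)."""
    low = center_hz - bandwidth_hz / 2.0
    high = center_hz + bandwidth_hz / 2.0
    _validate_band_edges(low, high, recording.sampling_rate_hz)
    sos = sps.butter(
        4, [low, high], btype="bandstop", fs=recording.sampling_rate_hz, output="sos"
    )
    x = interpolated_signal(recording)
    return recording.copy_with(signal=sps.sosfiltfilt(sos, x, axis=1))


def zscore_recording(recording: Recording) -> Recording:
    """Standardize each channel to mean 0, variance 1 over valid samples.

    Invalid samples are transformed with the same affine map but remain
    invalid. A constant channel is an error (its name is reported).
    """
    mask = recording.valid_mask
    if mask.sum() < 2:
        raise InsufficientDataError("need at least 2 valid samples to z-score")
    valid = recording.signal[:, mask]
    mu = valid.mean(axis=1)
    sd = valid.std(axis=1, ddof=0)
    zero = sd <= 0
    if zero.any():
        names = [recording.channel_labels[i] for i in np.flatnonzero(zero)]
        raise DataError(f"zero variance over valid samples in channel(s) {names}")
    z = (recording.signal - mu[:, None]) / sd[:, None]
    return recording.copy_with(signal=z)


def band_signal(
    recording: Recording,
    band: BandDef,
    order: int = 4,
    edge_margin_s: float | None = None,
) -> BandSignal:
    """Band-pass then analytic-signal transform.

    Envelope is the modulus of the analytic signal, phase its argument.
    ``edge_margin_s`` samples at each end (default six cycles of the band's
    low edge, after which the forward-backward filter transient is < 1%)
    are flagged invalid to hide filter startup.
    """
    fs = recording.sampling_rate_hz
    _validate_band_edges(band.low_hz, band.high_hz, fs)
    if edge_margin_s is None:
        edge_margin_s = 6.0 / band.low_hz
    sos = sps.butter(
        order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    x = interpolated_signal(recording)
    filtered = sps.sosfiltfilt(sos, x, axis=1)
    n = filtered.shape[1]
    analytic = sps.hilbert(filtered, N=next_fast_len(n), axis=1)[:, :n]

    valid = recording.valid_mask.copy()
    margin = int(round(edge_margin_s * fs))
    if margin > 0:
        valid[:margin] = False
        if margin < n:
            valid[n - margin :] = False
        else:
            valid[:] = False
    return BandSignal(
        band=band,
        envelope=np.abs(analytic),
        phase=np.angle(analytic),
        valid_mask=valid,
        sampling_rate_hz=fs,
    )


def standard_preprocess(
    recording: Recording,
    notch_center_hz: float | None = 105.0,
    notch_bandwidth_hz: float = 4.0,
    min_flat_ms: float = 20.0,
    max_flat_ms: float = 200.0,
    guard_ms: float = 8.0,
) -> Recording:
    """Blanking excision -> optional notch -> per-channel z-score."""
    blank = detect_blanking(
        recording, min_flat_ms=min_flat_ms, max_flat_ms=max_flat_ms, guard_ms=guard_ms
    )
    rec = apply_mask(recording, blank)
    if notch_center_hz is not None:
        rec = notch(rec, notch_center_hz, notch_bandwidth_hz)
    return zscore_recording(rec)
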