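"""Phase-locking and amplitude-correlation connectivity, on vs off.

Metrics between hippocampal and temporal-neocortex channels are computed on
paired, duration-matched stimulation-on and stimulation-off intervals of the
same recording and compared with Wilcoxon signed-rank tests, Bonferroni-
corrected across the four channel-pair permutations (adjusted alpha
0.05/4 = 0.0125).

Phase-locking uses instantaneous phases of the analytic signal; amplitude
correlation uses the envelope. Cross-frequency coupling is n:m phase-phase
locking with the integer ratio chosen as the best rational approximation of
the band-center ratio (an optional phase-amplitude mode exists behind a
flag, off by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InsufficientDataError

__all__ = [
    "ConnectivityResult",
    "PairedComparison",
    "plv",
    "nm_ratio",
    "cross_freq_plv",
    "amplitude_correlation",
    "phase_amplitude_coupling",
    "paired_on_off",
    "enhancement_series",
]

MIN_VALID_SAMPLES = 250


@dataclass(frozen=True)
class ConnectivityResult:
    """One paired on/off metric value for a channel pair and band pair."""

    recording_id: str
    channel_pair: tuple[str, str]
    metric: str  # plv | cross_freq_plv | amplitude_corr
    band_a: str
    band_b: str
    value_on: float
    value_off: float


@dataclass(frozen=True)
class PairedComparison:
    metric: str
    channel_pair: str
    bands: str
    n_pairs: int
    test_statistic: float
    p_value: float
    significant: bool
    n_comparisons: int
    alpha_adjusted: float
    median_on: float
    median_off: float
    n_zero_differences: int


def _joint_valid(a: np.ndarray, b: np.ndarray, valid_mask) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigError("input series must have equal length")
    if valid_mask is None:
        return np.ones(a.shape, dtype=bool)
    valid = np.asarray(valid_mask, dtype=bool)
    if valid.shape != a.shape:
        raise ConfigError("valid_mask length must match the series")
    return valid


def plv(phase_a: np.ndarray, phase_b: np.ndarray, valid_mask=None) -> float:
    """Phase-locking value: modulus of the mean unit phasor of the phase
    difference over jointly valid samples. 1 = perfect locking."""
    valid = _joint_valid(phase_a, phase_b, valid_mask)
    if valid.sum() < MIN_VALID_SAMPLES:
        raise InsufficientDataError(
            f"need >= {MIN_VALID_SAMPLES} valid samples for PLV, got {valid.sum()}"
        )
    diff = np.asarray(phase_a)[valid] - np.asarray(phase_b)[valid]
    return float(np.abs(np.exp(1j * diff).mean()))


def nm_ratio(center_a_hz: float, center_b_hz: float, cap: int = 12) -> tuple[int, int]:
    """Smallest integer pair (n, m) with n*f_a ~= m*f_b, i.e. n/m ~= f_b/f_a.

    Uses the best rational approximation with numerator and denominator
    bounded by ``cap``. E.g. theta (7.5 Hz) to beta (20 Hz) gives (8, 3).
    """
    if center_a_hz <= 0 or center_b_hz <= 0:
        raise ConfigError("band centers must be positive")
    frac = Fraction(center_b_hz / center_a_hz).limit_denominator(cap)
    if frac.numerator == 0 or frac.numerator > cap:
        raise ConfigError(
            f"no integer pair within cap {cap} approximates ratio "
            f"{center_b_hz / center_a_hz:.3f}; increase the cap"
        )
    return frac.numerator, frac.denominator


def cross_freq_plv(
    phase_a: np.ndarray,
    center_a_hz: float,
    phase_b: np.ndarray,
    center_b_hz: float,
    valid_mask=None,
    cap: int = 12,
) -> tuple[float, tuple[int, int]]:
    """n:m phase-phase locking |mean exp(i(n*phi_a - m*phi_b))|.

    Returns the value together with the (n, m) pair used, so the ratio is
    documented in downstream output.
    """
    n, m = nm_ratio(center_a_hz, center_b_hz, cap=cap)
    valid = _joint_valid(phase_a, phase_b, valid_mask)
    if valid.sum() < MIN_VALID_SAMPLES:
        raise InsufficientDataError(
            f"need >= {MIN_VALID_SAMPLES} valid samples, got {valid.sum()}"
        )
    diff = n * np.asarray(phase_a)[valid] - m * np.asarray(phase_b)[valid]
    return float(np.abs(np.exp(1j * diff).mean())), (n, m)


def amplitude_correlation(
    env_a: np.ndarray, env_b: np.ndarray, valid_mask=None
) -> float:
    """Pearson correlation of two band envelopes over jointly valid samples."""
    valid = _joint_valid(env_a, env_b, valid_mask)
    if valid.sum() < MIN_VALID_SAMPLES:
        raise InsufficientDataError(
            f"need >= {MIN_VALID_SAMPLES} valid samples, got {valid.sum()}"
        )
    a = np.asarray(env_a, dtype=float)[valid]
    b = np.asarray(env_b, dtype=float)[valid]
    if a.std() <= 0 or b.std() <= 0:
        raise InsufficientDataError("zero-variance envelope in correlation")
    return float(stats.pearsonr(a, b).statistic)


def phase_amplitude_coupling(
    phase_low: np.ndarray, env_high: np.ndarray, valid_mask=None
) -> float:
    """Mean-vector phase-amplitude coupling (optional alternative metric).

    Modulus of the envelope-weighted mean phasor of the low-frequency phase,
    normalised by the mean envelope.
    """
    valid = _joint_valid(phase_low, env_high, valid_mask)
    if valid.sum() < MIN_VALID_SAMPLES:
        raise InsufficientDataError(
            f"need >= {MIN_VALID_SAMPLES} valid samples, got {valid.sum()}"
        )
    ph = np.asarray(phase_low, dtype=float)[valid]
    env = np.asarray(env_high, dtype=float)[valid]
    if env.mean() <= 0:
        raise InsufficientDataError("nonpositive mean envelope")
    return float(np.abs((env * np.exp(1j * ph)).mean()) / env.mean())


def paired_on_off(
    results: Sequence[ConnectivityResult],
    n_comparisons: int = 4,
    alpha: float = 0.05,
) -> PairedComparison:
    """Wilcoxon signed-rank test on per-recording (on, off) value pairs.

    Zero differences are dropped before ranking (classic Wilcoxon
    procedure); their count is reported. Bonferroni-adjusted alpha is
    ``alpha / n_comparisons``.
    """
    if len(results) < 6:
        raise InsufficientDataError(
            f"need at least 6 paired recordings, got {len(results)}"
        )
    on = np.array([r.value_on for r in results])
    off = np.array([r.value_off for r in results])
    diffs = on - off
    n_zero = int(np.sum(diffs == 0))
    alpha_adj = alpha / n_comparisons
    if n_zero == len(diffs):
        warnings.warn("all on/off differences are zero; p set to 1", stacklevel=2)
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(on, off, zero_method="wilcox")
    first = results[0]
    return PairedComparison(
        metric=first.metric,
        channel_pair=f"{first.channel_pair[0]}~{first.channel_pair[1]}",
        bands=(
            first.band_a
            if first.band_a == first.band_b
            else f"{first.band_a}:{first.band_b}"
        ),
        n_pairs=len(results),
        test_statistic=float(stat),
        p_value=float(p),
        significant=bool(p < alpha_adj),
        n_comparisons=n_comparisons,
        alpha_adjusted=alpha_adj,
        median_on=float(np.median(on)),
        median_off=float(np.median(off)),
        n_zero_differences=n_zero,
    )


def enhancement_series(
    results: Sequence[ConnectivityResult],
    catalog: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-recording (on - off) enhancement, ready for trend regression.

    When a catalog frame (recording_id, days_since_implant, dbs_voltage) is
    supplied, dates and voltages are joined on.
    """
    frame = pd.DataFrame(
        {
            "recording_id": [r.recording_id for r in results],
            "metric": [r.metric for r in results],
            "bands": [
                r.band_a if r.band_a == r.band_b else f"{r.band_a}:{r.band_b}"
                for r in results
            ],
            "enhancement": [r.value_on - r.value_off for r in results],
        }
    )
    if catalog is not None:
        cols = [
            c
            for c in ("recording_id", "days_since_implant", "dbs_voltage")
            if c in catalog.columns
        ]
        frame = frame.merge(catalog[cols], on="recording_id", how="left")
    return frame
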