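"""Recording data model and file I/O.

Recordings are 4-channel bipolar intracranial EEG snippets (typically 180 s
"scheduled" captures or up to 15-min streamed segments) sampled at 250 Hz.
The canonical on-disk container is EDF (European Data Format); plain
delimited text with a comment header is accepted for fixtures. Catalogs and
event lists are CSV.

Conventions: within-recording times are seconds from recording start, sample
indices are 0-based, and all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
import io as _stdio
import struct
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError, UnsupportedFormatError

__all__ = [
    "TriggerType",
    "Recording",
    "BandDef",
    "CatalogEntry",
    "DEFAULT_BANDS",
    "DEFAULT_CHANNEL_LABELS",
    "read_recording",
    "write_recording",
    "read_catalog",
    "write_catalog",
    "read_events",
    "write_events",
    "read_intervals",
    "write_intervals",
    "check_catalog_integrity",
]


class TriggerType(str, Enum):
    """Why the sensing device stored a recording."""

    SCHEDULED = "scheduled"
    LONG_EPISODE = "long_episode"
    USER_SAVED = "user_saved"


#: Bipolar montage labels for the two hippocampal and two inferior-temporal
#: gyrus channel pairs.
DEFAULT_CHANNEL_LABELS = ("HPC1-HPC2", "HPC3-HPC4", "ITG1-ITG2", "ITG3-ITG4")

DEFAULT_START_TIME = datetime(2019, 5, 1, 0, 0, 0)


@dataclass(frozen=True)
class BandDef:
    """A named frequency band, half-open in neither sense: [low_hz, high_hz]."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ConfigError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)


#: Canonical analysis bands.
DEFAULT_BANDS = (
    BandDef("delta", 1.0, 5.0),
    BandDef("theta", 5.0, 10.0),
    BandDef("alpha", 10.0, 15.0),
    BandDef("beta", 15.0, 25.0),
    BandDef("low_gamma", 30.0, 40.0),
    BandDef("high_gamma", 70.0, 90.0),
)


def band_by_name(name: str, bands=DEFAULT_BANDS) -> BandDef:
    for b in bands:
        if b.name == name:
            return b
    raise ConfigError(f"unknown band {name!r}; known: {[b.name for b in bands]}")


@dataclass
class Recording:
    """A multichannel ECoG snippet.

    ``signal`` is a (channels x samples) float array in arbitrary
    microvolt-scale units. ``valid_mask`` marks samples usable for
    statistics; False samples (blanked or excised) are interpolated only for
    filter continuity and never contribute to any statistic.
    """

    signal: np.ndarray
    sampling_rate_hz: float
    start_time: datetime = DEFAULT_START_TIME
    trigger_type: TriggerType = TriggerType.SCHEDULED
    channel_labels: tuple[str, ...] = DEFAULT_CHANNEL_LABELS
    valid_mask: np.ndarray | None = None
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ConfigError("signal must be a 2-D (channels x samples) array")
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if isinstance(self.trigger_type, str):
            self.trigger_type = TriggerType(self.trigger_type)
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.n_channels:
            raise ConfigError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.n_samples, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (self.n_samples,):
                raise ConfigError("valid_mask length must equal sample count")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ConfigError(
                f"unknown channel {label!r}; have {self.channel_labels}"
            ) from None

    def copy_with(self, **kw) -> "Recording":
        base = dict(
            signal=self.signal.copy(),
            sampling_rate_hz=self.sampling_rate_hz,
            start_time=self.start_time,
            trigger_type=self.trigger_type,
            channel_labels=self.channel_labels,
            valid_mask=self.valid_mask.copy(),
            recording_id=self.recording_id,
        )
        base.update(kw)
        return Recording(**base)


@dataclass(frozen=True)
class CatalogEntry:
    recording_id: str
    path: str
    start_time: datetime
    trigger_type: TriggerType
    dbs_voltage_V: float
    days_since_implant: float

    def __post_init__(self) -> None:
        if self.dbs_voltage_V < 0:
            raise SchemaError(
                f"{self.recording_id}: negative stimulation voltage"
            )


# ---------------------------------------------------------------------------
# EDF writer/reader
#
# No pre-installed package writes EDF, so a minimal EDF(+C-free) codec lives
# here: 256-byte fixed header, 256 bytes per signal, little-endian int16 data
# records of 1 s each. Physical scaling uses the per-channel min/max, so a
# write->read round trip is exact to one 16-bit quantization step.
# ---------------------------------------------------------------------------


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


_TRIGGER_TAG = "trigger="


def write_edf(recording: Recording, path: str | Path) -> None:
    fs = recording.sampling_rate_hz
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise UnsupportedFormatError(
            f"EDF writer requires an integer sampling rate, got {fs}"
        )
    nch = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / spr))
    padded = np.zeros((nch, n_records * spr))
    padded[:, : recording.n_samples] = recording.signal

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    # guard degenerate flat channels
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((padded - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    st = recording.start_time
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field(
                f"Startdate X X X X {_TRIGGER_TAG}{recording.trigger_type.value}", 80
            ),
            _edf_field(st.strftime("%d.%m.%y"), 8),
            _edf_field(st.strftime("%H.%M.%S"), 8),
            _edf_field(str(256 * (nch + 1)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),
            _edf_field(str(nch), 4),
        ]
    )
    sig_headers = b"".join(
        [
            b"".join(_edf_field(lbl, 16) for lbl in recording.channel_labels),
            b"".join(_edf_field("", 80) for _ in range(nch)),
            b"".join(_edf_field("uV", 8) for _ in range(nch)),
            b"".join(_edf_field(f"{pmin[c]:.6g}"[:8], 8) for c in range(nch)),
            b"".join(_edf_field(f"{pmax[c]:.6g}"[:8], 8) for c in range(nch)),
            b"".join(_edf_field(str(dmin), 8) for _ in range(nch)),
            b"".join(_edf_field(str(dmax), 8) for _ in range(nch)),
            b"".join(_edf_field("", 80) for _ in range(nch)),
            b"".join(_edf_field(str(spr), 8) for _ in range(nch)),
            b"".join(_edf_field("", 32) for _ in range(nch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_headers)
        # record-major, signal-major within record
        rec3d = digital.reshape(nch, n_records, spr).transpose(1, 0, 2)
        fh.write(rec3d.tobytes())


def read_edf(path: str | Path) -> Recording:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise SchemaError(f"{path}: truncated or empty EDF header")
    def fld(off, width):
        return raw[off : off + width].decode("ascii", "replace").strip()

    rec_id = fld(88, 80)
    trigger = TriggerType.SCHEDULED
    for token in rec_id.split():
        if token.startswith(_TRIGGER_TAG):
            trigger = TriggerType(token[len(_TRIGGER_TAG):])
    try:
        start = datetime.strptime(fld(168, 8) + " " + fld(176, 8), "%d.%m.%y %H.%M.%S")
    except ValueError:
        start = DEFAULT_START_TIME
    n_records = int(fld(236, 8))
    record_dur = float(fld(244, 8))
    nch = int(fld(252, 4))

    off = 256
    def sig_fields(width):
        nonlocal off
        vals = [fld(off + i * width, width) for i in range(nch)]
        off += nch * width
        return vals

    labels = sig_fields(16)
    sig_fields(80)  # transducer
    sig_fields(8)  # dimension
    pmin = np.array([float(v) for v in sig_fields(8)])
    pmax = np.array([float(v) for v in sig_fields(8)])
    dmin = np.array([float(v) for v in sig_fields(8)])
    dmax = np.array([float(v) for v in sig_fields(8)])
    sig_fields(80)  # prefiltering
    spr = np.array([int(v) for v in sig_fields(8)])
    sig_fields(32)

    if len(set(spr)) != 1:
        raise UnsupportedFormatError(f"{path}: per-signal sampling rates differ")
    spr0 = int(spr[0])
    fs = spr0 / record_dur
    data_off = 256 * (nch + 1)
    expected = n_records * nch * spr0 * 2
    body = raw[data_off : data_off + expected]
    if len(body) != expected:
        raise SchemaError(f"{path}: EDF data shorter than header declares")
    digital = np.frombuffer(body, dtype="<i2").reshape(n_records, nch, spr0)
    digital = digital.transpose(1, 0, 2).reshape(nch, -1).astype(float)
    scale = (pmax - pmin) / (dmax - dmin)
    signal = (digital - dmin[:, None]) * scale[:, None] + pmin[:, None]
    return Recording(
        signal=signal,
        sampling_rate_hz=fs,
        start_time=start,
        trigger_type=trigger,
        channel_labels=tuple(labels),
    )


# ---------------------------------------------------------------------------
# Delimited-text recordings (fixture format)
# ---------------------------------------------------------------------------

_TEXT_EXT = {".csv", ".tsv", ".txt"}


def write_text_recording(recording: Recording, path: str | Path) -> None:
    path = Path(path)
    delim = "\t" if path.suffix == ".tsv" else ","
    with open(path, "w", newline="") as fh:
        fh.write(f"# sampling_rate_hz={recording.sampling_rate_hz}\n")
        fh.write(f"# start_time={recording.start_time.isoformat()}\n")
        fh.write(f"# trigger_type={recording.trigger_type.value}\n")
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(list(recording.channel_labels))
        for row in recording.signal.T:
            writer.writerow([f"{v:.9g}" for v in row])


def read_text_recording(path: str | Path) -> Recording:
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line.strip():
                body_lines.append(line)
    if not body_lines:
        raise SchemaError(f"{path}: no data rows")
    if "sampling_rate_hz" not in meta:
        raise SchemaError(f"{path}: missing '# sampling_rate_hz=' header line")
    sample = "".join(body_lines[:10])
    delim = "\t" if sample.count("\t") >= sample.count(",") else ","
    frame = pd.read_csv(_stdio.StringIO("".join(body_lines)), sep=delim)
    if frame.shape[0] == 0:
        raise SchemaError(f"{path}: header but no samples")
    return Recording(
        signal=frame.to_numpy().T,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        start_time=(
            datetime.fromisoformat(meta["start_time"])
            if "start_time" in meta
            else DEFAULT_START_TIME
        ),
        trigger_type=TriggerType(meta.get("trigger_type", "scheduled")),
        channel_labels=tuple(str(c) for c in frame.columns),
    )


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: empty file")
    suffix = path.suffix.lower()
    if suffix == ".edf":
        rec = read_edf(path)
    elif suffix in _TEXT_EXT:
        rec = read_text_recording(path)
    else:
        raise UnsupportedFormatError(
            f"{path}: unsupported extension {suffix!r} (expect .edf/.csv/.tsv/.txt)"
        )
    rec.recording_id = path.stem
    return rec


def write_recording(recording: Recording, path: str | Path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        write_edf(recording, path)
    elif suffix in _TEXT_EXT:
        write_text_recording(recording, path)
    else:
        raise UnsupportedFormatError(
            f"{path}: unsupported extension {suffix!r} (expect .edf/.csv/.tsv/.txt)"
        )


# ---------------------------------------------------------------------------
# Catalog / event-list tables
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = (
    "recording_id",
    "path",
    "start_time",
    "trigger_type",
    "dbs_voltage",
    "days_since_implant",
)
EVENT_COLUMNS = ("recording_id", "event_time_s", "event_type")


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_catalog(path: str | Path) -> list[CatalogEntry]:
    """Read the recording catalog, sorted by start time.

    Required columns: recording_id, path, start_time, trigger_type,
    dbs_voltage, days_since_implant.
    """
    frame = pd.read_csv(path)
    _require_columns(frame, CATALOG_COLUMNS, path)
    if frame["recording_id"].duplicated().any():
        dupes = frame.loc[frame["recording_id"].duplicated(), "recording_id"]
        raise SchemaError(f"{path}: duplicate recording_id(s): {sorted(set(dupes))}")
    entries = [
        CatalogEntry(
            recording_id=str(row.recording_id),
            path=str(row.path),
            start_time=pd.Timestamp(row.start_time).to_pydatetime(),
            trigger_type=TriggerType(str(row.trigger_type)),
            dbs_voltage_V=float(row.dbs_voltage),
            days_since_implant=float(row.days_since_implant),
        )
        for row in frame.itertuples()
    ]
    entries.sort(key=lambda e: e.start_time)
    return entries


def write_catalog(entries: list[CatalogEntry], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "recording_id": [e.recording_id for e in entries],
            "path": [e.path for e in entries],
            "start_time": [e.start_time.isoformat() for e in entries],
            "trigger_type": [e.trigger_type.value for e in entries],
            "dbs_voltage": [e.dbs_voltage_V for e in entries],
            "days_since_implant": [e.days_since_implant for e in entries],
        }
    )
    frame.to_csv(path, index=False)


def read_events(
    path: str | Path,
    durations_s: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Read per-recording event times as a tidy frame.

    Columns: recording_id, event_time_s, event_type, valid. When
    ``durations_s`` is given, events beyond a recording's duration are
    flagged invalid (``valid=False``) and a warning is emitted.
    """
    import warnings

    frame = pd.read_csv(path)
    _require_columns(frame, EVENT_COLUMNS, path)
    frame = frame.copy()
    frame["event_time_s"] = frame["event_time_s"].astype(float)
    frame["valid"] = True
    if durations_s is not None:
        for rid, dur in durations_s.items():
            bad = (frame["recording_id"] == rid) & (
                (frame["event_time_s"] < 0) | (frame["event_time_s"] >= dur)
            )
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} event(s) outside [0, {dur}) s in "
                    f"recording {rid}; flagged invalid",
                    stacklevel=2,
                )
                frame.loc[bad, "valid"] = False
    return frame.sort_values(["recording_id", "event_time_s"]).reset_index(drop=True)


def write_events(frame: pd.DataFrame, path: str | Path) -> None:
    frame.loc[:, list(EVENT_COLUMNS)].to_csv(path, index=False)


INTERVAL_COLUMNS = ("recording_id", "start_s", "end_s", "state", "method")


def write_intervals(intervals, path: str | Path) -> None:
    """Write StimIntervals (any iterable of objects with the five fields)."""
    frame = pd.DataFrame(
        {
            "recording_id": [iv.recording_id for iv in intervals],
            "start_s": [iv.start_s for iv in intervals],
            "end_s": [iv.end_s for iv in intervals],
            "state": [iv.state for iv in intervals],
            "method": [iv.method for iv in intervals],
        }
    )
    frame.to_csv(path, index=False)


def read_intervals(path: str | Path):
    from .segment import StimInterval

    frame = pd.read_csv(path)
    _require_columns(frame, INTERVAL_COLUMNS, path)
    return [
        StimInterval(
            recording_id=str(r.recording_id),
            start_s=float(r.start_s),
            end_s=float(r.end_s),
            state=str(r.state),
            method=str(r.method),
        )
        for r in frame.itertuples()
    ]


def check_catalog_integrity(
    entries: list[CatalogEntry], base_dir: str | Path = "."
) -> None:
    """Verify every catalog row points at a readable recording file.

    Run before any pipeline stage touches the data.
    """
    base = Path(base_dir)
    missing = [e.recording_id for e in entries if not (base / e.path).exists()]
    if missing:
        raise SchemaError(
            f"catalog references missing recording file(s) for: {missing}"
        )
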