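"""Readers and writers for the on-disk formats the pipeline touches.

Continuous EEG goes to EDF (16-bit, physical units µV) with event markers in
a BIDS-flavoured tab-separated sidecar ``*_events.tsv`` (columns
``onset_sample``, ``duration``, ``code``; 0-based sample indices, half-open
intervals).  Feature tables (one extracted measure per subject x dose x
timepoint) and metabolite series travel as UTF-8 CSV with a header row and
period decimal separator.

EDF is written by this module (plain EDF, one 1-second data record per
second of signal) and read back through MNE's EDF reader, so round-trips are
checked against an independent parser.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "FeatureRow",
    "EDFParseError",
    "read_edf",
    "write_edf",
    "read_feature_table",
    "write_feature_table",
    "feature_frame",
]

_EVENT_COLUMNS = ["onset_sample", "duration", "code"]
_FEATURE_COLUMNS = [
    "subject_id",
    "dose",
    "timepoint",
    "measure",
    "value",
    "baseline_value",
]


class EDFParseError(ValueError):
    """Raised when an EDF header field cannot be interpreted."""


@dataclass
class EEGRecording:
    """Continuous multi-channel EEG with event markers.

    data : ndarray, shape (n_channels, n_samples), µV
    events : DataFrame with columns onset_sample (0-based), duration
        (samples), code (str); onsets must lie in [0, n_samples).
    """

    fs: float
    channel_labels: list[str]
    data: np.ndarray
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_EVENT_COLUMNS)
    )
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) == 0:
            raise ValueError("channel list is empty")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but {self.data.shape[0]} "
                "data channels"
            )
        ev = pd.DataFrame(self.events)
        if not ev.empty:
            missing = [c for c in _EVENT_COLUMNS if c not in ev.columns]
            if missing:
                raise ValueError(f"events table missing columns {missing}")
            onsets = ev["onset_sample"].to_numpy()
            if np.any(onsets < 0) or np.any(onsets >= self.n_samples):
                raise ValueError(
                    "event onset_sample out of range [0, n_samples)"
                )
        self.events = ev.reset_index(drop=True)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def times_of(self, samples: np.ndarray) -> np.ndarray:
        return np.asarray(samples, dtype=float) / self.fs


# ---------------------------------------------------------------------------
# EDF writing (plain EDF, 16-bit)
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording to EDF plus its ``*_events.tsv`` sidecar.

    Uses 1-second data records, so the recording length must be a whole
    number of seconds and fs a whole number; per-channel physical ranges are
    taken from the data (symmetric, at least ±1 µV), giving a quantization
    step of range/2^16.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    if recording.n_samples % fs != 0:
        raise ValueError(
            "EDF writer requires a whole number of seconds "
            f"({recording.n_samples} samples at {fs} Hz); pad or trim first"
        )
    n_records = recording.n_samples // fs
    n_sig = recording.n_channels

    phys_max = np.maximum(np.max(np.abs(recording.data), axis=1), 1.0)
    phys_max = np.ceil(phys_max * 1.001)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768

    header = b"".join(
        [
            _ascii("0", 8),  # version
            _ascii("X X X X", 80),  # patient id (anonymous)
            _ascii("Startdate X X X X", 80),  # recording id
            _ascii("01.01.20", 8),  # start date
            _ascii("00.00.00", 8),  # start time
            _ascii(256 * (1 + n_sig), 8),  # header bytes
            _ascii("", 44),  # reserved
            _ascii(n_records, 8),
            _ascii("1", 8),  # record duration, seconds
            _ascii(n_sig, 4),
        ]
    )
    header += b"".join(_ascii(lbl, 16) for lbl in recording.channel_labels)
    header += b"".join(_ascii("EEG", 80) for _ in range(n_sig))  # transducer
    header += b"".join(_ascii("uV", 8) for _ in range(n_sig))
    header += b"".join(_ascii(f"{v:g}", 8) for v in phys_min)
    header += b"".join(_ascii(f"{v:g}", 8) for v in phys_max)
    header += b"".join(_ascii(dig_min, 8) for _ in range(n_sig))
    header += b"".join(_ascii(dig_max, 8) for _ in range(n_sig))
    header += b"".join(_ascii("", 80) for _ in range(n_sig))  # prefiltering
    header += b"".join(_ascii(fs, 8) for _ in range(n_sig))
    header += b"".join(_ascii("", 32) for _ in range(n_sig))  # reserved

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_max - gain * dig_max  # EDF linear mapping intercept
    digital = np.round((recording.data - offset[:, None]) / gain[:, None])
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # records: for each second, each signal's fs samples in sequence
        blocks = digital.reshape(n_sig, n_records, fs)
        for r in range(n_records):
            fh.write(blocks[:, r, :].tobytes())

    events_path = events_sidecar_path(path)
    ev = recording.events
    if ev.empty:
        ev = pd.DataFrame(columns=_EVENT_COLUMNS)
    ev[_EVENT_COLUMNS].to_csv(events_path, sep="\t", index=False)
    return path


def events_sidecar_path(edf_path: str | Path) -> Path:
    edf_path = Path(edf_path)
    return edf_path.with_name(edf_path.stem + "_events.tsv")


def _validate_edf_header(path: Path) -> None:
    """Check the fixed EDF header fields, naming the offender on failure."""
    with open(path, "rb") as fh:
        head = fh.read(256)
    if len(head) < 256:
        raise EDFParseError(f"{path}: truncated header (<256 bytes)")
    fields = {
        "version": (0, 8),
        "n_header_bytes": (184, 8),
        "n_records": (236, 8),
        "record_duration": (244, 8),
        "n_signals": (252, 4),
    }
    text = {}
    for name, (start, width) in fields.items():
        raw = head[start : start + width]
        try:
            text[name] = raw.decode("ascii").strip()
        except UnicodeDecodeError as exc:
            raise EDFParseError(f"{path}: field '{name}' is not ASCII") from exc
    if text["version"] != "0":
        raise EDFParseError(
            f"{path}: field 'version' is {text['version']!r}, expected '0'"
        )
    for name in ("n_header_bytes", "n_records", "n_signals"):
        try:
            value = int(text[name])
        except ValueError as exc:
            raise EDFParseError(
                f"{path}: field '{name}' is not an integer: {text[name]!r}"
            ) from exc
        if value <= 0 and name != "n_records":
            raise EDFParseError(f"{path}: field '{name}' must be positive")
    try:
        float(text["record_duration"])
    except ValueError as exc:
        raise EDFParseError(
            f"{path}: field 'record_duration' is not numeric: "
            f"{text['record_duration']!r}"
        ) from exc


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file (via MNE) and its events sidecar into an EEGRecording."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_edf_header(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE yields volts for EEG channels
    events_path = events_sidecar_path(path)
    if events_path.exists():
        events = pd.read_csv(events_path, sep="\t")
    else:
        events = pd.DataFrame(columns=_EVENT_COLUMNS)
    return EEGRecording(
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        data=data_uv,
        events=events,
    )


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureRow:
    """One extracted measure value in one crossover cell.

    ``baseline_value`` repeats the same measure at the session's pretreatment
    baseline and is required for every non-baseline row (it enters the dose
    models as a covariate).
    """

    subject_id: str
    dose: str
    timepoint: str
    measure: str
    value: float
    baseline_value: float | None = None


def feature_frame(rows: list[FeatureRow]) -> pd.DataFrame:
    """Convert FeatureRow records to the canonical long-format DataFrame."""
    df = pd.DataFrame([vars(r) for r in rows], columns=_FEATURE_COLUMNS)
    _validate_feature_frame(df)
    return df


def _validate_feature_frame(df: pd.DataFrame) -> None:
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    key = ["subject_id", "dose", "timepoint", "measure"]
    dup = df.duplicated(subset=key)
    if dup.any():
        offenders = df.loc[dup, key].to_records(index=False).tolist()
        raise ValueError(f"duplicate (subject,dose,timepoint,measure) keys: {offenders}")
    nonbase = df[df["timepoint"] != "baseline"]
    bad = nonbase[nonbase["baseline_value"].isna()]
    if len(bad):
        offenders = bad[key].to_records(index=False).tolist()
        raise ValueError(
            f"baseline_value missing for non-baseline rows: {offenders}"
        )


def write_feature_table(rows, path: str | Path) -> Path:
    """Write FeatureRow records (or an equivalent DataFrame) to CSV."""
    df = rows if isinstance(rows, pd.DataFrame) else feature_frame(list(rows))
    _validate_feature_frame(df)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature-table CSV.

    Unknown measure names pass through untouched: the stats stage is
    measure-agnostic (EEG scores and plasma analytes share one table shape).
    """
    df = pd.read_csv(path)
    _validate_feature_frame(df)
    return df
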