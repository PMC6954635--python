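"""Reading, writing and aligning the session file formats.

A session consists of an EEG recording (CSV with one electrode per column,
optionally EDF), a gaze stream (CSV: ``timestamp_s, x_px, y_px``) and a
therapist event log (CSV: ``timestamp_s, event_label, activity_id``).
All CSVs are comma-separated, UTF-8, '.'-decimal, with a header row.
Times are seconds, session-relative, with the origin at the EEG recording
start.

Readers never silently coerce: every dropped or repaired row increments a
counter stored on the returned object, and malformed input raises
:class:`ParseError` / :class:`FormatError` rather than yielding a partial
recording.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import HEADSET_CHANNELS, headset_for_labels

__all__ = [
    "ParseError",
    "FormatError",
    "AlignmentError",
    "RawEEGRecording",
    "GazeRecording",
    "EventLog",
    "SessionBundle",
    "read_eeg",
    "read_gaze",
    "read_events",
    "write_eeg_csv",
    "write_edf",
    "align_session",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line/field."""


class FormatError(ValueError):
    """A file parsed but violates the format contract (e.g. unknown montage)."""


class AlignmentError(ValueError):
    """EEG and gaze recordings share no overlapping time interval."""


@dataclass
class RawEEGRecording:
    """Multi-channel EEG, channels x time, in the headset's own montage."""

    samples: np.ndarray
    channel_labels: tuple[str, ...]
    sampling_rate: float = 128.0
    start_time: float = 0.0
    participant_id: str = ""
    session_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise FormatError("EEG samples must be a 2-D channels x time array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise FormatError(
                f"{self.samples.shape[0]} signal rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        self.headset = headset_for_labels(self.channel_labels)

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate

    @property
    def time_range(self) -> tuple[float, float]:
        return (self.start_time, self.start_time + self.duration)


@dataclass
class GazeRecording:
    """Eye-tracker stream with strictly increasing timestamps."""

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    screen_size: tuple[int, int] = (1920, 1080)
    participant_id: str = ""
    session_label: str = ""
    n_dropped: int = 0  # rows removed to enforce the invariants

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.timestamps) == len(self.x) == len(self.y)):
            raise FormatError("timestamp/x/y lengths differ")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise FormatError("timestamps not strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def time_range(self) -> tuple[float, float]:
        """Covered interval; the last sample extends one median period."""
        t = self.timestamps
        if len(t) == 0:
            return (0.0, 0.0)
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
        return (float(t[0]), float(t[-1]) + dt)


@dataclass
class EventLog:
    """Therapist events: (timestamp, label, optional activity id 1-8)."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["timestamp_s", "event_label", "activity_id"]
        )
    )

    def __post_init__(self) -> None:
        t = self.entries["timestamp_s"].to_numpy(dtype=float)
        if len(t) > 1 and np.any(np.diff(t) < 0):
            raise FormatError("event timestamps must be non-decreasing")
        ids = pd.to_numeric(self.entries["activity_id"], errors="coerce").dropna()
        if len(ids) and not ids.between(1, 8).all():
            raise FormatError("activity_id out of range [1, 8]")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SessionBundle:
    """Synchronized session: recordings untouched plus the overlap window."""

    eeg: RawEEGRecording
    gaze: GazeRecording
    events: EventLog
    overlap: tuple[float, float]


def _canonical_labels(raw_labels) -> tuple[str, ...]:
    """Map labels to montage spelling, case-insensitively."""
    headset = headset_for_labels(raw_labels)
    spelling = {c.lower(): c for c in HEADSET_CHANNELS[headset]}
    return tuple(spelling[str(c).strip().lower()] for c in raw_labels)


def read_eeg(path: str | Path, format: str | None = None, **meta) -> RawEEGRecording:
    """Read an EEG recording from CSV or EDF.

    ``format`` is inferred from the file suffix when omitted.  The header's
    electrode labels must match one of the two supported montages
    (case-insensitive); anything else raises :class:`FormatError`.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise ParseError(f"{path}: empty or headerless file") from exc
        if df.empty:
            raise ParseError(f"{path}: no sample rows")
        labels = _canonical_labels(df.columns)
        arr = np.empty((len(labels), len(df)))
        for i, col in enumerate(df.columns):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = int(vals.isna().idxmax())
                raise ParseError(
                    f"{path}: non-numeric value in column {col!r} at data row {row}"
                )
            arr[i] = vals.to_numpy()
        return RawEEGRecording(samples=arr, channel_labels=labels, **meta)
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        labels = _canonical_labels(raw.ch_names)
        data = raw.get_data() * 1e6  # mne returns volts; store microvolts
        return RawEEGRecording(
            samples=data,
            channel_labels=labels,
            sampling_rate=float(raw.info["sfreq"]),
            **meta,
        )
    raise ValueError(f"unknown EEG format {fmt!r}; expected 'csv' or 'edf'")


def read_gaze(path: str | Path, screen_size=(1920, 1080), **meta) -> GazeRecording:
    """Read a gaze CSV, enforcing strictly increasing timestamps.

    Rows that step backwards in time (or repeat a timestamp) and rows with
    non-finite coordinates are dropped; the count is recorded in
    ``n_dropped``.  Non-numeric fields raise :class:`ParseError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty or headerless file") from exc
    required = ["timestamp_s", "x_px", "y_px"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    cols = {}
    for c in required:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        if bad.any():
            raise ParseError(
                f"{path}: non-numeric value in column {c!r} at data row "
                f"{int(bad.idxmax())}"
            )
        cols[c] = vals.to_numpy(dtype=float)
    t, x, y = cols["timestamp_s"], cols["x_px"], cols["y_px"]
    finite = np.isfinite(t) & np.isfinite(x) & np.isfinite(y)
    # keep the longest prefix-greedy strictly increasing subsequence
    keep = np.zeros(len(t), dtype=bool)
    last = -np.inf
    for i in range(len(t)):
        if finite[i] and t[i] > last:
            keep[i] = True
            last = t[i]
    n_dropped = int(len(t) - keep.sum())
    return GazeRecording(
        timestamps=t[keep],
        x=x[keep],
        y=y[keep],
        screen_size=tuple(screen_size),
        n_dropped=n_dropped,
        **meta,
    )


def read_events(path: str | Path) -> EventLog:
    """Read a therapist event log CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return EventLog()
    required = ["timestamp_s", "event_label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if "activity_id" not in df.columns:
        df["activity_id"] = np.nan
    return EventLog(entries=df[["timestamp_s", "event_label", "activity_id"]])


def write_eeg_csv(path: str | Path, samples: np.ndarray, channel_labels) -> None:
    """Write channels x time EEG to CSV (one column per electrode)."""
    pd.DataFrame(np.asarray(samples).T, columns=list(channel_labels)).to_csv(
        Path(path), index=False, float_format="%.4f"
    )


def write_edf(
    path: str | Path,
    samples: np.ndarray,
    channel_labels,
    sampling_rate: float = 128.0,
    physical_dim: str = "uV",
) -> None:
    """Write a minimal EDF file (16-bit, one signal per electrode).

    One data record per second; the trailing partial record, if any, is
    zero-padded.  Physical scaling is per-signal min/max mapped onto the
    full digital range.
    """
    samples = np.asarray(samples, dtype=float)
    n_chan, n_samp = samples.shape
    spr = int(round(sampling_rate))  # samples per 1-s record
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_chan, n_rec * spr))
    padded[:, :n_samp] = samples

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max <= phys_min
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    def fld(value, width) -> bytes:
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    now = _dt.datetime(2020, 1, 1)
    header = b"".join(
        [
            fld("0", 8),
            fld("X X X X", 80),
            fld("Startdate 01-JAN-2020 X X X", 80),
            fld(now.strftime("%d.%m.%y"), 8),
            fld(now.strftime("%H.%M.%S"), 8),
            fld(256 * (1 + n_chan), 8),
            fld("", 44),
            fld(n_rec, 8),
            fld("1", 8),
            fld(n_chan, 4),
        ]
    )
    sig_fields = [
        (16, [str(c) for c in channel_labels]),
        (80, ["" for _ in range(n_chan)]),
        (8, [physical_dim] * n_chan),
        (8, [f"{v:.6g}" for v in phys_min]),
        (8, [f"{v:.6g}" for v in phys_max]),
        (8, [str(dig_min)] * n_chan),
        (8, [str(dig_max)] * n_chan),
        (80, ["" for _ in range(n_chan)]),
        (8, [str(spr)] * n_chan),
        (32, ["" for _ in range(n_chan)]),
    ]
    header += b"".join(
        fld(v, width) for width, values in sig_fields for v in values
    )

    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((padded - phys_min[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def align_session(
    eeg: RawEEGRecording, gaze: GazeRecording, events: EventLog | None = None
) -> SessionBundle:
    """Place EEG and gaze on a common session clock and record their overlap.

    The overlap interval (intersection of the two time ranges) is what the
    epoching stage partitions; both recordings are carried untouched.
    Disjoint ranges raise :class:`AlignmentError`.
    """
    e0, e1 = eeg.time_range
    g0, g1 = gaze.time_range
    lo, hi = max(e0, g0), min(e1, g1)
    if hi <= lo:
        raise AlignmentError(
            f"EEG [{e0}, {e1}] and gaze [{g0}, {g1}] do not overlap"
        )
    return SessionBundle(eeg=eeg, gaze=gaze, events=events or EventLog(), overlap=(lo, hi))
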