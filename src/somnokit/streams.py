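"""Domain types, validation and delimited-text I/O for sleep-session recordings.

A session is one night of multi-channel data on a shared 1 Hz time base:
eight pillow pressure channels (force-sensitive resistors laid out left to
right under the head), a sound-pressure level in dB, contactless body
temperature, room temperature, relative humidity, CO2 concentration, and
optionally illuminance and a wrist heart rate.  Time is integer seconds
since session start; all derived event intervals are half-open
``[start, end)`` on that grid.

Storage is RFC-4180 CSV with a fixed header vocabulary
(``t, p0..p7, sound_db, body_temp_c, room_temp_c, humidity_pct, co2_ppm,
lux, hr_bpm``), UTF-8, '.' decimal separator; gzip-compressed variants are
accepted anywhere a path is.  Event lists and hypnograms serialize to JSON.
"""

from __future__ import annotations

import gzip
import io
import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_PRESSURE_SENSORS",
    "PRESSURE_COLUMNS",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "SessionParseError",
    "ValidationError",
    "Posture",
    "Stage",
    "EventKind",
    "PressureFrame",
    "Event",
    "Hypnogram",
    "SessionRecord",
    "read_session",
    "write_session",
    "validate_session",
    "validate_events",
    "events_to_json",
    "events_from_json",
]

N_PRESSURE_SENSORS = 8

PRESSURE_COLUMNS = tuple(f"p{i}" for i in range(N_PRESSURE_SENSORS))
#: canonical CSV header, in order
REQUIRED_COLUMNS = ("t", *PRESSURE_COLUMNS, "sound_db", "body_temp_c",
                    "room_temp_c", "humidity_pct", "co2_ppm")
OPTIONAL_COLUMNS = ("lux", "hr_bpm")

#: plausible physical ranges used by validate_session
TEMP_RANGE_C = (-40.0, 300.0)
HEART_RATE_RANGE_BPM = (0.0, 300.0)  # open interval


class SessionParseError(ValueError):
    """Raised when a session file cannot be parsed into a SessionRecord."""


class ValidationError(ValueError):
    """Raised for structurally invalid inputs (e.g. non-monotone time)."""


class Posture(str, Enum):
    """Head posture on the pillow.

    ``OFF_PILLOW`` means the total frame pressure is below the presence
    threshold (no head on the pillow); the three lying postures are the
    ones the eight-sensor array can discriminate.
    """

    SUPINE = "supine"
    LEFT = "left"
    RIGHT = "right"
    OFF_PILLOW = "off_pillow"


class Stage(str, Enum):
    """Two-stage sleep label plus wake."""

    NREM = "nrem"
    REM = "rem"
    WAKE = "wake"


class EventKind(str, Enum):
    TOSS_TURN = "toss_turn"
    SNORE = "snore"
    BRADYCARDIA = "bradycardia"
    TACHYCARDIA = "tachycardia"
    POSTURE_CHANGE = "posture_change"


@dataclass(frozen=True)
class PressureFrame:
    """One timestamped vector of the 8 pillow pressure readings.

    ``t`` is seconds since session start on the 1 Hz grid; ``p`` holds the
    readings in sensor order, index 0 the leftmost sensor and 7 the
    rightmost, in arbitrary non-negative force units.
    """

    t: int
    p: tuple[float, ...]

    def __post_init__(self) -> None:
        p = tuple(float(v) for v in self.p)
        object.__setattr__(self, "p", p)
        if len(p) != N_PRESSURE_SENSORS:
            raise ValidationError(
                f"pressure frame needs exactly {N_PRESSURE_SENSORS} readings, "
                f"got {len(p)}"
            )
        if any(v < 0 for v in p):
            raise ValidationError("pressure readings must be non-negative")
        if self.t < 0:
            raise ValidationError("frame time must be >= 0")

    @property
    def total(self) -> float:
        return float(sum(self.p))


@dataclass
class Event:
    """A typed half-open interval ``[start, end)`` on the session timeline.

    ``attrs`` carries kind-specific scalars, e.g. ``peak_delta`` for a
    toss-and-turn, ``peak_db`` and onset-to-onset ``interval_s`` for a
    snore burst.
    """

    kind: EventKind
    start: int
    end: int
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = EventKind(self.kind)
        self.start = int(self.start)
        self.end = int(self.end)
        if self.end <= self.start:
            raise ValidationError(
                f"event interval must satisfy end > start, got "
                f"[{self.start}, {self.end})"
            )

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class Hypnogram:
    """Epoch-indexed sequence of sleep-stage labels.

    ``labels[k]`` covers seconds ``[k*epoch_len, (k+1)*epoch_len)``; the
    final epoch may cover a partial tail of the session.
    """

    labels: list[Stage]
    epoch_len: int = 60

    def __post_init__(self) -> None:
        if self.epoch_len <= 0:
            raise ValidationError("epoch_len must be > 0")
        self.labels = [Stage(s) for s in self.labels]

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    def stage_per_second(self, duration_s: int) -> list[Stage]:
        """Expand epoch labels to a per-second stage track of given length."""
        if duration_s > self.n_epochs * self.epoch_len:
            raise ValidationError("hypnogram does not cover requested duration")
        return [self.labels[t // self.epoch_len] for t in range(duration_s)]

    def to_json(self) -> str:
        return json.dumps(
            {"epoch_len": self.epoch_len,
             "labels": [s.value for s in self.labels]},
            sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Hypnogram":
        obj = json.loads(text)
        return cls(labels=[Stage(s) for s in obj["labels"]],
                   epoch_len=int(obj["epoch_len"]))


def _as_channel(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"channel {name} must be one-dimensional")
    return arr


@dataclass
class SessionRecord:
    """Aligned 1 Hz multi-channel recording of one night.

    All present channels share one time base (sample ``t`` is second ``t``
    since session start) and equal length.  ``lux`` and ``heart_rate`` are
    optional and are ``None`` when the sensor was absent — never
    zero-filled.  Construction coerces dtypes but does not range-check;
    use :func:`validate_session` for a full report.
    """

    pressure: np.ndarray          # (n, 8)
    sound_db: np.ndarray
    body_temp: np.ndarray         # °C
    room_temp: np.ndarray         # °C
    humidity: np.ndarray          # %
    co2: np.ndarray               # ppm
    lux: np.ndarray | None = None
    heart_rate: np.ndarray | None = None
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.pressure.ndim != 2 or self.pressure.shape[1] != N_PRESSURE_SENSORS:
            raise ValidationError(
                f"pressure must have {N_PRESSURE_SENSORS} columns, got shape "
                f"{self.pressure.shape}"
            )
        for name in ("sound_db", "body_temp", "room_temp", "humidity", "co2"):
            setattr(self, name, _as_channel(getattr(self, name), name))
        for name in ("lux", "heart_rate"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, _as_channel(v, name))

    def __len__(self) -> int:
        return self.pressure.shape[0]

    @property
    def duration_s(self) -> int:
        return len(self)

    def channels(self) -> dict[str, np.ndarray]:
        """Present 1-D channels by name (pressure excluded)."""
        out = {"sound_db": self.sound_db, "body_temp": self.body_temp,
               "room_temp": self.room_temp, "humidity": self.humidity,
               "co2": self.co2}
        if self.lux is not None:
            out["lux"] = self.lux
        if self.heart_rate is not None:
            out["heart_rate"] = self.heart_rate
        return out

    def frame(self, t: int) -> PressureFrame:
        return PressureFrame(t=t, p=tuple(self.pressure[t]))

    def __eq__(self, other) -> bool:
        if not isinstance(other, SessionRecord):
            return NotImplemented
        if len(self) != len(other) or self.start_time != other.start_time:
            return False
        if not np.array_equal(self.pressure, other.pressure):
            return False
        a, b = self.channels(), other.channels()
        if a.keys() != b.keys():
            return False
        return all(np.array_equal(a[k], b[k]) for k in a)


# ---------------------------------------------------------------------------
# validation

def validate_session(rec: SessionRecord) -> list[str]:
    """Check every type invariant; return violations, never raise.

    Each violation names the channel, sample index (where applicable) and
    the rule broken.  An empty list means the record is valid.
    """
    out: list[str] = []
    n = len(rec)
    for name, arr in rec.channels().items():
        if arr.shape[0] != n:
            out.append(
                f"{name}: length {arr.shape[0]} != pressure length {n} "
                f"(all channels must share one 1 Hz time base)")
    bad = np.nonzero(rec.pressure < 0)[0]
    if bad.size:
        out.append(f"pressure[{int(bad[0])}]: negative reading")
    for name in ("body_temp", "room_temp"):
        arr = getattr(rec, name)
        lo, hi = TEMP_RANGE_C
        bad = np.nonzero((arr < lo) | (arr > hi))[0]
        if bad.size:
            out.append(
                f"{name}[{int(bad[0])}]: value {arr[bad[0]]:g} outside "
                f"[{lo:g}, {hi:g}] °C")
    bad = np.nonzero(rec.co2 < 0)[0]
    if bad.size:
        out.append(f"co2[{int(bad[0])}]: negative concentration")
    if rec.heart_rate is not None:
        lo, hi = HEART_RATE_RANGE_BPM
        bad = np.nonzero(~((rec.heart_rate > lo) & (rec.heart_rate < hi)))[0]
        if bad.size:
            out.append(
                f"heart_rate[{int(bad[0])}]: value {rec.heart_rate[bad[0]]:g} "
                f"outside open range ({lo:g}, {hi:g}) bpm")
    for name, arr in rec.channels().items():
        bad = np.nonzero(~np.isfinite(arr))[0]
        if bad.size:
            out.append(f"{name}[{int(bad[0])}]: non-finite sample")
    return out


def validate_events(events: Sequence[Event]) -> list[str]:
    """Check the Event-list invariants for a single kind.

    Events must be sorted by start, pairwise non-overlapping, and of one
    kind.  Returns violations; empty list means valid.
    """
    out: list[str] = []
    kinds = {e.kind for e in events}
    if len(kinds) > 1:
        out.append(f"mixed event kinds in one list: {sorted(k.value for k in kinds)}")
    for i in range(1, len(events)):
        if events[i].start < events[i - 1].start:
            out.append(f"events[{i}]: not sorted by start")
        if events[i].start < events[i - 1].end:
            out.append(f"events[{i}]: overlaps previous event")
    return out


# ---------------------------------------------------------------------------
# CSV I/O

def _open_text(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t", encoding="utf-8", newline="")
    return open(path, mode, encoding="utf-8", newline="")


_START_PREFIX = "# start_time="


def read_session(path, schema: dict[str, str] | None = None) -> SessionRecord:
    """Read a session CSV (optionally gzipped) into a SessionRecord.

    ``schema`` optionally maps canonical column names (``p0`` .. ``hr_bpm``)
    to the header names actually present in the file.  Missing optional
    columns yield absent channels.  Raises :class:`SessionParseError` for
    malformed rows (naming the line) and :class:`ValidationError` for
    non-monotone timestamps or missing required columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path, "r") as fh:
        first = fh.readline()
        start_time = None
        if first.startswith(_START_PREFIX):
            start_time = datetime.fromisoformat(first[len(_START_PREFIX):].strip())
            body = fh.read()
        else:
            body = first + fh.read()
    try:
        df = pd.read_csv(io.StringIO(body), float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise SessionParseError(f"malformed CSV in {path.name}: {exc}") from exc

    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)

    missing_p = [c for c in PRESSURE_COLUMNS if c not in df.columns]
    if missing_p:
        present = len(PRESSURE_COLUMNS) - len(missing_p)
        raise ValidationError(
            f"expected {N_PRESSURE_SENSORS} pressure columns p0..p7, found "
            f"{present} (missing {', '.join(missing_p)})")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {', '.join(missing)}")

    def numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = vals.isna() & ~raw_na
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            line = int(bad.idxmax()) + 2 + (1 if start_time is not None else 0)
            raise SessionParseError(
                f"malformed value in column {col!r} at line {line} of {path.name}")
        if raw_na.any():
            idx = int(raw_na.idxmax())
            raise SessionParseError(
                f"missing value in column {col!r} at row {idx} of {path.name}; "
                "gaps must be imputed upstream")
        return vals.to_numpy(dtype=float)

    t = numeric("t")
    if len(t) and (np.any(np.diff(t) <= 0) or np.any(t != np.round(t))):
        raise ValidationError("timestamps must be strictly increasing integers")

    pressure = np.column_stack([numeric(c) for c in PRESSURE_COLUMNS]) \
        if len(df) else np.empty((0, N_PRESSURE_SENSORS))

    def optional(col: str) -> np.ndarray | None:
        return numeric(col) if col in df.columns else None

    return SessionRecord(
        pressure=pressure,
        sound_db=numeric("sound_db"),
        body_temp=numeric("body_temp_c"),
        room_temp=numeric("room_temp_c"),
        humidity=numeric("humidity_pct"),
        co2=numeric("co2_ppm"),
        lux=optional("lux"),
        heart_rate=optional("hr_bpm"),
        start_time=start_time,
    )


def write_session(rec: SessionRecord, path) -> None:
    """Write a SessionRecord to CSV (gzipped when the path ends in .gz).

    Numeric fields round-trip bit-exactly through :func:`read_session`
    (floats are written at full repr precision).  Absent optional channels
    are omitted from the header.
    """
    path = Path(path)
    n = len(rec)
    cols: dict[str, object] = {"t": np.arange(n, dtype=int)}
    for i, c in enumerate(PRESSURE_COLUMNS):
        cols[c] = rec.pressure[:, i]
    cols["sound_db"] = rec.sound_db
    cols["body_temp_c"] = rec.body_temp
    cols["room_temp_c"] = rec.room_temp
    cols["humidity_pct"] = rec.humidity
    cols["co2_ppm"] = rec.co2
    if rec.lux is not None:
        cols["lux"] = rec.lux
    if rec.heart_rate is not None:
        cols["hr_bpm"] = rec.heart_rate
    df = pd.DataFrame(cols)
    with _open_text(path, "w") as fh:
        if rec.start_time is not None:
            fh.write(f"{_START_PREFIX}{rec.start_time.isoformat()}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# JSON event serialization

def events_to_json(events: Iterable[Event]) -> str:
    payload = [
        {"kind": e.kind.value, "start": e.start, "end": e.end,
         "attrs": {k: (None if isinstance(v, float) and math.isnan(v) else v)
                   for k, v in sorted(e.attrs.items())}}
        for e in events
    ]
    return json.dumps(payload, sort_keys=True, indent=2)


def events_from_json(text: str) -> list[Event]:
    return [Event(kind=EventKind(o["kind"]), start=o["start"], end=o["end"],
                  attrs=dict(o.get("attrs") or {}))
            for o in json.loads(text)]
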