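"""Telemetry parsing, channel alignment and labelled-recording IO.

The insole transmits one JSON message per pressure sample::

    {"timestamp": "2020-10-25T17:12:24:6847", "data": [x1, ..., x16]}

Note the device's timestamp dialect: a colon separates the seconds from the
fractional part.  Both that dialect and standard dot notation are accepted;
the package always emits ISO-8601 with a dot.

Temperature and acceleration arrive on a separate, slightly delayed stream;
:func:`align_channels` assigns to each pressure timestamp the most recent
auxiliary reading at or before it (last observation carried forward), so all
twenty channels share the pressure clock.
"""

from __future__ import annotations

import json
import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from gaitcascade.events import (
    CHANNELS,
    CSV_CHANNEL_COLUMNS,
    EventLabel,
)

logger = logging.getLogger(__name__)

N_PRESSURE = 16


class SchemaError(ValueError):
    """A telemetry message violates the wire schema; ``field`` names the culprit."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


_TS_RE = re.compile(
    r"^(?:(?P<date>\d{4}-\d{2}-\d{2})T)?"
    r"(?P<h>\d{2}):(?P<m>\d{2}):(?P<s>\d{2})"
    r"(?:[:.](?P<frac>\d{1,6}))?$"
)


def parse_timestamp(raw: str) -> datetime:
    """Parse a device timestamp in either separator dialect.

    Accepts ``[YYYY-MM-DDT]HH:MM:SS[:ffff]`` and ``[YYYY-MM-DDT]HH:MM:SS[.ffff]``.
    The fractional field is read as a decimal fraction of a second.  Time-only
    stamps are anchored at 1970-01-01.
    """
    m = _TS_RE.match(raw.strip())
    if m is None:
        raise SchemaError("timestamp", f"unparseable timestamp {raw!r}")
    date = m.group("date") or "1970-01-01"
    frac = m.group("frac") or "0"
    micros = int(round(int(frac) / 10 ** len(frac) * 1e6))
    base = datetime.fromisoformat(
        f"{date}T{m.group('h')}:{m.group('m')}:{m.group('s')}"
    )
    return base.replace(microsecond=micros)


def format_timestamp(ts: datetime) -> str:
    """Render an instant as ISO-8601 with a dot before the fraction."""
    return ts.strftime("%Y-%m-%dT%H:%M:%S.%f")


@dataclass(frozen=True)
class SensorMessage:
    """One raw pressure sample off the wire: an instant plus 16 readings."""

    timestamp: datetime
    pressures: tuple[float, ...]

    def __post_init__(self):
        if len(self.pressures) != N_PRESSURE:
            raise SchemaError(
                "data", f"expected {N_PRESSURE} pressure values, got {len(self.pressures)}"
            )
        if any(p < 0 for p in self.pressures):
            raise SchemaError("data", "pressure readings must be non-negative")


@dataclass(frozen=True)
class SensorFrame:
    """One time-aligned reading of all 20 channels, in canonical order."""

    timestamp: datetime
    pressures: tuple[float, ...]
    temperature: float
    acceleration: tuple[float, float, float]

    def __post_init__(self):
        if len(self.pressures) != N_PRESSURE:
            raise SchemaError(
                "pressures", f"expected {N_PRESSURE} values, got {len(self.pressures)}"
            )
        if len(self.acceleration) != 3:
            raise SchemaError("acceleration", "expected 3 axis readings")
        if any(p < 0 for p in self.pressures):
            raise SchemaError("pressures", "pressure readings must be non-negative")

    def values(self) -> np.ndarray:
        """The frame as a length-20 vector in canonical channel order."""
        return np.array(
            list(self.pressures) + [self.temperature] + list(self.acceleration),
            dtype=float,
        )


@dataclass
class Recording:
    """A labelled, time-ordered run of frames from one data-collection bout.

    The collection protocol tags a whole recording with a single event, so
    every frame (and every window cut from it) inherits that label.
    """

    recording_id: str
    subject_id: str
    event: EventLabel
    frames: list[SensorFrame] = field(default_factory=list)
    nominal_rate: float = 4.0

    def __post_init__(self):
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(
                f"recording {self.recording_id!r}: frame timestamps must be "
                "strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.frames)

    def to_matrix(self) -> np.ndarray:
        """All frames stacked as an (n_frames, 20) array in channel order."""
        if not self.frames:
            return np.empty((0, len(CHANNELS)))
        return np.stack([f.values() for f in self.frames])


def parse_message(raw: str) -> SensorMessage:
    """Parse one JSON telemetry message into a :class:`SensorMessage`.

    Raises :class:`SchemaError` naming the offending field for a missing key,
    wrong-length data array or unparseable timestamp.
    """
    try:
        obj = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise SchemaError("message", f"invalid JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise SchemaError("message", "expected a JSON object")
    if "timestamp" not in obj:
        raise SchemaError("timestamp", "missing key")
    if "data" not in obj:
        raise SchemaError("data", "missing key")
    data = obj["data"]
    if not isinstance(data, list) or len(data) != N_PRESSURE:
        raise SchemaError(
            "data",
            f"expected an array of {N_PRESSURE} values, got "
            f"{len(data) if isinstance(data, list) else type(data).__name__}",
        )
    ts = parse_timestamp(str(obj["timestamp"]))
    try:
        pressures = tuple(float(x) for x in data)
    except (TypeError, ValueError) as exc:
        raise SchemaError("data", f"non-numeric pressure value: {exc}") from exc
    return SensorMessage(timestamp=ts, pressures=pressures)


def serialize_message(msg: SensorMessage) -> str:
    """Serialize a message back to the wire schema (dot timestamp dialect)."""
    return json.dumps(
        {"timestamp": format_timestamp(msg.timestamp), "data": list(msg.pressures)}
    )


def read_ndjson(path) -> list[SensorMessage]:
    """Read a newline-delimited JSON stream of telemetry messages."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(parse_message(line))
    return out


def write_ndjson(messages: Iterable[SensorMessage], path) -> None:
    with open(path, "w") as fh:
        for msg in messages:
            fh.write(serialize_message(msg) + "\n")


AuxReading = tuple[datetime, float, tuple[float, float, float]]


def align_channels(
    pressure_stream: Sequence[SensorMessage],
    aux_stream: Sequence[AuxReading],
) -> list[SensorFrame]:
    """Merge the delayed temperature/acceleration stream onto the pressure clock.

    Each pressure message becomes a :class:`SensorFrame` carrying the auxiliary
    reading whose timestamp is nearest at-or-before the pressure timestamp.
    Pressure messages arriving before any auxiliary reading cannot be completed
    and are dropped (the count is logged) — a bounded head loss analogous to
    discarding the warm-up frames of a recording.
    """
    if not pressure_stream:
        return []
    aux_times = [a[0] for a in aux_stream]
    frames: list[SensorFrame] = []
    dropped = 0
    for msg in pressure_stream:
        idx = bisect_right(aux_times, msg.timestamp) - 1
        if idx < 0:
            dropped += 1
            continue
        _, temp, accel = aux_stream[idx]
        frames.append(
            SensorFrame(
                timestamp=msg.timestamp,
                pressures=msg.pressures,
                temperature=temp,
                acceleration=tuple(accel),
            )
        )
    if dropped:
        logger.warning(
            "align_channels: dropped %d head frame(s) with no prior auxiliary reading",
            dropped,
        )
    return frames


_REQUIRED_COLUMNS = ("recording_id", "subject_id", "event", "timestamp") + CSV_CHANNEL_COLUMNS


def load_recordings(path) -> list[Recording]:
    """Load labelled recordings from the canonical CSV schema.

    One row per frame with columns ``recording_id, subject_id, event,
    timestamp, p0..p15, temp, ax, ay, az``.  Rows are grouped by recording id
    and time-sorted; event labels are validated against the closed six-event
    set; duplicate timestamps within a recording are an error.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    recordings = []
    for rid, group in df.groupby("recording_id", sort=False):
        events = group["event"].unique()
        if len(events) > 1:
            raise ValueError(
                f"recording {rid!r} carries multiple event labels: {sorted(events)}"
            )
        event = EventLabel.from_string(str(events[0]))
        subjects = group["subject_id"].unique()
        group = group.sort_values("timestamp", kind="stable")
        timestamps = [parse_timestamp(str(t)) for t in group["timestamp"]]
        if any(b <= a for a, b in zip(timestamps, timestamps[1:])):
            raise ValueError(
                f"recording {rid!r}: non-monotone (duplicate) timestamps after sorting"
            )
        values = group[list(CSV_CHANNEL_COLUMNS)].to_numpy(dtype=float)
        frames = [
            SensorFrame(
                timestamp=ts,
                pressures=tuple(row[:16]),
                temperature=float(row[16]),
                acceleration=(float(row[17]), float(row[18]), float(row[19])),
            )
            for ts, row in zip(timestamps, values)
        ]
        recordings.append(
            Recording(
                recording_id=str(rid),
                subject_id=str(subjects[0]),
                event=event,
                frames=frames,
            )
        )
    return recordings


def save_recordings(recordings: Sequence[Recording], path) -> None:
    """Write recordings to the canonical CSV schema (inverse of load_recordings)."""
    rows = []
    for rec in recordings:
        for f in rec.frames:
            row = {
                "recording_id": rec.recording_id,
                "subject_id": rec.subject_id,
                "event": str(rec.event),
                "timestamp": format_timestamp(f.timestamp),
            }
            vals = f.values()
            row.update({col: vals[i] for i, col in enumerate(CSV_CHANNEL_COLUMNS)})
            rows.append(row)
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(path, index=False)
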