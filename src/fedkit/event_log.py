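"""Canonical event-log data model and CSV I/O.

A pellet-dispenser device logs one row per behavioral event: a nose-poke on
the left or right port, or the removal of a food pellet from the feeding
well.  Each row carries cumulative counters and, for pellet events, the
latency from dispense to removal ("retrieval time").

The on-disk format is the *fedkit dialect*: UTF-8 CSV, comma-separated,
mandatory header::

    timestamp,device_id,session_type,event,active_poke,left_count,right_count,pellet_count,retrieval_time,operant

Timestamps are timezone-naive ISO-8601 at 1 s resolution
(``YYYY-MM-DDTHH:MM:SS``).  ``retrieval_time`` is empty for poke rows.
``operant`` is ``True``/``False``; pokes made while a pellet occupied the
well (or outside a feeding window) are recorded with ``operant=False``
rather than dropped, so analyses can include or exclude them.

Session-level metadata that does not fit the row schema (light cycle,
pellet mass, recording start/end) lives in an optional YAML sidecar file
``<log>.meta.yaml`` written and read alongside the CSV.
"""

from __future__ import annotations

import csv
import io
import math
import os
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Iterable, Optional

import pandas as pd
import yaml

__all__ = [
    "Event",
    "SessionLog",
    "LightCycle",
    "LogFormatError",
    "LogValidationError",
    "CANONICAL_HEADER",
    "read_log",
    "write_log",
    "slice_by_time",
    "split_by_day",
]

CANONICAL_HEADER = [
    "timestamp",
    "device_id",
    "session_type",
    "event",
    "active_poke",
    "left_count",
    "right_count",
    "pellet_count",
    "retrieval_time",
    "operant",
]

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"

EVENT_KINDS = ("LeftPoke", "RightPoke", "Pellet")
PORTS = ("Left", "Right")


class LogFormatError(ValueError):
    """The file does not conform to the canonical CSV dialect."""


class LogValidationError(ValueError):
    """Rows parse but violate the data-model invariants."""

    def __init__(self, message: str, rows: Optional[list[int]] = None):
        super().__init__(message)
        self.rows = rows or []


@dataclass(frozen=True)
class LightCycle:
    """Vivarium illumination schedule.

    ``lights_on``/``lights_off`` are clock hours in [0, 24).  Phase
    assignment uses the half-open convention: an instant is *light* iff its
    clock time falls in ``[lights_on, lights_off)`` (wrapping across
    midnight when ``lights_on > lights_off``); everything else is dark.
    """

    lights_on: float = 7.0
    lights_off: float = 19.0

    def __post_init__(self):
        for name in ("lights_on", "lights_off"):
            v = getattr(self, name)
            if not (0 <= v < 24):
                raise ValueError(f"{name} must be in [0, 24), got {v}")
        if self.lights_on == self.lights_off:
            raise ValueError("lights_on and lights_off must differ")

    def is_light(self, t: datetime) -> bool:
        h = t.hour + t.minute / 60 + t.second / 3600 + t.microsecond / 3.6e9
        on, off = self.lights_on, self.lights_off
        if on < off:
            return on <= h < off
        return h >= on or h < off


@dataclass(frozen=True)
class Event:
    """One timestamped device occurrence.

    ``retrieval_time`` (seconds, >= 0) is present iff ``event_kind`` is
    ``"Pellet"``.  Cumulative counters reflect the totals *as of* this
    event (i.e. they include it).
    """

    timestamp: datetime
    event_kind: str
    active_poke: str
    left_count: int
    right_count: int
    pellet_count: int
    retrieval_time: Optional[float] = None
    operant: bool = True

    def __post_init__(self):
        if self.event_kind not in EVENT_KINDS:
            raise ValueError(f"unknown event_kind {self.event_kind!r}")
        if self.active_poke not in PORTS:
            raise ValueError(f"unknown active_poke {self.active_poke!r}")
        if (self.retrieval_time is not None) != (self.event_kind == "Pellet"):
            raise ValueError(
                "retrieval_time must be present iff event_kind is Pellet"
            )
        if self.retrieval_time is not None and self.retrieval_time < 0:
            raise ValueError("retrieval_time must be non-negative")
        for name in ("left_count", "right_count", "pellet_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def is_poke(self) -> bool:
        return self.event_kind in ("LeftPoke", "RightPoke")

    @property
    def is_active_poke(self) -> bool:
        return self.is_poke and self.event_kind == f"{self.active_poke}Poke"


@dataclass
class SessionLog:
    """An ordered sequence of events plus session metadata.

    ``start_time``/``end_time`` bound the recording window; when absent
    they default to the first/last event timestamps.  Cumulative counters
    in sliced logs are deliberately *not* renumbered, so a slice remains
    traceable to its parent recording.
    """

    device_id: int = 0
    session_type: str = "FreeFeeding"
    light_cycle: LightCycle = field(default_factory=LightCycle)
    pellet_mass_mg: float = 20.0
    events: list[Event] = field(default_factory=list)
    start_time: Optional[datetime] = None
    end_time: Optional[datetime] = None

    def __len__(self) -> int:
        return len(self.events)

    @property
    def n_pellets(self) -> int:
        return sum(1 for e in self.events if e.event_kind == "Pellet")

    @property
    def pellet_times(self) -> list[datetime]:
        return [e.timestamp for e in self.events if e.event_kind == "Pellet"]

    def span(self) -> tuple[datetime, datetime]:
        """Recording window: explicit metadata, else the event extent."""
        if self.start_time is not None and self.end_time is not None:
            return self.start_time, self.end_time
        if not self.events:
            raise ValueError("empty log with no start/end metadata has no span")
        start = self.start_time or self.events[0].timestamp
        end = self.end_time or self.events[-1].timestamp
        return start, end

    def duration_days(self) -> float:
        start, end = self.span()
        return (end - start).total_seconds() / 86400.0

    def validate(self) -> None:
        """Raise :class:`LogValidationError` on the first broken invariant."""
        if self.pellet_mass_mg <= 0:
            raise LogValidationError("pellet_mass_mg must be positive")
        prev_t = None
        counts = {"LeftPoke": 0, "RightPoke": 0, "Pellet": 0}
        bad_rows: list[int] = []
        for i, e in enumerate(self.events):
            if prev_t is not None and e.timestamp < prev_t:
                bad_rows.append(i)
            prev_t = e.timestamp
        if bad_rows:
            raise LogValidationError(
                f"decreasing timestamps at event indices {bad_rows}", rows=bad_rows
            )
        for i, e in enumerate(self.events):
            counts[e.event_kind] += 1
            expect = (counts["LeftPoke"], counts["RightPoke"], counts["Pellet"])
            got = (e.left_count, e.right_count, e.pellet_count)
            if expect != got:
                raise LogValidationError(
                    f"cumulative counters wrong at event index {i}: "
                    f"expected {expect}, got {got}",
                    rows=[i],
                )

    def to_frame(self) -> pd.DataFrame:
        """Events as a pandas DataFrame (one row per event)."""
        return pd.DataFrame(
            {
                "timestamp": [e.timestamp for e in self.events],
                "event": [e.event_kind for e in self.events],
                "active_poke": [e.active_poke for e in self.events],
                "left_count": [e.left_count for e in self.events],
                "right_count": [e.right_count for e in self.events],
                "pellet_count": [e.pellet_count for e in self.events],
                "retrieval_time": [e.retrieval_time for e in self.events],
                "operant": [e.operant for e in self.events],
            }
        )


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_bool(s: str, line: int) -> bool:
    if s == "True":
        return True
    if s == "False":
        return False
    raise LogFormatError(f"line {line}: operant must be True/False, got {s!r}")


def read_log(
    path: str | os.PathLike,
    *,
    light_cycle: Optional[LightCycle] = None,
    pellet_mass_mg: Optional[float] = None,
    validate: bool = True,
) -> SessionLog:
    """Read a canonical CSV log (and its sidecar metadata, if present).

    Explicit ``light_cycle``/``pellet_mass_mg`` arguments override the
    sidecar.  Malformed headers raise :class:`LogFormatError` naming the
    column; bad rows raise row-level errors with 1-based line numbers;
    invariant violations raise :class:`LogValidationError` listing the
    offending rows.
    """
    path = os.fspath(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LogFormatError(f"{path}: file is empty (missing header)")
        if header != CANONICAL_HEADER:
            missing = [c for c in CANONICAL_HEADER if c not in header]
            extra = [c for c in header if c not in CANONICAL_HEADER]
            detail = []
            if missing:
                detail.append(f"missing column(s) {missing}")
            if extra:
                detail.append(f"unknown column(s) {extra}")
            if not detail:
                detail.append("columns out of order")
            raise LogFormatError(f"{path}: bad header: {'; '.join(detail)}")

        events: list[Event] = []
        device_id = 0
        session_type = "FreeFeeding"
        errors: list[str] = []
        bad_rows: list[int] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CANONICAL_HEADER):
                errors.append(f"line {lineno}: expected {len(CANONICAL_HEADER)} fields, got {len(row)}")
                bad_rows.append(lineno)
                continue
            (ts_s, dev_s, sess, kind, active, lc_s, rc_s, pc_s, rt_s, op_s) = row
            try:
                ts = datetime.strptime(ts_s, TIMESTAMP_FORMAT)
            except ValueError:
                errors.append(f"line {lineno}: unparseable timestamp {ts_s!r}")
                bad_rows.append(lineno)
                continue
            try:
                ev = Event(
                    timestamp=ts,
                    event_kind=kind,
                    active_poke=active,
                    left_count=int(lc_s),
                    right_count=int(rc_s),
                    pellet_count=int(pc_s),
                    retrieval_time=float(rt_s) if rt_s != "" else None,
                    operant=_parse_bool(op_s, lineno),
                )
            except (ValueError, LogFormatError) as exc:
                errors.append(f"line {lineno}: {exc}")
                bad_rows.append(lineno)
                continue
            device_id = int(dev_s)
            session_type = sess
            events.append(ev)
        if errors:
            raise LogValidationError(
                f"{path}: {len(errors)} bad row(s):\n  " + "\n  ".join(errors),
                rows=bad_rows,
            )

    meta = _read_sidecar(path)
    log = SessionLog(
        device_id=device_id,
        session_type=session_type,
        light_cycle=light_cycle
        or meta.get("light_cycle")
        or LightCycle(),
        pellet_mass_mg=pellet_mass_mg
        if pellet_mass_mg is not None
        else meta.get("pellet_mass_mg", 20.0),
        events=events,
        start_time=meta.get("start_time"),
        end_time=meta.get("end_time"),
    )
    if validate:
        log.validate()
    return log


def _sidecar_path(path: str) -> str:
    return f"{path}.meta.yaml"


def _read_sidecar(path: str) -> dict:
    sc = _sidecar_path(path)
    if not os.path.exists(sc):
        return {}
    with open(sc, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    meta: dict = {}
    if "lights_on" in raw and "lights_off" in raw:
        meta["light_cycle"] = LightCycle(raw["lights_on"], raw["lights_off"])
    if "pellet_mass_mg" in raw:
        meta["pellet_mass_mg"] = float(raw["pellet_mass_mg"])
    for key in ("start_time", "end_time"):
        if raw.get(key):
            meta[key] = datetime.strptime(raw[key], TIMESTAMP_FORMAT)
    return meta


def _format_retrieval(rt: Optional[float]) -> str:
    if rt is None:
        return ""
    # repr() of a float is the shortest string that round-trips exactly,
    # which keeps write->read->write byte-identical.
    return repr(float(rt))


def write_log(log: SessionLog, path: str | os.PathLike, *, sidecar: bool = True) -> None:
    """Write a log in the canonical dialect; refuses invalid logs.

    With ``sidecar=True`` (default) a ``<path>.meta.yaml`` file records the
    light cycle, pellet mass and recording window.
    """
    log.validate()
    path = os.fspath(path)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CANONICAL_HEADER)
    for e in log.events:
        writer.writerow(
            [
                e.timestamp.strftime(TIMESTAMP_FORMAT),
                log.device_id,
                log.session_type,
                e.event_kind,
                e.active_poke,
                e.left_count,
                e.right_count,
                e.pellet_count,
                _format_retrieval(e.retrieval_time),
                "True" if e.operant else "False",
            ]
        )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())
    if sidecar:
        meta = {
            "lights_on": log.light_cycle.lights_on,
            "lights_off": log.light_cycle.lights_off,
            "pellet_mass_mg": log.pellet_mass_mg,
            "start_time": log.start_time.strftime(TIMESTAMP_FORMAT)
            if log.start_time
            else None,
            "end_time": log.end_time.strftime(TIMESTAMP_FORMAT)
            if log.end_time
            else None,
        }
        with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
            yaml.safe_dump(meta, fh, default_flow_style=False, sort_keys=True)


# ---------------------------------------------------------------------------
# Slicing


def slice_by_time(log: SessionLog, start: datetime, end: datetime) -> SessionLog:
    """Events with ``start <= timestamp < end`` (half-open).

    Metadata is preserved and cumulative counters are *not* renumbered.
    """
    if start > end:
        raise ValueError(f"start {start} is after end {end}")
    events = [e for e in log.events if start <= e.timestamp < end]
    return replace(log, events=events, start_time=start, end_time=end)


def split_by_day(log: SessionLog, day_boundary: float = 0.0) -> list[SessionLog]:
    """Partition into consecutive 24-h windows anchored at ``day_boundary``.

    ``day_boundary`` is a clock hour in [0, 24).  The concatenation of the
    parts reproduces the original event sequence.  Returns [] for an empty
    log.
    """
    if not (0 <= day_boundary < 24):
        raise ValueError("day_boundary must be a clock hour in [0, 24)")
    if not log.events:
        return []
    first = log.events[0].timestamp
    anchor = first.replace(
        hour=int(day_boundary),
        minute=int(round((day_boundary % 1) * 60)),
        second=0,
        microsecond=0,
    )
    if anchor > first:
        anchor -= timedelta(days=1)
    last = log.events[-1].timestamp
    n_days = math.floor((last - anchor).total_seconds() / 86400.0) + 1
    parts = []
    for k in range(n_days):
        lo = anchor + timedelta(days=k)
        hi = lo + timedelta(days=1)
        part = [e for e in log.events if lo <= e.timestamp < hi]
        parts.append(replace(log, events=part, start_time=lo, end_time=hi))
    return parts
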