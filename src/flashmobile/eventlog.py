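"""Domain types and lossless I/O for device event streams.

A mobile device under study emits a time-stamped stream of five event kinds:
app moved to foreground, app moved to background, screen unlock, screen lock,
and the user's answer to the identification prompt ("child" or "other").
Timestamps are integer milliseconds since the Unix epoch (UTC) and all
intervals derived from them are half-open ``[start, end)``.

Two interchange formats are supported, JSON Lines and CSV; both round-trip
bit-exactly through :func:`write_event_log` / :func:`read_event_log`.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "EventKind",
    "Responder",
    "ProtocolVersion",
    "RawEvent",
    "EventLog",
    "canonical_sort_key",
    "normalize_events",
    "read_event_log",
    "write_event_log",
    "EventLogParseError",
]


class EventKind(str, Enum):
    FOREGROUND = "FOREGROUND"
    BACKGROUND = "BACKGROUND"
    UNLOCK = "UNLOCK"
    LOCK = "LOCK"
    IDENTIFY = "IDENTIFY"


class Responder(str, Enum):
    CHILD = "child"
    OTHER = "other"
    NONE = "none"


class ProtocolVersion(str, Enum):
    """Identification-prompt protocol.

    V1: modal prompt at unlock that must be answered before the device can
    be used. V2: notification banner at unlock plus a re-prompt after every
    15 minutes of continuous use. V3: banner at unlock only.
    """

    V1 = "V1"
    V2 = "V2"
    V3 = "V3"


# Tie-break priority for events sharing a timestamp: a lock closes open
# intervals before a new session (or a new app) can open at the same instant.
_KIND_PRIORITY = {
    EventKind.LOCK: 0,
    EventKind.BACKGROUND: 1,
    EventKind.FOREGROUND: 2,
    EventKind.UNLOCK: 3,
    EventKind.IDENTIFY: 4,
}


class EventLogParseError(ValueError):
    """Raised when an on-disk event log fails to parse or validate."""


@dataclass(frozen=True, order=False)
class RawEvent:
    """One time-stamped device event.

    Parameters
    ----------
    t : int
        Milliseconds since epoch, UTC. Non-negative.
    kind : EventKind
        One of FOREGROUND, BACKGROUND, UNLOCK, LOCK, IDENTIFY.
    app_id : str
        Reverse-DNS package name; required (nonempty) for FOREGROUND and
        BACKGROUND, empty otherwise.
    responder : Responder
        Meaningful only for IDENTIFY events (child or other); NONE otherwise.
    """

    t: int
    kind: EventKind
    app_id: str = ""
    responder: Responder = Responder.NONE

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"negative timestamp {self.t}")
        if self.kind in (EventKind.FOREGROUND, EventKind.BACKGROUND):
            if not self.app_id:
                raise ValueError(f"{self.kind.value} event requires app_id")
        elif self.app_id:
            raise ValueError(f"{self.kind.value} event must have empty app_id")
        if self.kind is EventKind.IDENTIFY:
            if self.responder is Responder.NONE:
                raise ValueError("IDENTIFY event requires responder child|other")
        elif self.responder is not Responder.NONE:
            raise ValueError(f"{self.kind.value} event must have responder=none")


def canonical_sort_key(e: RawEvent) -> tuple:
    """Deterministic total-order key: ascending t, then
    LOCK < BACKGROUND < FOREGROUND < UNLOCK < IDENTIFY, then app_id/responder
    so that equal-content logs sort identically regardless of input order."""
    return (e.t, _KIND_PRIORITY[e.kind], e.app_id, e.responder.value)


@dataclass
class EventLog:
    """An ordered device event stream over an observation window.

    ``span`` is the half-open observation window ``[t_start, t_end)`` in
    milliseconds. After :func:`normalize_events`, events are sorted by the
    canonical order and UNLOCK/LOCK strictly alternate.
    """

    device_id: str
    protocol_version: ProtocolVersion
    events: list[RawEvent] = field(default_factory=list)
    span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.span[1] < self.span[0]:
            raise ValueError(f"span end {self.span[1]} before start {self.span[0]}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        return (
            self.device_id == other.device_id
            and self.protocol_version == other.protocol_version
            and self.span == other.span
            and self.events == other.events
        )


def normalize_events(
    events: Iterable[RawEvent], span: tuple[int, int]
) -> list[RawEvent]:
    """Sort events canonically and repair UNLOCK/LOCK alternation.

    Repairs, each logged as a warning:

    * a second UNLOCK with no intervening LOCK gets a synthetic LOCK
      inserted at the offending UNLOCK's timestamp (the tie rule places it
      first);
    * a LOCK with no open UNLOCK is dropped;
    * a dangling UNLOCK at end of log gets a synthetic LOCK at span end.

    Idempotent: normalizing a normalized sequence is the identity. Because a
    synthetic LOCK shares its timestamp with the UNLOCK that triggered it
    (and sorts before it), the sort+repair pass is iterated to a fixpoint.
    """
    current = sorted(events, key=canonical_sort_key)
    for _ in range(10):  # converges in <= 2 passes in practice
        out: list[RawEvent] = []
        unlocked = False
        open_t = -1
        for e in current:
            if e.kind is EventKind.UNLOCK:
                if unlocked and e.t == open_t:
                    # same-instant duplicate: a LOCK here could not sort
                    # between the two UNLOCKs, so drop the duplicate
                    logger.warning("duplicate UNLOCK at t=%d dropped", e.t)
                    continue
                if unlocked:
                    logger.warning(
                        "UNLOCK at t=%d with session still open; "
                        "inserting synthetic LOCK",
                        e.t,
                    )
                    out.append(RawEvent(t=e.t, kind=EventKind.LOCK))
                unlocked = True
                open_t = e.t
            elif e.kind is EventKind.LOCK:
                if not unlocked:
                    logger.warning("LOCK at t=%d with no open session; dropped", e.t)
                    continue
                unlocked = False
            out.append(e)
        if unlocked:
            logger.warning(
                "log ends with open session; inserting synthetic LOCK at "
                "span end t=%d",
                span[1],
            )
            out.append(RawEvent(t=span[1], kind=EventKind.LOCK))
        out.sort(key=canonical_sort_key)
        if out == current:
            return out
        current = out
    return current


def _default_span(events: Sequence[RawEvent]) -> tuple[int, int]:
    if not events:
        return (0, 0)
    return (min(e.t for e in events), max(e.t for e in events))


# ---------------------------------------------------------------------------
# serialization

_FIELDS = ("t", "kind", "app_id", "responder")


def _event_to_record(e: RawEvent) -> dict:
    return {
        "t": e.t,
        "kind": e.kind.value,
        "app_id": e.app_id,
        "responder": e.responder.value,
    }


def _event_from_record(rec: dict, lineno: int) -> RawEvent:
    try:
        kind = EventKind(rec["kind"])
    except (KeyError, ValueError) as exc:
        raise EventLogParseError(f"line {lineno}: unknown or missing kind: {exc}")
    try:
        return RawEvent(
            t=int(rec["t"]),
            kind=kind,
            app_id=str(rec.get("app_id", "") or ""),
            responder=Responder(rec.get("responder", "none") or "none"),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise EventLogParseError(f"line {lineno}: malformed record: {exc}")


def write_event_log(log: EventLog, path: str | Path, format: str = "jsonl") -> Path:
    """Write an event log to ``path``; returns the path written.

    JSONL: a first-line header object (device_id, protocol_version, span)
    followed by one event object per line. CSV: RFC-4180 with a header row;
    device metadata goes to a ``<path>.meta.json`` sidecar.
    """
    path = Path(path)
    meta = {
        "device_id": log.device_id,
        "protocol_version": log.protocol_version.value,
        "span": list(log.span),
    }
    if format == "jsonl":
        with path.open("w") as fh:
            fh.write(json.dumps({"header": meta}) + "\n")
            for e in log.events:
                fh.write(json.dumps(_event_to_record(e)) + "\n")
    elif format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS)
            writer.writeheader()
            for e in log.events:
                writer.writerow(_event_to_record(e))
        Path(str(path) + ".meta.json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_event_log(path: str | Path, format: str = "jsonl") -> EventLog:
    """Read and normalize an event log written by :func:`write_event_log`.

    Raises :class:`EventLogParseError` naming the offending line on a
    malformed record. An empty file yields an empty log with zero-width span.
    """
    path = Path(path)
    meta: dict = {}
    records: list[RawEvent] = []
    if format == "jsonl":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise EventLogParseError(f"line {lineno}: invalid JSON: {exc}")
                if "header" in obj:
                    meta = obj["header"]
                    continue
                records.append(_event_from_record(obj, lineno))
    elif format == "csv":
        sidecar = Path(str(path) + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                records.append(_event_from_record(row, lineno))
    else:
        raise ValueError(f"unknown format {format!r}")

    span = tuple(meta.get("span", _default_span(records)))  # type: ignore[assignment]
    log = EventLog(
        device_id=str(meta.get("device_id", "")),
        protocol_version=ProtocolVersion(meta.get("protocol_version", "V3")),
        events=normalize_events(records, span),
        span=span,
    )
    return log
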