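"""Unlock-session reconstruction and per-interval user attribution.

Given a normalized event log, this module (1) pairs FOREGROUND/BACKGROUND
events into app-use intervals, (2) groups intervals and identification
responses into unlock sessions (UNLOCK..LOCK), and (3) labels every
millisecond of app use as ``child``, ``other`` or ``unidentified``.

Labeling rules within a session: with no response all use is unidentified;
the first response's label applies retroactively from the unlock instant
(the prompt fires at unlock, so use before a latent answer is credited to
the eventual responder — configurable via ``retroactive=False``); any later
response (the 15-minute re-prompts of protocol V2) relabels from its own
timestamp forward, splitting intervals at that point. Labels never cross a
LOCK.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction

from .eventlog import EventKind, EventLog, ProtocolVersion

logger = logging.getLogger(__name__)

__all__ = [
    "UserLabel",
    "AppInterval",
    "UnlockSession",
    "AttributedInterval",
    "pair_intervals",
    "segment_sessions",
    "attribute",
    "use_durations",
    "use_durations_ms",
]


class UserLabel(str, Enum):
    CHILD = "child"
    OTHER = "other"
    UNIDENTIFIED = "unidentified"


@dataclass(frozen=True)
class AppInterval:
    """Half-open app foreground interval ``[start, end)`` in ms."""

    app_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def duration_ms(self) -> int:
        return self.end - self.start


@dataclass
class UnlockSession:
    """One UNLOCK..LOCK period with its responses and app intervals.

    ``synthetic`` flags a catch-all session holding intervals that fell
    outside every real session (should not occur in simulator output).
    """

    unlock_t: int
    lock_t: int
    responses: list[tuple[int, UserLabel]] = field(default_factory=list)
    intervals: list[AppInterval] = field(default_factory=list)
    synthetic: bool = False


@dataclass(frozen=True)
class AttributedInterval:
    app_id: str
    start: int
    end: int
    user: UserLabel

    @property
    def duration_ms(self) -> int:
        return self.end - self.start


def pair_intervals(log: EventLog) -> list[AppInterval]:
    """Pair foreground/background events into non-overlapping app intervals.

    A FOREGROUND of app B while A is open closes A at B's start (single
    foreground app at a time); LOCK or span end closes any open interval.
    A BACKGROUND with no matching open FOREGROUND is ignored with a warning.
    """
    intervals: list[AppInterval] = []
    open_app: str | None = None
    open_t = 0

    def close(at: int) -> None:
        nonlocal open_app
        if open_app is not None and at > open_t:
            intervals.append(AppInterval(open_app, open_t, at))
        open_app = None

    for e in log.events:
        if e.kind is EventKind.FOREGROUND:
            close(e.t)
            open_app, open_t = e.app_id, e.t
        elif e.kind is EventKind.BACKGROUND:
            if open_app == e.app_id:
                close(e.t)
            else:
                logger.warning(
                    "BACKGROUND(%s) at t=%d with no open FOREGROUND; ignored",
                    e.app_id,
                    e.t,
                )
        elif e.kind is EventKind.LOCK:
            close(e.t)
    close(log.span[1])
    return intervals


def segment_sessions(
    log: EventLog, intervals: list[AppInterval]
) -> list[UnlockSession]:
    """Group intervals and IDENTIFY responses into unlock sessions.

    Every interval and response lands in exactly one session, decided by its
    start/event time lying in ``[unlock_t, lock_t)``. Orphans (outside every
    session) go to a flagged synthetic session with no responses; orphan
    responses are dropped from the compliance denominator and logged.
    """
    sessions: list[UnlockSession] = []
    unlock_t: int | None = None
    for e in log.events:
        if e.kind is EventKind.UNLOCK:
            unlock_t = e.t
        elif e.kind is EventKind.LOCK and unlock_t is not None:
            if e.t > unlock_t:
                sessions.append(UnlockSession(unlock_t=unlock_t, lock_t=e.t))
            unlock_t = None

    def find(t: int) -> UnlockSession | None:
        for s in sessions:
            if s.unlock_t <= t < s.lock_t:
                return s
        return None

    orphans = UnlockSession(
        unlock_t=log.span[0], lock_t=max(log.span[1], log.span[0] + 1),
        synthetic=True,
    )
    for e in log.events:
        if e.kind is EventKind.IDENTIFY:
            s = find(e.t)
            label = UserLabel(e.responder.value)
            if s is None:
                logger.warning(
                    "IDENTIFY(%s) at t=%d outside any unlock session; excluded",
                    label.value,
                    e.t,
                )
            else:
                s.responses.append((e.t, label))
    for iv in intervals:
        s = find(iv.start)
        (s if s is not None else orphans).intervals.append(iv)
    if orphans.intervals:
        logger.warning(
            "%d app interval(s) outside any unlock session; attached to a "
            "flagged synthetic session",
            len(orphans.intervals),
        )
        sessions.append(orphans)
    for s in sessions:
        s.responses.sort()
        s.intervals.sort(key=lambda iv: iv.start)
    return sessions


def _session_label_breakpoints(
    s: UnlockSession, retroactive: bool
) -> list[tuple[int, UserLabel]]:
    """(start_time, label) change points covering [unlock_t, lock_t)."""
    if not s.responses or s.synthetic:
        return [(s.unlock_t, UserLabel.UNIDENTIFIED)]
    points: list[tuple[int, UserLabel]] = []
    first_t, first_label = s.responses[0]
    if retroactive:
        points.append((s.unlock_t, first_label))
    else:
        points.append((s.unlock_t, UserLabel.UNIDENTIFIED))
        points.append((first_t, first_label))
    for t, label in s.responses[1:]:
        points.append((t, label))
    return points


def attribute(
    sessions: list[UnlockSession],
    version: ProtocolVersion = ProtocolVersion.V3,
    *,
    retroactive: bool = True,
) -> list[AttributedInterval]:
    """Label each app interval, splitting where the session label changes.

    ``version`` is accepted for provenance; V1 and V3 behave identically
    here (one response per session), and V2 differs only in that sessions
    may carry multiple responses, each relabeling from its own time forward.
    Zero-length fragments from coincident breakpoints are dropped.
    """
    out: list[AttributedInterval] = []
    for s in sessions:
        points = _session_label_breakpoints(s, retroactive)
        for iv in s.intervals:
            # active label at iv.start, then each later change point splits
            cuts: list[tuple[int, UserLabel]] = []
            current = points[0][1]
            for t, label in points:
                if t <= iv.start:
                    current = label
                elif t < iv.end:
                    cuts.append((t, label))
            bounds = [iv.start] + [t for t, _ in cuts] + [iv.end]
            labels = [current] + [lab for _, lab in cuts]
            for a, b, lab in zip(bounds[:-1], bounds[1:], labels):
                if b > a:
                    out.append(AttributedInterval(iv.app_id, a, b, lab))
    out.sort(key=lambda ai: (ai.start, ai.end))
    return out


def use_durations_ms(attributed: list[AttributedInterval]) -> dict[UserLabel, int]:
    """Exact per-label totals in integer milliseconds."""
    totals = {label: 0 for label in UserLabel}
    for ai in attributed:
        totals[ai.user] += ai.duration_ms
    return totals


def use_durations(attributed: list[AttributedInterval]) -> dict[UserLabel, Fraction]:
    """Per-label total seconds as exact rationals (ms / 1000).

    child + other + unidentified equals total use exactly; callers wanting
    floats can convert at the edge.
    """
    return {
        label: Fraction(ms, 1000) for label, ms in use_durations_ms(attributed).items()
    }
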