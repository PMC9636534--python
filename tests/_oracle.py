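"""Independent per-second replay oracle.

Re-derives device-side labels, durations, compliance counts and confusion
matrices by brute-force per-second state replay — no interval arithmetic,
no code shared with the package's attribution/agreement paths. All
simulator output lives on a whole-second lattice, so oracle counts must
match the package exactly.
"""

from __future__ import annotations

import numpy as np

from flashmobile.agreement import AgreementClass, collapse_gold
from flashmobile.eventlog import EventKind, EventLog

CLASS_ORDER = [
    AgreementClass.CHILD_USE,
    AgreementClass.OTHER_USE,
    AgreementClass.UNIDENTIFIED,
    AgreementClass.NO_USE,
]


def replay_device_labels(log: EventLog, retroactive: bool = True) -> list[str]:
    """One label per second of the span: 'child_use' / 'other_use' /
    'unidentified' / 'no_use', from a forward per-second state machine plus
    a per-session retroactive fix-up pass."""
    t0, t1 = log.span
    n = (t1 - t0) // 1000
    # second-indexed event buckets
    buckets: dict[int, list] = {}
    for e in log.events:
        buckets.setdefault((e.t - t0) // 1000, []).append(e)

    labels = ["no_use"] * n
    session_id = [-1] * n
    app_open = [False] * n

    unlocked = False
    cur_app = None
    sid = -1
    session_responses: dict[int, list[tuple[int, str]]] = {}
    for s in range(n):
        for e in sorted(buckets.get(s, []), key=lambda e: (e.t, _prio(e))):
            if e.kind is EventKind.UNLOCK:
                unlocked = True
                sid += 1
                session_responses[sid] = []
            elif e.kind is EventKind.LOCK:
                unlocked = False
                cur_app = None
            elif e.kind is EventKind.FOREGROUND:
                cur_app = e.app_id
            elif e.kind is EventKind.BACKGROUND:
                if cur_app == e.app_id:
                    cur_app = None
            elif e.kind is EventKind.IDENTIFY and unlocked:
                session_responses[sid].append((s, e.responder.value))
        if unlocked:
            session_id[s] = sid
        if cur_app is not None:
            app_open[s] = True

    for s in range(n):
        if not app_open[s]:
            continue
        my = session_id[s]
        if my < 0:
            labels[s] = "unidentified"
            continue
        resp = session_responses.get(my, [])
        lab = None
        for rt, rlab in resp:
            if rt <= s:
                lab = rlab
        if lab is None and resp and retroactive:
            lab = resp[0][1]  # first answer covers the pre-answer stretch
        labels[s] = {"child": "child_use", "other": "other_use", None: "unidentified"}[lab]
    return labels


def _prio(e) -> int:
    order = {
        EventKind.LOCK: 0,
        EventKind.BACKGROUND: 1,
        EventKind.FOREGROUND: 2,
        EventKind.UNLOCK: 3,
        EventKind.IDENTIFY: 4,
    }
    return order[e.kind]


def replay_durations_s(log: EventLog) -> dict[str, int]:
    """Per-label seconds of app use, by counting replayed seconds."""
    counts = {"child": 0, "other": 0, "unidentified": 0}
    for lab in replay_device_labels(log):
        if lab == "child_use":
            counts["child"] += 1
        elif lab == "other_use":
            counts["other"] += 1
        elif lab == "unidentified":
            counts["unidentified"] += 1
    return counts


def replay_compliance(log: EventLog) -> tuple[int, int]:
    """(n_unlocks, n_answered_sessions) counted straight off the stream."""
    n_unlocks = 0
    answered = 0
    in_session_answered = False
    unlocked = False
    for e in log.events:
        if e.kind is EventKind.UNLOCK:
            if unlocked and in_session_answered:
                answered += 1
            n_unlocks += 1
            unlocked = True
            in_session_answered = False
        elif e.kind is EventKind.LOCK:
            if unlocked and in_session_answered:
                answered += 1
            unlocked = False
            in_session_answered = False
        elif e.kind is EventKind.IDENTIFY and unlocked:
            in_session_answered = True
    if unlocked and in_session_answered:
        answered += 1
    return n_unlocks, answered


def gold_labels_per_second(timeline, span) -> list[str]:
    """Collapsed gold class per second, by point lookup at each second."""
    t0, t1 = span
    n = (t1 - t0) // 1000
    out = []
    for s in range(n):
        t = t0 + s * 1000
        lab = "no_use"
        for seg in timeline.segments:
            if seg.start <= t < seg.end:
                lab = collapse_gold(seg.code).value
                break
        out.append(lab)
    return out


def confusion_from_labels(gold: list[str], device: list[str]) -> np.ndarray:
    conf = np.zeros((4, 4), dtype=np.int64)
    idx = {c.value: i for i, c in enumerate(CLASS_ORDER)}
    for g, d in zip(gold, device):
        if g == "excluded":
            continue
        conf[idx[g], idx[d]] += 1
    return conf
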