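"""Household device-sharing simulator.

Generates paired (ground-truth timeline, device event log) corpora that
emulate the measurement situation: one mobile device shared by a child and
one or more other household members, unlock-triggered identification
prompts answered probabilistically (with occasional wrong answers), an
idle auto screen lock, app sessions drawn from a catalog of seven
categories, joint viewing ("coviewing"), multitasking, audio-only use, and
brief (<3 s) gaze diversions during screen use.

The behavioral model is deliberately minimal: each user generates device
pickups via exponential waiting times (one holder at a time); a pickup is a
log-normal-length run of consecutive app sessions followed by an idle
period that ends in an automatic lock. All generated event times are whole
seconds — the gold standard this emulates is second-scale duration coding —
stored as integer milliseconds.

Identification-prompt mechanics by protocol version: a prompt fires at
every unlock (all versions); V2 re-prompts after every 15 minutes of
continuous use; V1's prompt is modal, so an unanswered V1 prompt means the
pickup produces no app use at all, and an answered one delays app use until
after the response.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from .agreement import GoldCode, GoldSegment, GoldTimeline
from .eventlog import (
    EventKind,
    EventLog,
    ProtocolVersion,
    RawEvent,
    Responder,
    normalize_events,
    write_event_log,
)

__all__ = [
    "UserSpec",
    "AppSpec",
    "SimConfig",
    "GTSegment",
    "GroundTruth",
    "simulate_household",
    "render_gold_codes",
    "make_corpus",
    "DEFAULT_APP_CATALOG",
]

_MS = 1000  # all generation happens on a whole-second lattice

#: a small catalog spanning the seven app categories
DEFAULT_APP_CATALOG: list[dict] = [
    {"app_id": "org.khankids.android", "category": "educational", "mean_use_s": 300},
    {"app_id": "com.google.android.youtube", "category": "streaming", "mean_use_s": 600},
    {"app_id": "com.netflix.mediaclient", "category": "streaming", "mean_use_s": 900},
    {"app_id": "com.mojang.minecraftpe", "category": "gaming", "mean_use_s": 600},
    {"app_id": "com.instagram.android", "category": "social_media", "mean_use_s": 240},
    {"app_id": "com.android.chrome", "category": "browsing", "mean_use_s": 180},
    {"app_id": "com.android.settings", "category": "os", "mean_use_s": 60},
]


class UserSpec(BaseModel):
    role: Literal["child", "other"]
    pickup_rate_per_hour: float = Field(gt=0, default=2.0)
    mean_session_s: float = Field(gt=0, default=600.0)


class AppSpec(BaseModel):
    app_id: str
    category: str = "other"
    mean_use_s: float = Field(gt=0, default=300.0)


class SimConfig(BaseModel):
    """Scenario configuration; defaults describe a two-user household over
    one waking day with good-but-imperfect prompt compliance."""

    seed: int = 0
    span_hours: float = Field(gt=0, default=12.0)
    users: list[UserSpec] = Field(
        default_factory=lambda: [
            UserSpec(role="child", pickup_rate_per_hour=2.0, mean_session_s=600),
            UserSpec(role="other", pickup_rate_per_hour=1.0, mean_session_s=300),
        ]
    )
    p_comply: float = Field(ge=0, le=1, default=0.9)
    p_misid: float = Field(ge=0, le=1, default=0.02)
    response_latency_mean_s: float = Field(gt=0, default=5.0)
    auto_lock_s: float = Field(gt=0, default=120.0)
    protocol_version: ProtocolVersion = ProtocolVersion.V3
    app_catalog: list[AppSpec] = Field(
        default_factory=lambda: [AppSpec(**a) for a in DEFAULT_APP_CATALOG]
    )
    p_coview: float = Field(ge=0, le=1, default=0.1)
    p_multitask: float = Field(ge=0, le=1, default=0.1)
    p_audio: float = Field(ge=0, le=1, default=0.05)
    gaze_gap_rate_per_hour: float = Field(ge=0, default=6.0)

    @field_validator("app_catalog")
    @classmethod
    def _nonempty_catalog(cls, v: list[AppSpec]) -> list[AppSpec]:
        if not v:
            raise ValueError("app_catalog must be nonempty")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class GTSegment:
    """One ground-truth segment: who holds the device, what a human coder
    would code, and which app (if any) is in the foreground."""

    start: int  # ms
    end: int  # ms, half-open
    holder: Literal["child", "other", "nobody"]
    gold_code: GoldCode
    app_id: str = ""


@dataclass
class GroundTruth:
    """Segments tiling the span exactly, plus the prompt audit trail
    (prompt time, whether it was answered, and the label given)."""

    segments: list[GTSegment]
    span: tuple[int, int]
    prompt_events: list[tuple[int, bool, str | None]] = field(default_factory=list)

    def device_use_ms(self) -> dict[str, int]:
        """True device app-use milliseconds per holder (gaze-diverted
        moments count: the app is still in the foreground)."""
        out = {"child": 0, "other": 0}
        for seg in self.segments:
            if seg.holder in out and seg.app_id:
                out[seg.holder] += seg.end - seg.start
        return out


def _lognormal_s(rng: np.random.Generator, mean_s: float, sigma: float = 0.6) -> int:
    """Integer-second log-normal draw with the requested mean, >= 1 s."""
    mu = np.log(mean_s) - sigma**2 / 2
    return max(1, int(round(rng.lognormal(mu, sigma))))


def _session_gold_code(
    rng: np.random.Generator, role: str, cfg: SimConfig
) -> tuple[GoldCode, bool]:
    """Session-level flavor: (code, is_audio). Audio, coview and multitask
    are drawn sequentially and mutually exclusive."""
    if rng.random() < cfg.p_audio:
        return (
            GoldCode.CHILD_AUDIO if role == "child" else GoldCode.PARENT_AUDIO,
            True,
        )
    if role == "child":
        if rng.random() < cfg.p_coview:
            return GoldCode.BOTH_SCREEN, False
        if rng.random() < cfg.p_multitask:
            return GoldCode.CHILD_MULTITASK, False
        return GoldCode.CHILD_SCREEN, False
    return GoldCode.PARENT_SCREEN, False


def simulate_household(config: SimConfig) -> tuple[GroundTruth, EventLog]:
    """Generate one paired (GroundTruth, EventLog) realization.

    Identical configs (including seed) give identical outputs. A span too
    short to hold any pickup yields valid empty-use outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    span_s = int(round(cfg.span_hours * 3600))
    span = (0, span_s * _MS)
    rates = np.array([u.pickup_rate_per_hour / 3600.0 for u in cfg.users])

    events: list[RawEvent] = []
    segments: list[GTSegment] = []
    prompts: list[tuple[int, bool, str | None]] = []
    misid_flip = {"child": Responder.OTHER, "other": Responder.CHILD}

    def add_seg(a_s: int, b_s: int, holder: str, code: GoldCode, app: str = "") -> None:
        if b_s > a_s:
            segments.append(GTSegment(a_s * _MS, b_s * _MS, holder, code, app))

    def draw_prompt(
        t_s: int, holder: str, latest_s: int, *, clamp: bool
    ) -> tuple[int, Responder] | None:
        """One identification prompt at t_s; returns (response_t_s, label)
        or None for non-response. ``clamp=True`` (unlock prompts) pulls a
        slow answer back to the last usable second, so an intending
        responder always answers; re-prompt answers slower than the session
        are dropped as non-responses."""
        answered = rng.random() < cfg.p_comply
        latency = int(round(rng.exponential(cfg.response_latency_mean_s)))
        resp_t = t_s + latency
        if answered and clamp:
            resp_t = min(resp_t, latest_s)
        if not answered or resp_t > latest_s:
            prompts.append((t_s * _MS, False, None))
            return None
        wrong = rng.random() < cfg.p_misid
        label = misid_flip[holder] if wrong else Responder(holder)
        prompts.append((t_s * _MS, True, label.value))
        return resp_t, label

    t = 0  # seconds; device currently locked and idle
    while True:
        waits = rng.exponential(1.0, size=len(rates)) / rates  # seconds, per user
        who = int(np.argmin(waits))
        unlock_s = t + max(1, int(round(waits[who])))
        if unlock_s >= span_s - 2:
            add_seg(t, span_s, "nobody", GoldCode.NO_USE)
            break
        add_seg(t, unlock_s, "nobody", GoldCode.NO_USE)
        user = cfg.users[who]
        role = user.role
        dur = max(3, _lognormal_s(rng, user.mean_session_s))
        use_end = min(unlock_s + dur, span_s - 1)

        events.append(RawEvent(t=unlock_s * _MS, kind=EventKind.UNLOCK))
        # V1's answer must strictly precede app use, so leave room for it
        latest = use_end - 2 if cfg.protocol_version is ProtocolVersion.V1 else use_end - 1
        resp = draw_prompt(unlock_s, role, latest, clamp=True)

        if cfg.protocol_version is ProtocolVersion.V1 and resp is None:
            # modal prompt never answered: the pickup yields no app use
            lock_s = min(unlock_s + int(cfg.auto_lock_s), span_s)
            lock_s = max(lock_s, unlock_s + 1)
            events.append(RawEvent(t=lock_s * _MS, kind=EventKind.LOCK))
            add_seg(unlock_s, lock_s, role, GoldCode.NO_USE)
            t = lock_s
            continue

        if resp is not None:
            resp_t, label = resp
            events.append(
                RawEvent(t=resp_t * _MS, kind=EventKind.IDENTIFY, responder=label)
            )

        use_start = unlock_s
        if cfg.protocol_version is ProtocolVersion.V1 and resp is not None:
            use_start = resp[0] + 1  # use strictly follows the modal answer

        # V2 re-prompts after every 15 min of continuous use
        if cfg.protocol_version is ProtocolVersion.V2:
            rp = unlock_s + 900
            while rp < use_end:
                r2 = draw_prompt(rp, role, use_end - 1, clamp=False)
                if r2 is not None:
                    events.append(
                        RawEvent(
                            t=r2[0] * _MS, kind=EventKind.IDENTIFY, responder=r2[1]
                        )
                    )
                rp += 900

        code, _is_audio = _session_gold_code(rng, role, cfg)
        add_seg(unlock_s, use_start, role, GoldCode.NO_USE)

        # fill [use_start, use_end) with consecutive app sessions
        cur = use_start
        app_bounds: list[tuple[int, int, str]] = []
        while cur < use_end:
            spec = cfg.app_catalog[int(rng.integers(len(cfg.app_catalog)))]
            d = min(_lognormal_s(rng, spec.mean_use_s), use_end - cur)
            events.append(
                RawEvent(t=cur * _MS, kind=EventKind.FOREGROUND, app_id=spec.app_id)
            )
            events.append(
                RawEvent(t=(cur + d) * _MS, kind=EventKind.BACKGROUND, app_id=spec.app_id)
            )
            app_bounds.append((cur, cur + d, spec.app_id))
            cur += d

        # gaze diversions (<3 s) inside screen-use sessions of the child
        gap_set: set[int] = set()
        if (
            role == "child"
            and code in (GoldCode.CHILD_SCREEN, GoldCode.BOTH_SCREEN, GoldCode.CHILD_MULTITASK)
            and cfg.gaze_gap_rate_per_hour > 0
        ):
            n_gaps = rng.poisson(cfg.gaze_gap_rate_per_hour * (use_end - use_start) / 3600)
            for _ in range(n_gaps):
                g_dur = int(rng.integers(1, 3))  # 1 or 2 s, always < 3 s
                lo, hi = use_start + 1, use_end - g_dur - 1
                if hi <= lo:
                    continue
                g0 = int(rng.integers(lo, hi))
                # keep diversions separated so no merged run reaches 3 s
                if any(s in gap_set for s in range(g0 - 1, g0 + g_dur + 1)):
                    continue
                gap_set.update(range(g0, g0 + g_dur))

        for a, b, app in app_bounds:
            cursor = a
            s = cursor
            while s < b:
                in_gap = s in gap_set
                e = s + 1
                while e < b and ((e in gap_set) == in_gap):
                    e += 1
                add_seg(s, e, role, GoldCode.NO_USE if in_gap else code, app)
                s = e

        lock_s = min(use_end + int(cfg.auto_lock_s), span_s)
        events.append(RawEvent(t=lock_s * _MS, kind=EventKind.LOCK))
        add_seg(use_end, lock_s, role, GoldCode.NO_USE)
        t = lock_s

    gt = GroundTruth(segments=segments, span=span, prompt_events=prompts)
    log = EventLog(
        device_id=f"sim-{cfg.seed}",
        protocol_version=cfg.protocol_version,
        events=normalize_events(events, span),
        span=span,
    )
    return gt, log


def render_gold_codes(gt: GroundTruth) -> GoldTimeline:
    """Render the ground truth the way a human duration-coder would.

    Gaze diversions shorter than 3 s inside a screen-use stretch stay coded
    as that screen use (a coder ignores quick glances away); adjacent
    equal-code segments are merged.
    """
    screen_codes = {
        GoldCode.CHILD_SCREEN,
        GoldCode.PARENT_SCREEN,
        GoldCode.BOTH_SCREEN,
        GoldCode.CHILD_MULTITASK,
    }
    codes: list[list[int | GoldCode]] = []
    for s in gt.segments:
        # pre-merge equal-code neighbors (e.g. a gaze gap crossing an app
        # boundary) so the smoothing pass sees whole gaps
        if codes and codes[-1][2] == s.gold_code and codes[-1][1] == s.start:
            codes[-1][1] = s.end
        else:
            codes.append([s.start, s.end, s.gold_code])
    for i in range(1, len(codes) - 1):
        s, e, c = codes[i]
        prev_c = codes[i - 1][2]
        next_c = codes[i + 1][2]
        if (
            c is GoldCode.NO_USE
            and (e - s) < 3 * _MS
            and prev_c == next_c
            and prev_c in screen_codes
        ):
            codes[i][2] = prev_c
    merged: list[GoldSegment] = []
    for s, e, c in codes:
        if merged and merged[-1].code == c and merged[-1].end == s:
            merged[-1] = GoldSegment(merged[-1].start, e, c)
        else:
            merged.append(GoldSegment(s, e, c))
    return GoldTimeline(segments=merged, span=gt.span)


def write_gold_csv(gt: GroundTruth, path: str | Path) -> Path:
    """Ground-truth segments as CSV (start_ms, end_ms, code, holder, app_id)."""
    import csv as _csv

    path = Path(path)
    with path.open("w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["start_ms", "end_ms", "code", "holder", "app_id"])
        for s in gt.segments:
            w.writerow([s.start, s.end, s.gold_code.value, s.holder, s.app_id])
    return path


def read_gold_csv(path: str | Path) -> GoldTimeline:
    """Read a gold-timeline CSV (ignores holder/app columns if present)."""
    import csv as _csv

    segments: list[GoldSegment] = []
    with Path(path).open(newline="") as fh:
        for row in _csv.DictReader(fh):
            segments.append(
                GoldSegment(int(row["start_ms"]), int(row["end_ms"]), GoldCode(row["code"]))
            )
    span = (segments[0].start, segments[-1].end) if segments else (0, 0)
    return GoldTimeline(segments=segments, span=span)


def make_corpus(configs: list[SimConfig], out_dir: str | Path) -> dict:
    """Simulate every config and write paired files plus a manifest.

    Files: ``events_<seed>.jsonl`` and ``gold_<seed>.csv`` per config;
    ``manifest.json`` lists (seed, config hash, file names) and carries a
    corpus-level hash. Reruns with the same configs are byte-identical.
    Duplicate seeds are refused before anything is written.
    """
    seeds = [c.seed for c in configs]
    if len(set(seeds)) != len(seeds):
        raise ValueError(f"duplicate seeds in corpus configs: {sorted(seeds)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for cfg in configs:
        gt, log = simulate_household(cfg)
        ev_name = f"events_{cfg.seed}.jsonl"
        gold_name = f"gold_{cfg.seed}.csv"
        write_event_log(log, out / ev_name, format="jsonl")
        write_gold_csv(gt, out / gold_name)
        entries.append(
            {
                "seed": cfg.seed,
                "config_hash": cfg.config_hash(),
                "events_file": ev_name,
                "gold_file": gold_name,
            }
        )
    manifest = {"entries": entries}
    manifest["corpus_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
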