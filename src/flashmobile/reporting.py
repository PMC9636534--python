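"""App categorization, the parent-facing use log, and daily summaries.

Apps fall into seven categories (educational, streaming, gaming,
social_media, browsing, os, other); unknown packages default to ``other``.
The use log is the artifact a family reviews: one row per attributed
interval with local start time, duration, category and who used the device
(``unidentified`` when the prompt was ignored). Local time is an explicit
fixed UTC offset — no DST database — so report fixtures reproduce exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .attribution import AttributedInterval, UserLabel

__all__ = [
    "CATEGORIES",
    "AppCategoryMap",
    "UseLogRow",
    "UseLogReport",
    "categorize_app",
    "build_use_log",
    "daily_summary",
]

CATEGORIES = (
    "educational",
    "streaming",
    "gaming",
    "social_media",
    "browsing",
    "os",
    "other",
)

#: seed entries for the editable category map
_SEED_ENTRIES = {
    "org.khankids.android": "educational",
    "com.learning.mathjumps": "educational",
    "com.google.android.youtube": "streaming",
    "com.netflix.mediaclient": "streaming",
    "com.mojang.minecraftpe": "gaming",
    "com.instagram.android": "social_media",
    "com.android.chrome": "browsing",
    "com.android.settings": "os",
}

_MS_PER_DAY = 24 * 3600 * 1000


class AppCategoryMap:
    """Total app_id → category lookup; unmapped packages are ``other``."""

    def __init__(self, entries: dict[str, str] | None = None):
        entries = dict(_SEED_ENTRIES) if entries is None else dict(entries)
        for app, cat in entries.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for {app!r}")
        self.entries = entries

    @classmethod
    def from_csv(cls, path: str | Path) -> "AppCategoryMap":
        with Path(path).open(newline="") as fh:
            return cls({r["app_id"]: r["category"] for r in csv.DictReader(fh)})

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["app_id", "category"])
            for app, cat in sorted(self.entries.items()):
                w.writerow([app, cat])
        return path

    def __getitem__(self, app_id: str) -> str:
        return self.entries.get(app_id, "other")


def categorize_app(app_id: str, category_map: AppCategoryMap) -> str:
    """Category for one app; ``other`` when unmapped; empty id rejected."""
    if not app_id:
        raise ValueError("empty app_id")
    return category_map[app_id]


@dataclass(frozen=True)
class UseLogRow:
    date: str  # local calendar date, ISO
    start_local: str  # HH:MM:SS
    duration_min: float
    app_id: str
    category: str
    user: UserLabel


@dataclass
class UseLogReport:
    rows: list[UseLogRow]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["date", "start_local", "duration_min", "app_id", "category", "user"])
            for r in self.rows:
                w.writerow(
                    [r.date, r.start_local, f"{r.duration_min:.4f}", r.app_id,
                     r.category, r.user.value]
                )
        return path


def _local_parts(t_ms: int) -> tuple[str, str]:
    day, rem = divmod(t_ms, _MS_PER_DAY)
    ts = pd.Timestamp(day * _MS_PER_DAY, unit="ms")
    secs = rem // 1000
    return ts.strftime("%Y-%m-%d"), f"{secs // 3600:02d}:{secs % 3600 // 60:02d}:{secs % 60:02d}"


def build_use_log(
    attributed: list[AttributedInterval],
    category_map: AppCategoryMap,
    tz_offset_min: int = 0,
    include_unidentified: bool = True,
) -> UseLogReport:
    """One row per attributed interval, split at local midnight.

    Midnight splitting is lossless: the split rows' durations sum to the
    original interval's duration exactly. ``include_unidentified=False``
    omits rows whose user is unknown (both renderings are supported).
    """
    offset_ms = tz_offset_min * 60_000
    rows: list[UseLogRow] = []
    for ai in sorted(attributed, key=lambda a: a.start):
        if not include_unidentified and ai.user is UserLabel.UNIDENTIFIED:
            continue
        s = ai.start + offset_ms
        end = ai.end + offset_ms
        while s < end:
            day_end = (s // _MS_PER_DAY + 1) * _MS_PER_DAY
            e = min(end, day_end)
            date, clock = _local_parts(s)
            rows.append(
                UseLogRow(
                    date=date,
                    start_local=clock,
                    duration_min=(e - s) / 60_000,
                    app_id=ai.app_id,
                    category=categorize_app(ai.app_id, category_map),
                    user=ai.user,
                )
            )
            s = e
    return UseLogReport(rows=rows)


def daily_summary(report: UseLogReport) -> pd.DataFrame:
    """Per-calendar-day totals: minutes per user label, child minutes per
    category, and the count of distinct child-used apps. Days inside the
    report's date range with no use appear as all-zero rows."""
    cols = (
        ["date", "child_min", "other_min", "unidentified_min"]
        + [f"{c}_child_min" for c in CATEGORIES]
        + ["distinct_child_apps"]
    )
    if not report.rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(
        {
            "date": r.date,
            "user": r.user.value,
            "category": r.category,
            "app_id": r.app_id,
            "duration_min": r.duration_min,
        }
        for r in report.rows
    )
    all_days = pd.date_range(df["date"].min(), df["date"].max()).strftime("%Y-%m-%d")
    out = []
    for day in all_days:
        d = df[df["date"] == day]
        child = d[d["user"] == "child"]
        rec = {
            "date": day,
            "child_min": child["duration_min"].sum(),
            "other_min": d.loc[d["user"] == "other", "duration_min"].sum(),
            "unidentified_min": d.loc[d["user"] == "unidentified", "duration_min"].sum(),
        }
        for c in CATEGORIES:
            rec[f"{c}_child_min"] = child.loc[child["category"] == c, "duration_min"].sum()
        rec["distinct_child_apps"] = child["app_id"].nunique()
        out.append(rec)
    return pd.DataFrame(out, columns=cols)
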