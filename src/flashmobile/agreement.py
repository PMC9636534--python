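"""Agreement between a device-derived timeline and gold-standard coding.

The gold standard is duration coding of an observation session with one of
ten mutually exclusive codes (child/parent/both screen use, child
multitasking, child/parent/both audio use, no mobile device use, uncertain,
out of frame). For validation those codes are collapsed to four classes —
``child_use`` (child screen use alone, with someone else, or while
multitasking), ``other_use`` (parent screen use), ``no_use`` (audio use and
true non-use; screen use is defined by gaze, so audio-only use is not screen
use), and ``excluded`` (uncertain / out of frame, dropped from scoring).

Both timelines are discretized onto a common grid (default 1 s cells) and
compared via a 4x4 confusion matrix, observed agreement, Cohen's kappa, the
prevalence- and bias-adjusted kappa PABAK = (k*Po - 1)/(k - 1), and — for
per-dyad use durations — the intraclass correlation coefficient ICC(2,1)
(two-way random effects, absolute agreement, single measures).

Per-class "agreement" has two natural conditional directions (given the
gold class, or given the device class); both are reported, the
gold-conditional value being the headline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .attribution import AttributedInterval, UserLabel

__all__ = [
    "GoldCode",
    "AgreementClass",
    "GoldSegment",
    "GoldTimeline",
    "AgreementResult",
    "collapse_gold",
    "discretize_gold",
    "discretize_device",
    "confusion_matrix",
    "cohen_kappa",
    "pabak",
    "icc_absolute_agreement",
    "dyad_agreement_report",
]


class GoldCode(str, Enum):
    """The ten duration-coding observation codes."""

    CHILD_SCREEN = "child screen use"
    PARENT_SCREEN = "parent screen use"
    BOTH_SCREEN = "both screen use"
    CHILD_MULTITASK = "child multitasking"
    CHILD_AUDIO = "child audio use"
    PARENT_AUDIO = "parent audio use"
    BOTH_AUDIO = "both audio use"
    NO_USE = "no mobile device use"
    UNCERTAIN = "uncertain"
    OUT_OF_FRAME = "out of frame"


class AgreementClass(str, Enum):
    CHILD_USE = "child_use"
    OTHER_USE = "other_use"
    UNIDENTIFIED = "unidentified"
    NO_USE = "no_use"
    EXCLUDED = "excluded"  # gold-only; dropped before scoring


#: scoring classes, fixed order for confusion-matrix axes
CLASSES: tuple[AgreementClass, ...] = (
    AgreementClass.CHILD_USE,
    AgreementClass.OTHER_USE,
    AgreementClass.UNIDENTIFIED,
    AgreementClass.NO_USE,
)
_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

_COLLAPSE = {
    GoldCode.CHILD_SCREEN: AgreementClass.CHILD_USE,
    GoldCode.BOTH_SCREEN: AgreementClass.CHILD_USE,
    GoldCode.CHILD_MULTITASK: AgreementClass.CHILD_USE,
    GoldCode.PARENT_SCREEN: AgreementClass.OTHER_USE,
    GoldCode.CHILD_AUDIO: AgreementClass.NO_USE,
    GoldCode.PARENT_AUDIO: AgreementClass.NO_USE,
    GoldCode.BOTH_AUDIO: AgreementClass.NO_USE,
    GoldCode.NO_USE: AgreementClass.NO_USE,
    GoldCode.UNCERTAIN: AgreementClass.EXCLUDED,
    GoldCode.OUT_OF_FRAME: AgreementClass.EXCLUDED,
}

_DEVICE_CLASS = {
    UserLabel.CHILD: AgreementClass.CHILD_USE,
    UserLabel.OTHER: AgreementClass.OTHER_USE,
    UserLabel.UNIDENTIFIED: AgreementClass.UNIDENTIFIED,
}


def collapse_gold(code: GoldCode | str) -> AgreementClass:
    """Collapse a ten-code observation code to a scoring class.

    Child screen use alone, joint ("both") screen use and multitasking all
    count as child use; audio codes count as no screen use (screen use
    requires gaze on the screen); uncertain and out-of-frame are excluded.
    """
    try:
        code = GoldCode(code)
    except ValueError:
        raise ValueError(f"unknown gold code {code!r}")
    return _COLLAPSE[code]


@dataclass(frozen=True)
class GoldSegment:
    start: int  # ms
    end: int  # ms, half-open
    code: GoldCode

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty gold segment [{self.start}, {self.end})")


@dataclass
class GoldTimeline:
    """Ordered, non-overlapping coded segments over an observation span."""

    segments: list[GoldSegment]
    span: tuple[int, int]

    def __post_init__(self) -> None:
        prev_end = None
        for seg in self.segments:
            if prev_end is not None and seg.start < prev_end:
                raise ValueError("gold segments overlap")
            prev_end = seg.end


@dataclass
class AgreementResult:
    grid_resolution_s: float
    n_scored_cells: int
    confusion: np.ndarray  # rows = gold, cols = device, order CLASSES
    overall_po: float
    per_class_gold_conditional: dict[AgreementClass, float] = field(
        default_factory=dict
    )
    per_class_device_conditional: dict[AgreementClass, float] = field(
        default_factory=dict
    )
    kappa: float = math.nan
    pabak: float = math.nan

    def to_dict(self) -> dict:
        return {
            "grid_resolution_s": self.grid_resolution_s,
            "n_scored_cells": self.n_scored_cells,
            "classes": [c.value for c in CLASSES],
            "confusion": self.confusion.tolist(),
            "overall_po": self.overall_po,
            "per_class_gold_conditional": {
                c.value: v for c, v in self.per_class_gold_conditional.items()
            },
            "per_class_device_conditional": {
                c.value: v for c, v in self.per_class_device_conditional.items()
            },
            "kappa": self.kappa,
            "pabak": self.pabak,
        }


# ---------------------------------------------------------------------------
# discretization

def _discretize(
    segments: Sequence[tuple[int, int, AgreementClass]],
    span: tuple[int, int],
    resolution_s: float,
    fill: AgreementClass,
) -> list[AgreementClass]:
    """One label per half-open grid cell; majority coverage wins, ties go to
    the earlier-starting segment; cells not covered at all take ``fill``."""
    if resolution_s <= 0:
        raise ValueError("resolution must be positive")
    res_ms = resolution_s * 1000
    t0, t1 = span
    n = int(math.ceil((t1 - t0) / res_ms)) if t1 > t0 else 0
    labels: list[AgreementClass] = []
    ordered = sorted(segments, key=lambda s: (s[0], s[1]))
    j = 0
    for k in range(n):
        a = t0 + k * res_ms
        b = min(t0 + (k + 1) * res_ms, t1)
        # advance past segments that end at or before the cell start
        while j < len(ordered) and ordered[j][1] <= a:
            j += 1
        best: AgreementClass | None = None
        best_cov = 0.0
        i = j
        while i < len(ordered) and ordered[i][0] < b:
            s, e, lab = ordered[i]
            cov = min(e, b) - max(s, a)
            if cov > best_cov:  # strict: ties keep the earlier segment
                best_cov, best = cov, lab
            i += 1
        covered = best_cov
        uncovered = (b - a) - sum(
            min(e, b) - max(s, a)
            for s, e, _ in ordered[j:i]
            if min(e, b) > max(s, a)
        )
        # uncovered time competes as an implicit fill segment; on a tie the
        # explicit (earlier-starting) segment wins
        if best is None or uncovered > best_cov:
            labels.append(fill)
        else:
            labels.append(best)
    return labels


def discretize_gold(
    timeline: GoldTimeline, span: tuple[int, int], resolution_s: float = 1.0
) -> list[AgreementClass]:
    """Gold timeline → per-cell collapsed class sequence."""
    segs = [
        (s.start, s.end, collapse_gold(s.code)) for s in timeline.segments
    ]
    return _discretize(segs, span, resolution_s, fill=AgreementClass.NO_USE)


def discretize_device(
    attributed: Sequence[AttributedInterval],
    span: tuple[int, int],
    resolution_s: float = 1.0,
) -> list[AgreementClass]:
    """Attributed device intervals → per-cell class sequence; cells with no
    app in the foreground map to ``no_use``."""
    segs = [
        (ai.start, ai.end, _DEVICE_CLASS[ai.user]) for ai in attributed
    ]
    return _discretize(segs, span, resolution_s, fill=AgreementClass.NO_USE)


# ---------------------------------------------------------------------------
# statistics

def confusion_matrix(
    gold_seq: Sequence[AgreementClass],
    device_seq: Sequence[AgreementClass],
    resolution_s: float = 1.0,
) -> AgreementResult:
    """4x4 gold-by-device confusion counts plus observed agreement.

    Cells whose gold label is ``excluded`` are dropped from both sequences
    before counting. Per-class conditionals are NaN for classes absent from
    the relevant margin.
    """
    if len(gold_seq) != len(device_seq):
        raise ValueError(
            f"sequence lengths differ: {len(gold_seq)} vs {len(device_seq)}"
        )
    conf = np.zeros((4, 4), dtype=np.int64)
    for g, d in zip(gold_seq, device_seq):
        if g is AgreementClass.EXCLUDED:
            continue
        conf[_CLASS_INDEX[g], _CLASS_INDEX[d]] += 1
    total = int(conf.sum())
    if total == 0:
        raise ValueError("no scored cells after exclusions")
    po = float(np.trace(conf)) / total
    row = conf.sum(axis=1)
    col = conf.sum(axis=0)
    gold_cond = {
        c: (float(conf[i, i]) / row[i] if row[i] > 0 else math.nan)
        for c, i in _CLASS_INDEX.items()
    }
    dev_cond = {
        c: (float(conf[i, i]) / col[i] if col[i] > 0 else math.nan)
        for c, i in _CLASS_INDEX.items()
    }
    return AgreementResult(
        grid_resolution_s=resolution_s,
        n_scored_cells=total,
        confusion=conf,
        overall_po=po,
        per_class_gold_conditional=gold_cond,
        per_class_device_conditional=dev_cond,
    )


def cohen_kappa(confusion: np.ndarray) -> float:
    """Cohen's kappa from a square confusion matrix.

    Chance agreement Pe comes from the row/column marginal products. Returns
    1.0 whenever observed agreement is perfect (even at Pe = 1), NaN when
    Pe = 1 with imperfect agreement (kappa undefined).
    """
    conf = np.asarray(confusion, dtype=float)
    total = conf.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(conf) / total
    pe = float((conf.sum(axis=1) / total) @ (conf.sum(axis=0) / total))
    if po == 1.0:
        return 1.0
    if pe == 1.0:
        return math.nan
    return float((po - pe) / (1.0 - pe))


def pabak(overall_po: float, k: int = 4) -> float:
    """Prevalence- and bias-adjusted kappa: (k*Po - 1)/(k - 1).

    Depends only on observed agreement Po and the class count k; at k = 2 it
    reduces to 2*Po - 1.
    """
    if k < 2:
        raise ValueError("PABAK requires at least 2 classes")
    if not 0.0 <= overall_po <= 1.0:
        raise ValueError(f"Po must be in [0, 1], got {overall_po}")
    return (k * overall_po - 1.0) / (k - 1.0)


def icc_absolute_agreement(
    paired_values: Sequence[tuple[float, float]],
) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``paired_values`` holds one (gold, device) measurement pair per dyad,
    e.g. observed vs device-derived child-use minutes. Computed from the
    two-way ANOVA mean squares::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with n dyads and k = 2 raters. Returns NaN (not applicable) when the
    total variance is zero.
    """
    arr = np.asarray(paired_values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 dyads of (gold, device) pairs")
    if np.isnan(arr).any():
        raise ValueError("missing values not allowed")
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((arr - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        return math.nan
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return math.nan
    return float((msr - mse) / denom)


def dyad_agreement_report(
    gold: GoldTimeline,
    attributed: Sequence[AttributedInterval],
    resolution_s: float = 1.0,
    span: tuple[int, int] | None = None,
) -> AgreementResult:
    """End-to-end scoring of one dyad: collapse, discretize, confusion,
    kappa and PABAK. ``span`` defaults to the gold timeline's span; the
    device record must overlap it."""
    if span is None:
        span = gold.span
    if attributed:
        dev_lo = min(ai.start for ai in attributed)
        dev_hi = max(ai.end for ai in attributed)
        if dev_hi <= span[0] or dev_lo >= span[1]:
            raise ValueError("device record does not overlap the gold span")
    gold_seq = discretize_gold(gold, span, resolution_s)
    dev_seq = discretize_device(attributed, span, resolution_s)
    result = confusion_matrix(gold_seq, dev_seq, resolution_s)
    result.kappa = cohen_kappa(result.confusion)
    result.pabak = pabak(result.overall_po, k=len(CLASSES))
    return result
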