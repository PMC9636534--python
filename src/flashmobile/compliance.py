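"""Compliance scoring, the identified-use validity threshold, and feedback.

Two dimensions of participant compliance are computed. The *compliance
score* is the percentage of unlocks for which the identification prompt was
answered (a session answered twice under the V2 re-prompt protocol still
counts once — the denominator is unlocks, not prompts). *Unidentified use*
is the percentage of total device use whose user is unknown because the
prompt was ignored. A dyad's data are considered valid for analysis when at
least ``threshold_pct`` (default 70) of total use is identified, threshold
inclusive.

Percentages are carried as exact rationals (:class:`fractions.Fraction`)
and only rendered to float/1-decimal at the reporting edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Mapping

from .attribution import UnlockSession, UserLabel

__all__ = [
    "NOT_APPLICABLE",
    "MessageKind",
    "ComplianceSummary",
    "compliance_score",
    "unidentified_use_pct",
    "passes_threshold",
    "feedback_message",
    "summarize_compliance",
]


class _NotApplicable:
    """Sentinel for degenerate denominators (no unlocks, zero use)."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NOT_APPLICABLE"

    def __bool__(self) -> bool:
        return False


NOT_APPLICABLE = _NotApplicable()


class MessageKind(str, Enum):
    REMINDER = "reminder"
    ENCOURAGEMENT = "encouragement"
    NO_DATA = "no_data"


@dataclass
class ComplianceSummary:
    n_unlocks: int
    n_responses: int
    compliance_pct: Fraction | _NotApplicable
    total_use_s: Fraction
    identified_use_s: Fraction
    unidentified_use_s: Fraction
    unidentified_pct: Fraction | _NotApplicable
    passes_threshold: bool | _NotApplicable
    threshold_pct: Fraction = Fraction(70)


def compliance_score(
    sessions: list[UnlockSession],
) -> Fraction | _NotApplicable:
    """Percentage of unlock sessions with at least one response.

    Synthetic catch-all sessions are excluded from the denominator. With
    zero sessions the score is undefined and ``NOT_APPLICABLE`` is returned,
    never 0.
    """
    real = [s for s in sessions if not s.synthetic]
    if not real:
        return NOT_APPLICABLE
    answered = sum(1 for s in real if s.responses)
    return Fraction(100) * Fraction(answered, len(real))


def unidentified_use_pct(
    durations: Mapping[UserLabel, Fraction | int | float],
) -> Fraction | _NotApplicable:
    """Percentage of total use whose user label is unidentified.

    Zero total use returns ``NOT_APPLICABLE`` (flagged, by convention
    distinct from a measured 0 %). Negative durations are rejected.
    """
    vals = {k: Fraction(durations.get(k, 0)) for k in UserLabel}
    if any(v < 0 for v in vals.values()):
        raise ValueError(f"negative duration in {durations!r}")
    total = sum(vals.values(), Fraction(0))
    if total == 0:
        return NOT_APPLICABLE
    return Fraction(100) * vals[UserLabel.UNIDENTIFIED] / total


def passes_threshold(summary: ComplianceSummary) -> bool | _NotApplicable:
    """True iff identified use / total use ≥ threshold_pct/100, inclusive."""
    if summary.total_use_s == 0:
        return NOT_APPLICABLE
    return (
        Fraction(summary.identified_use_s) / Fraction(summary.total_use_s)
        >= Fraction(summary.threshold_pct) / 100
    )


def feedback_message(
    summary: ComplianceSummary, reminder_below_pct: float | Fraction = 80
) -> tuple[MessageKind, str]:
    """Daily feedback: a reminder below the cutoff, encouragement at or
    above it (strict-less rule: exactly-at-cutoff earns encouragement)."""
    pct = summary.compliance_pct
    if pct is NOT_APPLICABLE or isinstance(pct, _NotApplicable):
        return (
            MessageKind.NO_DATA,
            "No device unlocks were recorded today, so there is no "
            "identification compliance to report.",
        )
    pct_f = float(pct)
    if pct < Fraction(reminder_below_pct):
        return (
            MessageKind.REMINDER,
            f"Today you answered the user prompt on {pct_f:.1f}% of unlocks. "
            "Please remember to tap 'child' or 'other' each time the device "
            "is unlocked.",
        )
    return (
        MessageKind.ENCOURAGEMENT,
        f"Great job! You answered the user prompt on {pct_f:.1f}% of unlocks "
        "today. Keep it up!",
    )


def summarize_compliance(
    sessions: list[UnlockSession],
    durations: Mapping[UserLabel, Fraction],
    threshold_pct: float | Fraction = 70,
) -> ComplianceSummary:
    """Assemble the full compliance record for one device-day (or study)."""
    vals = {k: Fraction(durations.get(k, 0)) for k in UserLabel}
    total = sum(vals.values(), Fraction(0))
    unid = vals[UserLabel.UNIDENTIFIED]
    real = [s for s in sessions if not s.synthetic]
    summary = ComplianceSummary(
        n_unlocks=len(real),
        n_responses=sum(1 for s in real if s.responses),
        compliance_pct=compliance_score(sessions),
        total_use_s=total,
        identified_use_s=total - unid,
        unidentified_use_s=unid,
        unidentified_pct=unidentified_use_pct(durations),
        passes_threshold=NOT_APPLICABLE,
        threshold_pct=Fraction(threshold_pct),
    )
    summary.passes_threshold = passes_threshold(summary)
    return summary
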