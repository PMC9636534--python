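"""flashmobile: shared-device screen-time measurement and validation.

Reconstructs who used a shared mobile device and when from a raw event
stream (app foreground/background, unlocks, identification-prompt
responses), scores participant compliance, renders parent-facing use logs,
and validates attributed timelines against gold-standard duration coding
with agreement statistics (observed agreement, Cohen kappa, PABAK, ICC).
A bundled household simulator produces paired event logs and ground truth
for end-to-end evaluation.
"""

from .agreement import (
    AgreementClass,
    AgreementResult,
    GoldCode,
    GoldSegment,
    GoldTimeline,
    cohen_kappa,
    collapse_gold,
    dyad_agreement_report,
    icc_absolute_agreement,
    pabak,
)
from .attribution import (
    AppInterval,
    AttributedInterval,
    UnlockSession,
    UserLabel,
    attribute,
    pair_intervals,
    segment_sessions,
    use_durations,
    use_durations_ms,
)
from .compliance import (
    NOT_APPLICABLE,
    ComplianceSummary,
    MessageKind,
    compliance_score,
    feedback_message,
    passes_threshold,
    summarize_compliance,
    unidentified_use_pct,
)
from .eventlog import (
    EventKind,
    EventLog,
    ProtocolVersion,
    RawEvent,
    Responder,
    canonical_sort_key,
    normalize_events,
    read_event_log,
    write_event_log,
)
from .reporting import AppCategoryMap, build_use_log, categorize_app, daily_summary
from .simulator import (
    GroundTruth,
    GTSegment,
    SimConfig,
    UserSpec,
    make_corpus,
    render_gold_codes,
    simulate_household,
)

__version__ = "0.1.0"


def measure(log: EventLog, threshold_pct: float = 70):
    """Run the full measurement pipeline on one event log.

    Returns (attributed intervals, unlock sessions, compliance summary).
    """
    intervals = pair_intervals(log)
    sessions = segment_sessions(log, intervals)
    attributed = attribute(sessions, log.protocol_version)
    summary = summarize_compliance(
        sessions, use_durations(attributed), threshold_pct=threshold_pct
    )
    return attributed, sessions, summary
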