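# Methods

## The measurement problem

One mobile device, several possible users, and a research question that
needs *child* screen time, not *device* screen time. The measurement
approach implemented here combines (1) passive event logging (app
foreground/background, unlock, lock), (2) an identification prompt at every
unlock answered with "child" or "other", (3) compliance feedback to the
family, and (4) a minimum identified-use threshold below which a dyad's
data are excluded. The package reconstructs attributed timelines from such
logs and quantifies their validity against gold-standard human duration
coding.

## Event model and attribution

Timestamps are integer milliseconds UTC; all intervals are half-open
`[start, end)`, which makes durations additive and prevents
double-counting at boundaries. At equal timestamps, events order as
LOCK < BACKGROUND < FOREGROUND < UNLOCK < IDENTIFY, so a lock closes open
state before anything new opens in the same instant. Real OS event streams
do not document an ordering for simultaneous events; this tie rule is a
repository convention chosen for deterministic replay. Normalization sorts,
repairs UNLOCK/LOCK alternation (synthetic lock at span end for a dangling
session; same-instant duplicate unlocks dropped, since no lock can sort
between them), and iterates sort+repair to a fixpoint so that normalizing
twice is the identity.

Foreground/background pairing follows single-foreground semantics: a new
foreground closes the previous app at the new app's start; lock or span end
closes anything open. Each UNLOCK..LOCK pair is one *unlock session*; every
app interval and prompt response belongs to exactly one session.

Within a session, the first response's label is applied retroactively from
the unlock instant. The prompt fires at unlock, and the compliance /
unidentified-use distinction in the underlying protocol implies
identification is per unlock rather than per second; without retroactivity
every session would start with spurious unidentified seconds equal to the
response latency. Whether a deployed logger labels pre-response seconds
retroactively is unknowable from the outside, so the rule is configurable
(`attribute(..., retroactive=False)`). Later responses (V2 re-prompts)
relabel from their own timestamp forward, splitting intervals; labels never
cross a lock.

## Compliance and the validity threshold

The compliance score is per unlock, not per prompt: a V2 session answered
at the unlock and again at a 15-minute re-prompt counts once. Re-prompts
affect only the attribution (and thus unidentified use). Percentages are
carried as exact rationals (`fractions.Fraction`) so that identified and
unidentified shares always sum to 100 exactly; rounding to one decimal
happens only in rendered reports. The threshold test is inclusive:
identified use of exactly 70 % passes. The feedback cutoff (reminder below
80 % compliance, encouragement at or above) is a configurable default; the
protocol this emulates used staff judgment rather than a stated cutoff.
Degenerate denominators (no unlocks, zero use) return a flagged
not-applicable value, never 0, so they cannot masquerade as measured zeros.

## Gold coding and agreement

The gold standard is duration coding with ten codes: child / parent / both
screen use, child multitasking, child / parent / both audio use, no mobile
device use, uncertain, out of frame. Screen use is gaze-defined, so for
validation the codes collapse to four classes: child screen use, joint
("both") screen use and multitasking → **child_use**; parent screen use →
**other_use**; all audio codes and true non-use → **no_use** (audio-only
use is not screen use under a gaze definition; an optional fifth audio
class could be added, but the four-class scheme matches the device's own
label space plus *unidentified*); uncertain and out of frame are excluded
from scoring entirely — exclusion drops grid cells without relabeling
neighbors.

Both timelines are discretized to a common grid, default 1 s — the natural
resolution of second-scale video coding, and the resolution at which the
oracle tests are exact. A cell takes the label covering the plurality of
it; uncovered time competes as an implicit no-use segment; ties go to the
earlier-starting explicit segment.

Statistics: observed agreement `Po`; per-class conditional agreement in
*both* directions (P(device=c|gold=c) and P(gold=c|device=c)) because the
conditional direction of "per-class agreement" is ambiguous in practice — a
device can produce a class (unidentified) that the gold coder cannot, so
the device-conditional view is the only one defined for it; Cohen's κ with
the convention κ=1 whenever Po=1 and not-applicable when Pe=1 with
imperfect agreement; PABAK `(k·Po − 1)/(k − 1)`, which depends only on Po
and is the appropriate chance correction when class prevalences are highly
skewed (screen-use data are mostly "no use"); and ICC for per-dyad duration
pairs. The ICC variant is pinned to ICC(2,1) — two-way random effects,
absolute agreement, single measures — computed from the standard
mean-squares decomposition: absolute agreement is the right choice because
a constant offset between device and coder durations is a real
disagreement, and single-measures because each dyad is measured once per
method. pingouin's ICC(A,1) and scikit-learn's kappa serve as independent
cross-checks in the test suite only.

## The household simulator

The generator is the package's test bed: it emulates every phenomenon the
measurement situation presents, with the simplest dynamics that exhibit
them. One device; each user (a child and, by default, one adult) generates
pickups by exponential waiting times, at most one holder at a time. A
pickup is a log-normal-length run of consecutive app sessions (log-normal:
right-skewed durations with two parameters; no empirical distribution of
young children's session lengths is assumed), followed by idle time and an
automatic lock after `auto_lock_s` (default 120 s, the "uniform auto screen
lock" configuration the protocol recommends). App identities come from a
small catalog spanning the seven report categories (educational, streaming,
gaming, social media, browsing, OS, other).

Prompts: one per unlock; V2 re-prompts every 900 s of use. A prompt is
answered with probability `p_comply` (default 0.9, matching the >90 %
compliance regime of the final protocol version); an answered prompt
carries the wrong label with probability `p_misid` (default 0.02 — wrong
log-ins by siblings/parents were observed but rare). Response latency is
exponential (mean 5 s). For the unlock prompt, an intending responder's
answer is clamped into the session (they answer before putting the device
down), so `p_comply` alone governs the response fraction; V2 re-prompt
answers that would land after use ends are dropped as non-responses. Under
V1 the prompt is modal: an unanswered V1 prompt produces a pickup with no
app use at all, and app use starts strictly after the answer otherwise.

Session flavor is drawn per pickup: audio-only (`p_audio`, default 0.05),
else for child pickups coviewing (`p_coview`, 0.1) or multitasking
(`p_multitask`, 0.1). Gaze diversions — glances away shorter than 3 s that
a human coder ignores — occur at `gaze_gap_rate_per_hour` (default 6)
inside child screen sessions as 1–2 s ground-truth micro-segments, kept
non-adjacent so no merged diversion reaches the 3 s rule.
`render_gold_codes` reproduces the coder's view: no-use gaps under 3 s
flanked by the same screen code are smoothed back into it.

All generated event times lie on a whole-second lattice (stored as
integer ms). This is a deliberate design choice: duration coding is
second-scale, and it makes interval arithmetic and the per-second replay
oracle *exactly* equal at 1 s resolution, turning the main correctness
tests into exact integer comparisons rather than tolerance checks. The
format itself supports millisecond timestamps; real logs with sub-second
events are handled by the majority-cell rule.

What the simulator does **not** model: app content, notification fatigue
drift over weeks, multi-device households, nighttime routines, or
empirically calibrated pickup rates and session lengths for any real
population. Passing tests therefore demonstrate the pipeline's
correctness and its qualitative behavior under compliance variation — not
population-level accuracy claims for real families.

## Evaluation sizes and numerical choices

The test suite and acceptance script use simulated spans of 1–3 h with
busy pickup rates, 100–200 random scenarios for oracle-equivalence checks,
and 300–500 paired-seed replicates per grid point for monotonicity —
sizes chosen so the full evaluation completes in well under a minute while
every stochastic check has comfortable statistical margin. Durations and
confusion counts are integers end to end; percentage identities hold in
rational arithmetic; closed-form statistic checks are asserted at 1e-12.
Zero-length interval fragments from coincident split points are dropped.

## Known limitations

- The attribution rule set assumes the logger's event semantics
  (single foreground app, unlock/lock bracketing); exotic OS behaviors
  (split screen, overlays) are out of scope.
- Per-class agreement percentages from real deployments depend on the
  (undocumented) conditional direction used; both directions are reported
  but no numeric reproduction of any particular deployment is claimed.
- The simulator's behavioral parameters are method-evaluation defaults,
  not population estimates.
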