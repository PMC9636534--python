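# flashmobile

Measuring how much time a young child spends on a **shared** mobile device
is hard: passive usage logging tells you *that* the device was used, but not
*who* used it. `flashmobile` implements a complete measurement pipeline for
the unlock-prompt approach to this problem: the device logs app
foreground/background events, unlocks and locks, and shows a brief
identification prompt ("child" or "other") at every unlock; the pipeline
reconstructs unlock sessions, attributes every second of app use to the
child, another household member, or *unidentified* (prompt ignored), scores
participant compliance, applies an identified-use validity threshold, and
validates the attributed timeline against gold-standard human duration
coding.

It is intended for researchers building or evaluating screen-time exposure
measures for pediatric and family studies.

## What it computes

For an event log `E` over an observation window, with unlock sessions
`s_1..s_n`:

- **Compliance score** `C = 100 · #{s_i with ≥1 prompt response} / n` —
  the share of unlocks whose identification prompt was answered.
- **Unidentified use** `U = 100 · T_unid / (T_child + T_other + T_unid)`,
  from half-open interval arithmetic at millisecond precision. Within a
  session the first response's label applies retroactively from the unlock;
  later responses (the 15-minute re-prompts of protocol V2) relabel from
  their own time forward. No response ⇒ unidentified.
- **Validity threshold**: a dyad's data are analyzable when identified use
  ≥ 70 % of total use (inclusive; configurable).
- **Agreement statistics** against a ten-code gold timeline collapsed to
  four classes (child use, other use, unidentified, no use) on a 1 s grid:
  observed agreement `P_o`, per-class conditionals in both directions,
  Cohen's `κ = (P_o − P_e)/(1 − P_e)`, the prevalence- and bias-adjusted
  kappa `PABAK = (k·P_o − 1)/(k − 1)`, and `ICC(2,1)` (two-way random,
  absolute agreement, single measures) for per-dyad use durations.

A bundled **household simulator** generates paired (ground-truth timeline,
device event log) realizations — shared pickups, probabilistic prompt
compliance and misidentification, coviewing, multitasking, audio-only use,
auto screen lock, sub-3-second gaze diversions — so the whole pipeline is
testable end to end with no device. See `docs/methods.md` for the model.

## Worked example

```python
import flashmobile as fm

cfg = fm.SimConfig(seed=11, span_hours=12)      # two-user household, one day
gt, log = fm.simulate_household(cfg)

attributed, sessions, summary = fm.measure(log)
print(f"compliance {float(summary.compliance_pct):.1f}%  "
      f"unidentified {float(summary.unidentified_pct):.1f}%  "
      f"passes {summary.passes_threshold}")

gold = fm.render_gold_codes(gt)                 # what a human coder would code
res = fm.dyad_agreement_report(gold, attributed)
print(f"po {res.overall_po:.3f}  kappa {res.kappa:.3f}  pabak {res.pabak:.3f}")
```

Output:

```
compliance 88.0%  unidentified 6.1%  passes True
po 0.895  kappa 0.778  pabak 0.859
```

Read: the prompt was answered at 22 of 25 unlocks (88.0 %); only 6.1 % of
device use could not be attributed, so the dyad clears the 70 %
identified-use threshold; and the attributed timeline agrees with the
simulated gold coding on 89.5 % of scored seconds (PABAK 0.859).

The same pipeline is scriptable from a shell:

```bash
flash-mobile simulate scenario.yaml --out-dir corpus
flash-mobile measure corpus/events_11.jsonl --out-dir measured
flash-mobile validate corpus/events_11.jsonl corpus/gold_11.csv --out agreement.json
```

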