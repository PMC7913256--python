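# Methods

## The problem

The case-crossover design estimates the effect of an intermittent exposure
on an acute outcome by comparing each subject's exposure just before the
event (the *case window*) with the same subject's exposure at an earlier
reference time (the *control window*); every case is its own control, so
time-invariant confounders cancel. With binary exposure and one control
window per subject, only *discordant* subjects — exposed in exactly one of
the two windows — carry information, and the odds ratio is the ratio of the
two discordant counts. The estimate, however, depends on where the control
window is placed, and a control window set too far from the event can turn
genuinely continuous medicine users into apparent intermittent users
(*persistent user bias*), inflating the odds ratio.

`crossvis` implements a deterministic, auditable version of the
visual-assessment procedure for this problem: classify every subject's
exposure under two alternative control windows, stratify subjects by how
their status changes between them, apply a per-stratum rule that decides
which window classifies that group correctly, aggregate the verdicts into
percent correctly/potentially mis-classified per window, and draw the
stratified dispensing-timeline figure on which those rules can be checked
by eye.

## Coordinates and windows

All computation happens in *days pre-event*: day 1 is the day immediately
before the subject's index event. Windows are closed integer intervals
`[start, end]` in this coordinate; the default design is

| window | days pre-event |
|---|---|
| case | 1–50 |
| washout (for CW1) | 51–100 |
| control window 1 (CW1) | 101–150 |
| control window 2 (CW2) | 151–200 |

over a 200-day horizon. CW2's washout is the whole span 51–150 between the
case window and CW2. A dispensing *on* the event day is excluded — it
cannot precede the outcome — and multiple dispensings on one day collapse
to a single binary exposure marker, since the classification only asks
whether any dispensing falls in a window. The 50-day width itself comes
from a data-driven heuristic (below).

Exposure status per control window is the cross of two booleans (any
dispensing in the case window × any in the control window): *intermittent*
(case only), *recent stopper* (control only), *continuous* (both),
*non-user* (neither). Case-window exposure is a single fact, so a subject's
two classifications always agree on it; the eight admissible status pairs
map bijectively onto strata A–H.

## Strata and rules

Six strata capture a change (or a discordance that persists) when CW2
replaces CW1; two are concordant under both windows and are not assessed:

- A: recent stopper → non-user
- B: non-user → recent stopper
- C: recent stopper → recent stopper
- D: intermittent → continuous
- E: continuous → intermittent
- F: intermittent → intermittent
- G: continuous → continuous (not assessed)
- H: non-user → non-user (not assessed)

Each assessed stratum carries one rule, and the rule's verdict applies to
the *whole stratum*, not to individuals — the method treats the stratum as
the unit of adjudication. On a timeline drawn with the event at the right,
a window's **RHS** is its boundary nearer the event (`start` in days
pre-event) and its **LHS** the far boundary (`end`). Each rule asks whether
a strict majority of members satisfy a condition about one *reference
dispensing*: the latest dispensing (smallest offset) for A–C, whose members
are unexposed in the case window, and the earliest (largest offset) for
D–F, whose members are unexposed in the control window(s). Rule B instead
asks whether the member had any dispensing in the washout.

| stratum | condition (per member) | if met (CW1, CW2) | else |
|---|---|---|---|
| A | latest closer to RHS of CW1 than LHS of CW1 | correct, misclassified | misclassified, correct |
| B | any dispensing in the washout (51–100) | misclassified, correct | correct, misclassified |
| C | latest closer to RHS of CW1 than LHS of CW2 | correct, correct | misclassified, misclassified (warned) |
| D | earliest closer to RHS of CW2 than LHS of CW2 | misclassified, correct | correct, misclassified |
| E | earliest closer to LHS of CW1 than RHS of CW1 | correct, misclassified | misclassified, correct |
| F | earliest located in the case window rather than the washout | correct, correct | misclassified, misclassified (warned) |

Design choices in this table that were genuinely open:

- **Reference dispensing for D.** Read literally, a "latest dispensing"
  condition for stratum D is vacuous: D members are exposed in the case
  window by definition, so their latest dispensing (≤ 50 days pre-event) is
  always nearer CW2's RHS (day 151) than its LHS (day 200). We therefore use
  one reference dispensing per member throughout, *earliest* for D–F — the
  same dispensing these strata are sorted by in the figure, and the quantity
  the persistent-user-bias argument for stratum E is phrased in ("the
  earliest dispensing clusters toward the beginning of CW1"). A
  `count_mode="dispensing"` option counts every dispensing instead of one
  per member for the distance rules, for users who prefer the
  all-prescriptions reading.
- **Else branches.** The rules are stated as one-sided "if" conditions; the
  complement branch assigns the mirrored verdict pair. For C and F the
  complement means "misclassified under both windows", which the group-level
  logic cannot avoid; it is emitted with a warning. (Under the default
  geometry rule C's complement is actually unreachable — every admissible
  latest dispensing is nearer day 101 than day 200 — but it matters for
  designs with a short CW2.)
- **Ties.** "Closer" is a strict inequality: an equidistant reference counts
  as *not* closer, and "greater than half" is a strict majority (an exact
  half-split fails the condition). Both choices are conservative; the signed
  per-subject margins are exported in `RuleDecision.per_subject_metric` so
  the majority can be audited.

The summary step divides each stratum's size by the number of subjects in
strata A–F (the union of subjects discordant under either window) and sums
the shares of strata judged correct (resp. misclassified) per window;
empty strata are indeterminate and contribute nothing, so the three
percentages always total 100.

## Odds ratio

For 1:1 self-matched binary exposure the conditional likelihood of a
conditional logistic regression with subjects as strata reduces to b + c
Bernoulli trials — each discordant subject is "case-window exposed" with
probability ψ/(1+ψ) — so the MLE is the closed form ψ̂ = b/c and no
iterative fit is needed. The confidence interval is Wald on the log scale,
`exp(ln(b/c) ± z₁₋α/₂·√(1/b + 1/c))`, which reproduces published
conditional-logistic output to the printed 2 decimal places. The test suite
verifies the closed form against a brute-force maximiser of the conditional
likelihood (scipy `minimize_scalar` on log ψ) to 1e-6 relative error over
all cells 1 ≤ b, c ≤ 30. A zero discordant cell is degenerate (OR of 0 or
∞); the estimator raises unless the Haldane–Anscombe +0.5 correction is
explicitly requested — never silently. Values are kept unrounded;
formatting happens only at presentation.

## Window-length heuristic

`suggest_window_length(histories, percentile=75)` computes, per subject
with ≥ 2 dispensings, the time from the first to the second dispensing in
calendar order, and returns the smallest integer d such that at least the
given percent of those gaps are ≤ d. The empirical "smallest observed gap
with ≥ p% coverage" definition (no interpolation) guarantees a whole-day
answer that is an actually observed gap. Whether gaps are first-to-second
("first-gap", default), all consecutive gaps, or per-subject medians is a
caller-selected policy, and whether to restrict to users of the medicine
class is the caller's choice — the function takes whatever histories it is
given.

## Visualisation

`build_panels` produces a deterministic `PanelLayout`: panels A–F in order
(configurable), rows sorted by the conventions above with subject-id
tie-breaks, window bands annotated, event at the right. `render` draws it
with matplotlib (SVG or PNG); markers sit at x = horizon − offset so day 1
is at the right edge. Styling (marker glyph, band colours, figure size) is
configurable and deliberately outside the tested surface; the TSV layout
export (`stratum, row, subject_id, offsets`) is byte-stable across runs and
input orderings and is what regression tests compare.

## Synthetic cohorts

The generator plants archetypes over the 200-day horizon:

- `CONTINUOUS_REFILLER` — refill gaps ~ Normal(mean, sd) truncated to ≥ 1
  day (default mean 30 days, a standard one-month supply), walking from an
  onset day toward the event. With the default onset near the horizon the
  subject is exposed in every window; planting the onset inside CW1
  (e.g. days 126–150) constructs the stratum-E persistent-user-bias case.
- `INTERMITTENT_CASE_USER` — a 1–2 dispensing course inside the case window
  (or any supplied window).
- `RECENT_STOPPER` — a short course inside a control window (default CW1)
  and nothing later.
- `WASHOUT_ONLY_USER` — a course confined to days 51–100.
- `NON_USER` — no dispensings.

Event dates are uniform over 2009–2012 and distinct across subjects when
the range allows; calendar structure is otherwise irrelevant to the method,
so no seasonality is modelled. All randomness flows through a single
seeded `numpy` Generator (same seed ⇒ byte-identical output). The truth
table records statuses *recomputed from the emitted offsets*, not the
archetype's intent, so jitter that pushes a course across a boundary cannot
make the truth lie.

What the generator does **not** emulate: days-supply and adherence
(dispensing is taken as the marker of use), stockpiling, seasonality,
claims-schema details, or demographic confounders (the self-matched design
removes them). Passing tests on these cohorts therefore demonstrate the
*mechanics* of the method — classification, rules, estimation, layout — not
its clinical performance on real claims, where non-adherence and indication
data remain genuine limitations.

## Problem sizes and determinism

The test suite and the acceptance script run on cohorts of tens to a few
hundred subjects (500 for the window-length check), which this method
targets by design — it is a visualisation for hundreds, not tens of
thousands, of cases. Published cohort descriptives that depend on
restricted claims data (the 86%/14% and 55%/45% splits, the 348-subject
union, age/sex distributions) are replaced by parameter-recovery checks on
planted compositions. Stochastic checks fix seeds; hypothesis-based
property tests are seeded by the pytest plugin's deterministic default.

## Known limitations

- Verdicts are stratum-level by construction; a heterogeneous stratum is
  still judged as one group (the per-subject margins are exported for
  auditing, not for per-subject verdicts).
- The rule engine codifies one reading of conditions that were originally
  adjudicated by human consensus; the per-dispensing counting mode and the
  gap-policy options expose the main alternative readings rather than
  guessing a single intent.
- The Wald CI is asymptotic; with very small discordant counts an exact
  conditional (binomial) interval would be wider. The closed-form point
  estimate is exact regardless.
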