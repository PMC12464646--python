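# Methods

This note documents the procedures the package implements, the
numerical conventions chosen where the source material is silent, and
what the synthetic generators do and do not emulate.

## Band summaries

A rating round is a matrix of 7-point Likert responses, panellist ×
item × dimension (importance, risk, or agreement), with two non-rating
states: an explicit *outside my expertise* answer and a missing
response. Both are excluded from every denominator. For each item the
engine reports the count of valid ratings `n_valid`, per-score counts,
the median, and the percentage of valid ratings in the bands 1–2, 3–5,
5–7 and 6–7.

Conventions:

- **Median for even n** is the mean of the two central values. The
  published aggregate tables print half-integer medians (6.5), which
  fixes this convention.
- **Empty items** (no valid ratings) raise an error rather than
  returning zero percentages: "nobody could rate this" and "everybody
  rated this low" are different facts.
- Summaries built from a published table carry the printed one-decimal
  percentages verbatim; decisions are taken on those values with no
  re-rounding. Band sums drift from 100 by up to 0.15 under printed
  rounding, and the validator allows exactly that.
- The implied 1–2 band of a printed risk row is `100 − P₃₋₅ − P₆₋₇`,
  clipped at zero.

## Decision rules

All thresholds are inclusive (≥), configurable via `ConsensusRule`,
and default to the study's pre-specified values:

- **Inclusion** (importance dimension): P₆₋₇ ≥ 75 % or P₅₋₇ ≥ 85 %.
- **Agreement** (agreement dimension): same structure, same defaults.
- **Risk tier** (risk dimension): red if P₆₋₇ ≥ 75 %; else amber if
  P₃₋₅ ≥ 75 %; else green if P₁₋₂ ≥ 75 %; else, when the majority
  fallback is enabled, amber if P₃₋₅ + P₆₋₇ > 50 % (the stakeholder
  rule that an indicator rated medium-or-high by a majority counts as
  medium risk); else unassigned. Because 75 + 75 > 100, at most one
  band can reach the threshold, so the cascade order never changes the
  answer among the three primary outcomes.

Applied to the packaged tables these rules reproduce the published
counts exactly: 47/109 indicators included in round 1 and 82/123 in
round 2; 12/29 statements agreed in round 1 and 13/30 in round 2. A
round's denominator contains only the items actually rated in that
round — the 14 indicators and 1 statement added for the second rounds
have blank first-round cells and are simply absent from the round-1
summary lists.

Whether the original analysis thresholded raw counts or printed
percentages is unknowable from the aggregates alone; this package
thresholds the printed values, and the exact reproduction above is
evidence the distinction never bites at the printed precision.

## Rank aggregation

Ranking questions (most to least preferred) are aggregated by
first-choice plurality. Ties cascade to second-rank counts, then
third, and finally lexicographic option id, making the winner total
and deterministic. The cascade is not an invention of convenience: the
medium-risk review-frequency question ties 11–11 on first choices and
is decided 8–7 at rank 2, matching the frequency the study adopted.

## Controlled feedback

Second-round feedback documents contain, per item: the recipient's own
previous response ("not rated" when skipped), the group median, the
full 1–7 count breakdown, an optional narrative summary, and an
annotation — the literal strings `*Newly added indicator` or
`Modified from: <original text>`. Narratives are authored inputs;
summarising free-text comments is a human analysis step and is never
automated here. Newly added items carry no prior-round statistics.
Rendering (markdown or CSV) is deterministic, and no panellist
identity other than the recipient's appears anywhere in a document.

## Catalog editing

The catalog records each indicator's wording, group (high-risk
medicine / patient / drug / hospital-related), provenance sources,
status and tier. `union_sources` merges two source lists by id,
keeping both provenance annotations on shared entries (hence `sources`
is a tuple, not a scalar); with the study's list sizes (48 and 415,
3 shared) the union has 460 entries. `apply_merge_plan` absorbs
near-duplicates into a representative (each absorbed entry reduces the
active count by one — the only reading consistent with the study's
82 − 10 − 1 = 71 arithmetic) and marks exclusions, keeping an audit
note on every touched entry.

The packaged merge plan reproduces the published *arithmetic*; the
membership of the merge groups is only partly published (the CKD
regrouping is), so the remaining groups are plausibility-based
reconstructions and every such entry is marked "inferred" in the plan
file. Downstream behaviour depends only on the surviving 71 active
indicators and their tiers.

## Predicate grammar and triage

Each active indicator carries one predicate:

| type | semantics |
|---|---|
| `medication_name_in` | case-insensitive name match against a list |
| `medication_class_in` | ditto on the medication's class label |
| `regular_med_count_ge` | count of regular (non-PRN) medications, optionally class-restricted, ≥ threshold (inclusive, per the polypharmacy wording) |
| `missed_dose_of` | a listed name/class with ≥ `min_missed` missed doses |
| `lab_compare` | most recent result of a named lab vs lt/le/gt/ge/between; units must match exactly, mismatch is an error, never a silent conversion |
| `age_compare` | strict comparisons, matching the printed wordings (> 70, > 80, < 12, < 18 are exclusive) |
| `flag_present` | a recorded boolean clinical fact |
| `days_since_event_ge` | days since last review / admission |
| `manual` | requires clinical judgement; matches only via an explicit assessor flag |

Indicators whose wording needs judgement or an external knowledge base
(significant interaction, significant ADR, nonadherence, teratogenic
risk in childbearing potential, and similar) are typed `manual`; no
interaction database or terminology service is bundled, and facts the
engine cannot derive (QTc outside range, high creatine kinase, covert
administration, …) are consumed as recorded flags. The only numeric
lab predicate shipped is eGFR, whose thresholds the indicator wordings
state explicitly.

Classification: any red match → red; else more than
`amber_escalation_threshold` amber matches → red with `escalated`
set; else any amber → amber; else green. The default threshold is 4
("more than 4 amber criteria"), the more sensitive of the two
escalation rules that reached agreement; it is configurable because
both did. Severity is monotone in the match set, and classification is
invariant to match order. Overrides replace the tier while retaining
the original tier, author and a compulsory non-blank comment (unless
the policy relaxes it). Live indicators lacking a consensus tier would
be treated as amber, per the stakeholder fallback; the shipped catalog
has none (35 red, 36 amber).

## Scheduling

Red and amber reviews fall due 1–2 and 2–4 *calendar* days after the
last review; green patients fall due by the 5th *working* day, because
the panel's winning green option is phrased as "once every working
week" while the red/amber options are phrased in days. The working
week defaults to Monday–Friday with a configurable holiday set. A
referral pulls the deadline forward (never backward) and flags the
schedule. The worklist orders overdue before due-today before future;
within a stratum red < amber < green, then days overdue descending,
then patient id — the overdue-first policy is this package's choice
(the source material orders nothing) and is deliberately a pure sort
key, easy to swap.

## Synthetic generators

`generate_panel` emulates the panel structure: exact per-score counts
(remaining panellists answer outside-expertise; summaries reproduce
the counts exactly) or target score distributions with an
outside-expertise probability, plus between-round dropout (the study
lost 7 of 36 panellists between rounds; the default tests use sizes of
that order). `generate_cohort` builds patient records that satisfy a
planted set of indicators — medications, lab values, flags, ages and
review dates consistent with each predicate — against a base record
drawn to match nothing: ages from a range avoiding all age predicates,
medications from a formulary disjoint from every name list, no flags,
a recent review. Accidental matches are handled by rejection sampling
(default 5 rebuilds); a match that survives — typically a structural
implication, e.g. planting "two antipsychotics" necessarily matches
"on an antipsychotic" — is added to the ground truth rather than
dropped, so the returned truth always equals what the matcher finds.
Random planting never selects two predicates competing for the same
scalar fact (one age, one value per lab); explicitly planted sets may,
and then fail loudly.

All streams derive from one integer seed via
`numpy.random.SeedSequence([seed, stream, index])` (stream 0 panels,
1 cohorts; index = round or patient), so outputs are bit-reproducible
and per-patient draws are independent of cohort size.

What the generators do **not** emulate: opinion change between rounds
(rounds are independent), correlation structure among indicators in
real patients, realistic marginal prevalences, or free-text comments.
Passing round-trip tests therefore demonstrates the correctness of the
matching and classification machinery, not the clinical performance of
the indicator set on real wards.

## Problem sizes in the test suite

The suite exercises brute-force oracles up to 50 × 50 rating matrices,
a 500-patient planted cohort for the triage round-trip, and a
2000-rater panel for distribution-mode convergence (±3 percentage
points); these sizes give exact or tightly-bounded checks while
keeping the whole suite in the low seconds.

## Known limitations

- The merge-plan membership and some predicate parameterisations
  reconstruct unpublished editorial decisions; they are marked as
  inferred where so.
- The indicator grouping into the four handling groups is keyword
  heuristics over wordings, used only for organisation.
- Medication matching is exact lower-cased string equality against
  catalog lists; deployments would substitute a terminology service.
- The engine computes no pharmacology (no interaction checking, dose
  screening or QTc maths): it classifies recorded facts.
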