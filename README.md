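# impact-tool

Consensus-driven patient prioritization for mental health inpatient
pharmacy teams: a modified-Delphi consensus engine and the traffic-light
triage tool it produces.

## The problem

Inpatient mental health pharmacy teams cannot review every patient every
day. A defensible way to ration attention is to triage patients by their
risk of drug-related problems — an event or circumstance involving drug
therapy that actually or potentially interferes with desired health
outcomes — using a catalog of risk indicators (high-risk medicines such
as clozapine and lithium, patient factors such as renal impairment,
drug factors such as polypharmacy, and organisational factors such as
time since last pharmacy review) agreed by an expert panel.

This package implements both computational halves of that workflow:

1. **Consensus engine** (`consensus`, `feedback`): per-item band
   summaries of 7-point Likert ratings (median; % of valid ratings in
   the 1–2, 3–5, 5–7 and 6–7 bands, with "outside my expertise" and
   missing responses excluded from denominators), percent-agreement
   decision rules, controlled-feedback documents for second rounds, and
   plurality rank aggregation with a cascading tie-break. The decision
   rules are, with P_b the percentage of valid ratings in band b:
   - *inclusion / agreement*: P₆₋₇ ≥ 75 % **or** P₅₋₇ ≥ 85 %;
   - *risk tier*: red if P₆₋₇ ≥ 75 %, amber if P₃₋₅ ≥ 75 %, green if
     P₁₋₂ ≥ 75 %, else amber when a majority rated 3–7 (stakeholder
     fallback).
2. **Triage engine** (`catalog`, `triage`, `scheduler`): a
   machine-readable indicator catalog with editorial operations (source
   union, merge plans, exclusions), a predicate grammar for matching
   patient records (medications, labs with units, flags, demographics),
   red/amber/green classification with the agreed amber-escalation rule
   (> 4 amber criteria → red), clinical-judgement overrides with a
   compulsory comment, and review scheduling (red: every 1–2 days,
   amber: every 2–4 days, green: once every working week or sooner on
   referral) with an overdue-first worklist.

The full panel dataset — aggregate ratings for 123 risk indicators over
two Delphi rounds, 30 tool-use statements, and the ranking tallies — is
packaged as fixtures, so every headline number of the source study is
recomputable offline. A seeded synthetic module (`synthetic`) generates
rating matrices with controllable consensus structure and patient
cohorts with planted indicator matches for testing.

## Worked example

```python
from impact_tool import fixtures
from impact_tool.consensus import Dimension, run_round, winner_by_first_choice
from impact_tool.triage import PatientRecord, Medication, LabResult, \
    match_indicators, classify

# 1. which indicators reached consensus in round 2?
report = run_round(fixtures.table2_band_summaries(2, Dimension.IMPORTANCE),
                   decision="inclusion")
print(report.n_included, "/", report.n_items)      # 82 / 123

# 2. the preferred classification system
print(winner_by_first_choice(fixtures.classification_ranking()))
# ('traffic_light', 17)

# 3. triage a patient against the 71-indicator tool catalog
catalog = fixtures.development_catalog()
patient = PatientRecord(
    patient_id="example", age=45,
    medications=[Medication(name="clozapine", med_class="antipsychotic")],
    labs=[LabResult(name="egfr", value=40, units="mL/min")])
matches = match_indicators(patient, catalog)
result = classify(matches, patient_id=patient.patient_id)
print(result.tier.value, [m.indicator_id for m in matches])
# red ['1', '4', '10']
```

The first call applies the inclusion rule to the round-2 importance
percentages of all 123 indicators: 82 meet it. The triage call matches
clozapine by name (a red indicator), the antipsychotic class (amber)
and an eGFR of 40 mL/min (the moderate-CKD red indicator), so the
patient is red without needing the amber-escalation rule.

The same operations are exposed on the command line:

```bash
impact consensus --fixture table2 --round 1 --dimension importance --out report
# 47/109 items met the inclusion rule (43.1%)
impact triage --patients cohort.json --amber-threshold 4 --out triage
impact synth --spec spec.yaml --seed 42 --out synthetic
```

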