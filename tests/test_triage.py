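"""Predicate grammar, indicator matching, classification and overrides."""

from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

from impact_tool.catalog import Tier
from impact_tool.triage import (DEFAULT_POLICY, IndicatorMatch, LabResult,
                                Medication, PatientRecord, TriageError,
                                TriagePolicy, UnitMismatchError, apply_override,
                                classify, evaluate_predicate, match_indicators)

TODAY = date(2024, 6, 3)


def patient(**kw):
    base = dict(patient_id="p1", age=45.0)
    base.update(kw)
    return PatientRecord(**base)


class TestEvaluatePredicate:
    def test_medication_name_match(self):
        p = patient(medications=[Medication(name="Clozapine")])
        spec = {"type": "medication_name_in", "names": ["clozapine"]}
        assert evaluate_predicate(p, spec) == "medication Clozapine"

    def test_lab_range_match(self):
        p = patient(labs=[LabResult(name="eGFR", value=40, units="mL/min")])
        spec = {"type": "lab_compare", "lab": "egfr", "units": "mL/min",
                "op": "between", "low": 30, "high": 44}
        assert "40" in evaluate_predicate(p, spec)

    def test_lab_unit_mismatch_never_converts(self):
        p = patient(labs=[LabResult(name="egfr", value=40, units="mL/s")])
        spec = {"type": "lab_compare", "lab": "egfr", "units": "mL/min",
                "op": "lt", "value": 60}
        with pytest.raises(UnitMismatchError):
            evaluate_predicate(p, spec)

    def test_most_recent_lab_decides(self):
        p = patient(labs=[
            LabResult(name="egfr", value=40, units="mL/min", date=date(2024, 5, 1)),
            LabResult(name="egfr", value=70, units="mL/min", date=date(2024, 6, 1)),
        ])
        spec = {"type": "lab_compare", "lab": "egfr", "units": "mL/min",
                "op": "between", "low": 30, "high": 44}
        assert evaluate_predicate(p, spec) is None

    @pytest.mark.parametrize("n_meds,expect", [(9, False), (10, True)])
    def test_polypharmacy_boundary_inclusive(self, n_meds, expect):
        meds = [Medication(name=f"m{i}") for i in range(n_meds)]
        spec = {"type": "regular_med_count_ge", "min_count": 10}
        got = evaluate_predicate(patient(medications=meds), spec)
        assert (got is not None) is expect

    def test_prn_medication_not_counted_as_regular(self):
        meds = [Medication(name=f"m{i}") for i in range(9)]
        meds.append(Medication(name="prn", regular=False))
        spec = {"type": "regular_med_count_ge", "min_count": 10}
        assert evaluate_predicate(patient(medications=meds), spec) is None

    @pytest.mark.parametrize("age,op,years,expect", [
        (80, "gt", 80, False), (80.5, "gt", 80, True),
        (18, "lt", 18, False), (17.9, "lt", 18, True),
    ])
    def test_age_boundaries_exclusive(self, age, op, years, expect):
        spec = {"type": "age_compare", "op": op, "years": years}
        assert (evaluate_predicate(patient(age=age), spec) is not None) is expect

    def test_missed_dose_by_class(self):
        p = patient(medications=[
            Medication(name="sertraline", med_class="antidepressant",
                       missed_doses=2)])
        spec = {"type": "missed_dose_of", "classes": ["antidepressant"]}
        assert "missed" in evaluate_predicate(p, spec)

    def test_days_since_last_review(self):
        p = patient(last_review=date(2024, 5, 20))
        spec = {"type": "days_since_event_ge", "event": "last_review", "days": 8}
        assert evaluate_predicate(p, spec, today=TODAY) is not None

    def test_manual_predicate_never_auto_matches(self):
        assert evaluate_predicate(patient(), {"type": "manual"}) is None

    def test_incomplete_spec_rejected(self):
        with pytest.raises(TriageError, match="missing parameter"):
            evaluate_predicate(patient(), {"type": "flag_present"})

    def test_manual_with_parameters_rejected(self):
        with pytest.raises(TriageError, match="parameters"):
            evaluate_predicate(patient(), {"type": "manual", "flag": "x"})


class TestMatchIndicators:
    def test_empty_record_matches_nothing(self, tool_catalog):
        assert match_indicators(patient(), tool_catalog, today=TODAY) == []

    def test_lithium_with_toxic_level_matches_both_indicators(self, tool_catalog):
        p = patient(medications=[Medication(name="lithium",
                                            med_class="mood_stabiliser")],
                    flags={"toxic_lithium_level": True})
        ids = {m.indicator_id for m in
               match_indicators(p, tool_catalog, today=TODAY)}
        assert ids == {"5", "20"}

    def test_manual_flag_injects_match(self, tool_catalog):
        # indicator 29: significant drug interaction (clinical judgement)
        ms = match_indicators(patient(), tool_catalog, manual_flags=["29"],
                              today=TODAY)
        assert [(m.indicator_id, m.mode) for m in ms] == [("29", "manual")]

    def test_manual_flag_for_unknown_indicator_rejected(self, tool_catalog):
        with pytest.raises(TriageError, match="unknown"):
            match_indicators(patient(), tool_catalog, manual_flags=["999"])

    def test_manual_flag_for_automatic_indicator_rejected(self, tool_catalog):
        with pytest.raises(TriageError, match="non-manual"):
            match_indicators(patient(), tool_catalog, manual_flags=["4"])

    def test_merged_indicators_never_match(self, tool_catalog):
        # indicator 60 (warfarin) was absorbed; the representative matches
        p = patient(medications=[Medication(name="warfarin",
                                            med_class="anticoagulant")])
        ids = {m.indicator_id for m in
               match_indicators(p, tool_catalog, today=TODAY)}
        assert "60" not in ids and "51" in ids


def amber(i):
    return IndicatorMatch(indicator_id=f"a{i}", tier=Tier.AMBER, evidence="e")


def red(i=0):
    return IndicatorMatch(indicator_id=f"r{i}", tier=Tier.RED, evidence="e")


class TestClassify:
    def test_any_red_match_dominates(self):
        res = classify([red(), amber(1), amber(2)])
        assert res.tier is Tier.RED and not res.escalated

    def test_five_ambers_escalate_at_default_threshold(self):
        res = classify([amber(i) for i in range(5)])
        assert res.tier is Tier.RED and res.escalated

    def test_no_matches_is_green(self):
        res = classify([])
        assert res.tier is Tier.GREEN and not res.escalated

    def test_some_ambers_without_escalation(self):
        res = classify([amber(1), amber(2)])
        assert res.tier is Tier.AMBER

    @pytest.mark.parametrize("k", range(1, 7))
    def test_escalation_boundary_for_all_thresholds(self, k):
        policy = TriagePolicy(amber_escalation_threshold=k)
        at = classify([amber(i) for i in range(k)], policy)
        above = classify([amber(i) for i in range(k + 1)], policy)
        assert at.tier is Tier.AMBER and not at.escalated
        assert above.tier is Tier.RED and above.escalated

    def test_invariant_to_match_order(self):
        ms = [amber(2), red(), amber(1)]
        assert classify(ms).tier is classify(list(reversed(ms))).tier
        assert classify(ms).matches == classify(list(reversed(ms))).matches


@settings(deadline=None, max_examples=50, derandomize=True)
@given(n_red=st.integers(0, 3), n_amber=st.integers(0, 8),
       extra=st.sampled_from(["red", "amber"]))
def test_adding_a_match_never_lowers_severity(n_red, n_amber, extra):
    ms = [red(i) for i in range(n_red)] + [amber(i) for i in range(n_amber)]
    before = classify(ms).tier.severity
    ms.append(red(99) if extra == "red" else amber(99))
    assert classify(ms).tier.severity >= before


class TestOverride:
    def test_override_keeps_audit_trail(self):
        res = classify([])
        out = apply_override(res, Tier.RED, "new rapid titration", "rx1")
        assert out.tier is Tier.RED
        assert out.override.original_tier is Tier.GREEN
        assert out.override.comment == "new rapid titration"
        assert out.override.author == "rx1"

    @pytest.mark.parametrize("comment", ["", "   "])
    def test_blank_comment_rejected(self, comment):
        with pytest.raises(TriageError, match="comment"):
            apply_override(classify([]), Tier.RED, comment, "rx1")

    def test_comment_optional_when_policy_relaxed(self):
        policy = TriagePolicy(require_override_comment=False)
        out = apply_override(classify([]), Tier.AMBER, "", "rx1", policy)
        assert out.tier is Tier.AMBER

    def test_override_disallowed_by_policy(self):
        policy = TriagePolicy(allow_override=False)
        with pytest.raises(TriageError, match="disallow"):
            apply_override(classify([]), Tier.RED, "c", "rx1", policy)
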