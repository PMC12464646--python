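"""Packaged study data: the published Delphi round aggregates and rankings.

The entire quantitative dataset of the development study is printed as
four tables of per-item aggregates; this module loads the transcribed
fixtures and rebuilds the catalogs used downstream:

* ``table2_aggregates`` — per risk-indicator band summaries for both
  Delphi-1 rounds (risk and importance dimensions, 123 indicators);
* ``table4_statements`` — per tool-use statement summaries for both
  Delphi-2 rounds (30 statements);
* ``rankings`` — the classification-system ranking and the per-tier
  review-frequency rankings;
* ``study_catalog`` / ``development_catalog`` — the 123-indicator panel
  catalog and the 71-indicator tool catalog derived from it via the
  consensus rules and the editorial merge plan.

Percentages are stored in the CSVs exactly as printed (one decimal) and
parsed to floats without re-rounding, so threshold decisions run on the
published values.
"""

from __future__ import annotations

import json
from datetime import date
from importlib import resources
from pathlib import Path

import pandas as pd

from .catalog import (Group, IndicatorCatalog, MergeGroup, RiskIndicator,
                      Source, Tier, apply_merge_plan)
from .consensus import (BandSummary, ConsensusRule, DEFAULT_RULE, Dimension,
                        RankingTally, assign_tier, include_indicator)


def _data_path(name: str) -> Path:
    return Path(resources.files("impact_tool").joinpath("data", name))


def table2_aggregates() -> pd.DataFrame:
    """Long-format Delphi-1 aggregates: one row per indicator x round x dimension.

    Indicators added in round 2 have empty round-1 cells (NaN).
    """
    df = pd.read_csv(_data_path("table2_aggregates.csv"),
                     dtype={"row": int, "round": int})
    return df


def table4_statements() -> pd.DataFrame:
    """Delphi-2 statement aggregates, one row per statement x round."""
    return pd.read_csv(_data_path("table4_statements.csv"),
                       dtype={"statement": int, "round": int})


def _t2_summary(rec) -> BandSummary:
    dim = Dimension(rec.dimension)
    kwargs = dict(item=str(rec.row), dimension=dim, round=int(rec.round),
                  median=float(rec.median), pct_6_7=float(rec.pct_6_7))
    if dim is Dimension.RISK:
        p35 = float(rec.pct_3_5)
        kwargs["pct_3_5"] = p35
        kwargs["pct_1_2"] = max(0.0, round(100.0 - p35 - kwargs["pct_6_7"], 1))
    else:
        kwargs["pct_5_7"] = float(rec.pct_5_7)
    return BandSummary(**kwargs)


def table2_band_summaries(round: int, dimension: Dimension | str
                          ) -> list[BandSummary]:
    """Band summaries for one round/dimension, skipping unrated items.

    Round 1 yields 109 summaries (the 14 indicators added in round 2
    were not rated then); round 2 yields all 123.
    """
    dim = Dimension(dimension)
    df = table2_aggregates()
    sel = df[(df["round"] == round) & (df["dimension"] == dim.value)]
    sel = sel.dropna(subset=["median", "pct_6_7"])
    return [_t2_summary(rec) for rec in sel.itertuples(index=False)]


def table4_band_summaries(round: int) -> list[BandSummary]:
    """Agreement-dimension summaries for one Delphi-2 round.

    Round 1 yields 29 statements; round 2 yields 30 (one added).
    """
    df = table4_statements()
    sel = df[df["round"] == round].dropna(subset=["median", "pct_6_7"])
    return [
        BandSummary(item=str(rec.statement), dimension=Dimension.AGREEMENT,
                    round=int(rec.round), n_valid=int(rec.n),
                    median=float(rec.median), pct_5_7=float(rec.pct_5_7),
                    pct_6_7=float(rec.pct_6_7))
        for rec in sel.itertuples(index=False)
    ]


def _rankings_payload() -> dict:
    return json.loads(_data_path("rankings.json").read_text(encoding="utf-8"))


def _tally(block: dict) -> RankingTally:
    return RankingTally(
        counts={k: tuple(v["counts"]) for k, v in block["options"].items()},
        n_rankers=block["n_rankers"],
        labels={k: v["label"] for k, v in block["options"].items()})


def classification_ranking() -> RankingTally:
    """Panel ranking of candidate classification systems (29 rankers)."""
    return _tally(_rankings_payload()["classification_systems"])


def review_frequency_ranking(tier: Tier | str) -> RankingTally:
    """Panel ranking of review frequencies for one risk tier."""
    tier = Tier(tier)
    return _tally(_rankings_payload()["review_frequency"][tier.value])


# ---------------------------------------------------------------------------
# catalogs
# ---------------------------------------------------------------------------

_HOSPITAL_KEYWORDS = ("pharmacist", "pharmacy", "homecare", "clinical trial",
                      "formulary", "discharge", "self-administration",
                      "self‐administration", "compliance aid", "seclusion",
                      "ward", "electroconvulsive")
_DRUG_KEYWORDS = ("missed", "dose", "polypharmacy", "more than",
                  "interaction", "adverse drug", "depot", "covert",
                  "unlicensed", "off-label", "off‐label", "unverified",
                  "cessation", "prescribed", "rapid", "spitting",
                  "high-dose", "high‐dose", "bnf", "vte", "t2/t3",
                  "monitoring", "formulation")
_PATIENT_KEYWORDS = ("patient", "ckd", "impairment", "levels", "fall",
                     "capacity", "aged", "swallowing", "qtc results",
                     "allergy", "substance", "smoking", "covid", "dementia",
                     "hospitalisation", "electrocardiogram", "country",
                     "palliative", "harm")


def _infer_group(text: str) -> Group:
    low = text.lower()
    for kw in _HOSPITAL_KEYWORDS:
        if kw in low:
            return Group.HOSPITAL_RELATED
    for kw in _DRUG_KEYWORDS:
        if kw in low:
            return Group.DRUG_RELATED
    for kw in _PATIENT_KEYWORDS:
        if kw in low:
            return Group.PATIENT_RELATED
    return Group.HIGH_RISK_MEDICINE


def _split_modified(text: str) -> tuple[str, str | None]:
    """Rows reworded between rounds read '<original> Round 2: <new>'."""
    marker = "Round 2:"
    if marker in text:
        original, new = text.split(marker, 1)
        return new.strip(), original.strip().rstrip(".")
    return text, None


#: Machine predicates for the active indicators of the development catalog.
#: Indicators whose wording needs clinical judgement or an external
#: knowledge base are typed "manual" and match only via an explicit flag.
PREDICATES: dict[int, dict] = {
    1: {"type": "medication_class_in", "classes": ["antipsychotic"]},
    2: {"type": "medication_class_in", "classes": ["anticonvulsant"]},
    3: {"type": "medication_class_in", "classes": ["strong_opioid"]},
    4: {"type": "medication_name_in", "names": ["clozapine"]},
    5: {"type": "medication_name_in",
        "names": ["lithium", "lithium carbonate", "lithium citrate", "priadel"]},
    6: {"type": "medication_class_in", "classes": ["insulin"]},
    7: {"type": "medication_name_in",
        "names": ["valproate", "sodium valproate", "valproic acid",
                  "semisodium valproate"]},
    8: {"type": "missed_dose_of",
        "classes": ["psychotropic", "antipsychotic", "antidepressant",
                    "mood_stabiliser", "anxiolytic", "hypnotic"]},
    10: {"type": "lab_compare", "lab": "egfr", "units": "mL/min",
         "op": "between", "low": 30, "high": 59},
    11: {"type": "lab_compare", "lab": "egfr", "units": "mL/min",
         "op": "lt", "value": 30},
    14: {"type": "flag_present", "flag": "enteral_tube"},
    15: {"type": "flag_present", "flag": "bpsd_not_on_dementia_ward"},
    16: {"type": "flag_present", "flag": "covert_administration"},
    17: {"type": "flag_present", "flag": "refusing_medication"},
    18: {"type": "flag_present", "flag": "high_creatine_kinase"},
    19: {"type": "flag_present", "flag": "toxic_clozapine_level"},
    20: {"type": "flag_present", "flag": "toxic_lithium_level"},
    21: {"type": "flag_present", "flag": "qtc_outside_range"},
    23: {"type": "flag_present", "flag": "unverified_new_medication"},
    24: {"type": "flag_present", "flag": "unlicensed_medicine"},
    25: {"type": "flag_present", "flag": "abrupt_cessation"},
    26: {"type": "medication_class_in", "classes": ["depot_antipsychotic"]},
    27: {"type": "medication_name_in",
         "names": ["zuclopenthixol acetate", "zuclopenthixol acuphase"]},
    28: {"type": "manual"},
    29: {"type": "manual"},
    30: {"type": "regular_med_count_ge", "min_count": 2,
         "classes": ["antipsychotic"]},
    31: {"type": "regular_med_count_ge", "min_count": 2, "classes": ["hypnotic"]},
    32: {"type": "manual"},
    34: {"type": "missed_dose_of", "classes": ["high_risk"]},
    36: {"type": "flag_present", "flag": "high_dose_antipsychotic"},
    37: {"type": "flag_present", "flag": "above_bnf_limit"},
    38: {"type": "manual"},
    39: {"type": "flag_present", "flag": "rapid_tranquillisation"},
    40: {"type": "flag_present", "flag": "acute_renal_impairment"},
    41: {"type": "flag_present", "flag": "chronic_hepatic_impairment"},
    42: {"type": "flag_present", "flag": "receiving_ect"},
    43: {"type": "manual"},
    44: {"type": "flag_present", "flag": "electrolytes_outside_range"},
    45: {"type": "days_since_event_ge", "event": "last_review", "days": 8},
    46: {"type": "regular_med_count_ge", "min_count": 10},
    47: {"type": "flag_present", "flag": "mha_t2_t3"},
    48: {"type": "flag_present", "flag": "swallowing_difficulty"},
    49: {"type": "flag_present", "flag": "acute_hepatic_impairment"},
    50: {"type": "medication_class_in", "classes": ["antiparkinsonian"]},
    51: {"type": "medication_class_in", "classes": ["anticoagulant"]},
    52: {"type": "manual"},
    53: {"type": "manual"},
    55: {"type": "flag_present", "flag": "recent_overseas_admission"},
    56: {"type": "flag_present", "flag": "lacks_capacity"},
    57: {"type": "age_compare", "op": "gt", "years": 80},
    58: {"type": "flag_present", "flag": "wbc_outside_range"},
    59: {"type": "flag_present", "flag": "outstanding_ecg"},
    61: {"type": "medication_name_in",
         "names": ["phenytoin", "carbamazepine", "digoxin", "theophylline",
                   "gentamicin", "vancomycin"]},
    62: {"type": "flag_present", "flag": "recent_fall"},
    63: {"type": "regular_med_count_ge", "min_count": 2,
         "classes": ["antidepressant"]},
    64: {"type": "medication_class_in", "classes": ["qtc_prolonging"]},
    65: {"type": "flag_present", "flag": "substance_misuse"},
    66: {"type": "flag_present", "flag": "physical_health_follow_up"},
    67: {"type": "age_compare", "op": "gt", "years": 70},
    68: {"type": "flag_present", "flag": "allergy_status_undetermined"},
    69: {"type": "flag_present", "flag": "planned_discharge"},
    71: {"type": "manual"},
    72: {"type": "flag_present", "flag": "seclusion"},
    74: {"type": "age_compare", "op": "lt", "years": 18},
    75: {"type": "flag_present", "flag": "palliative_care"},
    76: {"type": "age_compare", "op": "lt", "years": 12},
    77: {"type": "medication_name_in", "names": ["pabrinex", "chlordiazepoxide"]},
    78: {"type": "regular_med_count_ge", "min_count": 2, "classes": ["anxiolytic"]},
    79: {"type": "flag_present", "flag": "self_harm_risk"},
    81: {"type": "medication_class_in", "classes": ["cytotoxic"]},
    82: {"type": "flag_present", "flag": "haemoglobin_outside_range"},
}


def study_catalog(rule: ConsensusRule = DEFAULT_RULE) -> IndicatorCatalog:
    """The full 123-indicator panel catalog with round-2 decisions attached.

    Every indicator rated by the panel is present and active; indicators
    meeting the round-2 inclusion rule carry the tier assigned from the
    round-2 risk ratings, everything else stays unassigned. Item ids are
    the published row numbers.
    """
    imp = {s.item: s for s in table2_band_summaries(2, Dimension.IMPORTANCE)}
    risk = {s.item: s for s in table2_band_summaries(2, Dimension.RISK)}
    round1_items = {s.item for s in table2_band_summaries(1, Dimension.IMPORTANCE)}
    df = table2_aggregates()
    meta = df[(df["round"] == 2) & (df["dimension"] == "importance")]

    indicators = []
    for rec in meta.itertuples(index=False):
        item = str(rec.row)
        text, original = _split_modified(rec.indicator_text)
        included = include_indicator(imp[item], rule)
        tier = assign_tier(risk[item], rule) if included else Tier.UNASSIGNED
        if item in round1_items:
            sources = (Source.SYSTEMATIC_REVIEW, Source.PRACTICE_SURVEY)
            note = "from the combined source lists (per-item provenance unpublished)"
        else:
            sources = (Source.PANEL_ROUND2_ADDITION,)
            note = "added after round 1 from panel suggestions"
        if original is not None:
            note += f"; Modified from: {original}"
        indicators.append(RiskIndicator(
            id=item, text=text, group=_infer_group(text), sources=sources,
            status="modified" if original is not None else "active",
            tier=tier, predicate=None,
            notes=note + ("" if included else "; did not meet inclusion rule")))
    return IndicatorCatalog(version="delphi1-round2",
                            created=date(2024, 2, 1), indicators=indicators)


def merge_plan() -> tuple[list[MergeGroup], list[str], str]:
    payload = json.loads(_data_path("merge_plan.json").read_text(encoding="utf-8"))
    plan = [MergeGroup(representative=m["representative"],
                       absorbed=tuple(m["absorbed"]), note=m.get("note", ""))
            for m in payload["merges"]]
    return plan, list(payload["exclusions"]), payload.get("exclusion_note", "")


def development_catalog(rule: ConsensusRule = DEFAULT_RULE) -> IndicatorCatalog:
    """The tool catalog: included indicators after merges and exclusions.

    Starts from the indicators meeting the round-2 inclusion rule,
    applies the packaged editorial merge plan, and attaches a matching
    predicate to every remaining active indicator (71 with the shipped
    data). Active indicators without a consensus tier are treated as
    amber downstream, per the stakeholder fallback.
    """
    from dataclasses import replace

    base = study_catalog(rule)
    included_ids = {s.item for s in table2_band_summaries(2, Dimension.IMPORTANCE)
                    if include_indicator(s, rule)}
    cat = IndicatorCatalog(
        version="impact-tool", created=base.created,
        indicators=[i for i in base if i.id in included_ids])
    plan, exclusions, note = merge_plan()
    cat = apply_merge_plan(cat, plan, exclusions, exclusion_note=note)
    out = [replace(ind, predicate=dict(PREDICATES.get(int(ind.id),
                                                      {"type": "manual"})))
           if ind.is_active else ind
           for ind in cat]
    return IndicatorCatalog(version=cat.version, created=cat.created,
                            indicators=out)
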