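{
  "note": "Editorial refinement applied to the 82 indicators reaching consensus, reducing the catalog to the 71 used in the tool. Only the CKD regrouping is described in the published text; every other entry is an inferred, plausibility-based reconstruction (marked 'inferred') since the authoritative membership sits in an unpublished appendix. The arithmetic (10 absorbed + 1 excluded) is authoritative.",
  "merges": [
    {"representative": "10", "absorbed": ["9"], "note": "CKD stages combined: CKD stage <= 3b group (eGFR 30-59 mL/min)"},
    {"representative": "11", "absorbed": ["12"], "note": "CKD stages combined: CKD stage > 3b group (eGFR < 30 mL/min)"},
    {"representative": "8", "absorbed": ["33"], "note": "inferred: missed doses folded into missed mental health medications"},
    {"representative": "34", "absorbed": ["35"], "note": "inferred: missed high-risk mental-health doses folded into missed high-risk doses"},
    {"representative": "48", "absorbed": ["13"], "note": "inferred: new swallowing difficulties folded into swallowing difficulties / nil by mouth"},
    {"representative": "41", "absorbed": ["73"], "note": "inferred: moderate hepatic impairment folded into chronic hepatic impairment"},
    {"representative": "46", "absorbed": ["80"], "note": "inferred: polypharmacy >=5 folded into polypharmacy >=10"},
    {"representative": "47", "absorbed": ["70"], "note": "inferred: T2/T3 renewal folded into new T2/T3 under the Mental Health Act"},
    {"representative": "39", "absorbed": ["54"], "note": "inferred: oral when-required psychotropic folded into rapid tranquillisation"},
    {"representative": "51", "absorbed": ["60"], "note": "inferred: warfarin folded into anticoagulants"}
  ],
  "exclusions": ["22"],
  "exclusion_note": "inferred: medicines prescribed as part of a clinical trial excluded by stakeholders"
}
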