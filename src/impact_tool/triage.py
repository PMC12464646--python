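"""Traffic-light triage engine.

Matches a patient record against the active indicator catalog through a
small predicate grammar, classifies the patient red/amber/green, applies
the consensus-backed amber-escalation rule (more than ``threshold``
amber criteria promotes the patient to red), and supports clinical-
judgement overrides with a compulsory comment.

The engine consumes recorded clinical facts only — medication lists,
laboratory results with units, and boolean flags. It performs no
pharmacology: indicators whose wording requires clinical judgement
(significant interaction, adverse drug reaction, nonadherence, ...) are
typed ``manual`` and match only when a user raises them explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
import datetime as _dt
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from pydantic import BaseModel, Field, field_validator

from .catalog import IndicatorCatalog, RiskIndicator, Tier


class TriageError(ValueError):
    """Invalid triage input (schema, units, unknown flag, bad override)."""


class UnitMismatchError(TriageError):
    """A lab comparison met a result recorded in different units."""


# ---------------------------------------------------------------------------
# patient records
# ---------------------------------------------------------------------------

class Medication(BaseModel):
    name: str
    med_class: str = Field(default="", alias="class")
    route: str = "oral"
    regular: bool = True
    start: Optional[date] = None
    missed_doses: int = 0

    model_config = {"populate_by_name": True}

    @field_validator("missed_doses")
    @classmethod
    def _non_negative(cls, v: int) -> int:
        if v < 0:
            raise ValueError("missed_doses must be >= 0")
        return v


class LabResult(BaseModel):
    name: str
    value: float
    units: str
    date: Optional[_dt.date] = None


class PatientRecord(BaseModel):
    """The triage engine's input: demographics, medications, labs, flags."""

    patient_id: str
    age: float
    ward: str = ""
    admitted: Optional[date] = None
    medications: list[Medication] = Field(default_factory=list)
    labs: list[LabResult] = Field(default_factory=list)
    flags: dict[str, bool] = Field(default_factory=dict)
    last_review: Optional[date] = None

    @field_validator("age")
    @classmethod
    def _age_non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("age must be non-negative")
        return v

    def flag(self, key: str) -> bool:
        return bool(self.flags.get(key, False))


def load_patients(path: str | Path) -> list[PatientRecord]:
    """Read patient records from a JSON file (a list or a single object)."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if isinstance(payload, dict):
        payload = [payload]
    return [PatientRecord.model_validate(p) for p in payload]


def save_patients(patients: Sequence[PatientRecord], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(
        [json.loads(p.model_dump_json(by_alias=True)) for p in patients],
        indent=2) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# predicate grammar
# ---------------------------------------------------------------------------

PREDICATE_TYPES = frozenset({
    "medication_name_in", "medication_class_in", "regular_med_count_ge",
    "missed_dose_of", "lab_compare", "age_compare", "flag_present",
    "days_since_event_ge", "manual",
})

_COMPARATORS = {
    "lt": lambda x, v: x < v,
    "le": lambda x, v: x <= v,
    "gt": lambda x, v: x > v,
    "ge": lambda x, v: x >= v,
}


def validate_predicate(spec: dict) -> dict:
    """Check a predicate spec is complete for its declared type."""
    ptype = spec.get("type")
    if ptype not in PREDICATE_TYPES:
        raise TriageError(f"unknown predicate type {ptype!r}")
    need = {
        "medication_name_in": ("names",),
        "medication_class_in": ("classes",),
        "regular_med_count_ge": ("min_count",),
        "missed_dose_of": (),
        "lab_compare": ("lab", "units", "op"),
        "age_compare": ("op", "years"),
        "flag_present": ("flag",),
        "days_since_event_ge": ("event", "days"),
        "manual": (),
    }[ptype]
    for key in need:
        if key not in spec:
            raise TriageError(f"predicate {ptype}: missing parameter {key!r}")
    if ptype == "missed_dose_of" and not (spec.get("names") or spec.get("classes")):
        raise TriageError("predicate missed_dose_of: needs names or classes")
    if ptype == "lab_compare":
        op = spec["op"]
        if op == "between":
            if "low" not in spec or "high" not in spec:
                raise TriageError("lab_compare between: needs low and high")
        elif op in _COMPARATORS:
            if "value" not in spec:
                raise TriageError(f"lab_compare {op}: needs value")
        else:
            raise TriageError(f"lab_compare: unknown op {op!r}")
    if ptype == "age_compare" and spec["op"] not in _COMPARATORS:
        raise TriageError(f"age_compare: unknown op {spec['op']!r}")
    if ptype == "manual":
        extra = set(spec) - {"type"}
        if extra:
            raise TriageError(f"manual predicate carries parameters: {sorted(extra)}")
    return spec


def evaluate_predicate(patient: PatientRecord, spec: dict,
                       today: date | None = None) -> str | None:
    """Evaluate one predicate; return a human-readable evidence string or None.

    ``manual`` predicates always return None — they match only through
    the explicit flag channel of :func:`match_indicators`. Lab
    comparisons raise :class:`UnitMismatchError` on a unit mismatch
    rather than converting silently.
    """
    validate_predicate(spec)
    ptype = spec["type"]

    if ptype == "manual":
        return None

    if ptype == "medication_name_in":
        wanted = {n.lower() for n in spec["names"]}
        for med in patient.medications:
            if med.name.lower() in wanted:
                return f"medication {med.name}"
        return None

    if ptype == "medication_class_in":
        wanted = {c.lower() for c in spec["classes"]}
        for med in patient.medications:
            if med.med_class.lower() in wanted:
                return f"medication {med.name} (class {med.med_class})"
        return None

    if ptype == "regular_med_count_ge":
        classes = {c.lower() for c in spec.get("classes", [])}
        meds = [m for m in patient.medications if m.regular
                and (not classes or m.med_class.lower() in classes)]
        if len(meds) >= int(spec["min_count"]):
            what = f"class {sorted(classes)}" if classes else "regular medications"
            return f"{len(meds)} {what} (threshold {spec['min_count']})"
        return None

    if ptype == "missed_dose_of":
        names = {n.lower() for n in spec.get("names", [])}
        classes = {c.lower() for c in spec.get("classes", [])}
        min_missed = int(spec.get("min_missed", 1))
        for med in patient.medications:
            hit = (med.name.lower() in names) or (med.med_class.lower() in classes)
            if hit and med.missed_doses >= min_missed:
                return f"{med.missed_doses} missed dose(s) of {med.name}"
        return None

    if ptype == "lab_compare":
        lab_name = spec["lab"].lower()
        results = [lab for lab in patient.labs if lab.name.lower() == lab_name]
        for lab in results:
            if lab.units != spec["units"]:
                raise UnitMismatchError(
                    f"lab {lab.name!r}: record in {lab.units!r}, "
                    f"predicate expects {spec['units']!r}")
        # most recent result decides; undated results sort first
        results.sort(key=lambda lab: (lab.date is not None, lab.date or date.min))
        if not results:
            return None
        lab = results[-1]
        op = spec["op"]
        if op == "between":
            ok = float(spec["low"]) <= lab.value <= float(spec["high"])
        else:
            ok = _COMPARATORS[op](lab.value, float(spec["value"]))
        if ok:
            return f"{lab.name} = {lab.value} {lab.units}"
        return None

    if ptype == "age_compare":
        if _COMPARATORS[spec["op"]](patient.age, float(spec["years"])):
            return f"age {patient.age:g} years"
        return None

    if ptype == "flag_present":
        if patient.flag(spec["flag"]):
            return f"flag {spec['flag']}"
        return None

    if ptype == "days_since_event_ge":
        ref = {"last_review": patient.last_review,
               "admitted": patient.admitted}.get(spec["event"])
        if ref is None:
            return None
        today = today or date.today()
        days = (today - ref).days
        if days >= int(spec["days"]):
            return f"{days} days since {spec['event']}"
        return None

    raise TriageError(f"unhandled predicate type {ptype!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# matching and classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndicatorMatch:
    indicator_id: str
    tier: Tier
    evidence: str
    mode: Literal["auto", "manual"] = "auto"

    def __post_init__(self) -> None:
        if self.mode == "auto" and not self.evidence:
            raise TriageError("auto match requires non-empty evidence")


def _effective_tier(indicator: RiskIndicator) -> Tier:
    # stakeholder fallback: live indicators without a consensus tier count amber
    return Tier.AMBER if indicator.tier is Tier.UNASSIGNED else indicator.tier


def match_indicators(patient: PatientRecord, catalog: IndicatorCatalog,
                     manual_flags: Iterable[str] = (),
                     today: date | None = None) -> list[IndicatorMatch]:
    """Evaluate every active catalog indicator against one patient.

    ``manual_flags`` names manual-predicate indicators the assessing
    clinician has raised for this patient; naming an unknown or
    non-manual indicator is an error. Merged and excluded indicators
    never match.
    """
    manual = set(manual_flags)
    active = catalog.active()
    active_ids = {i.id for i in active}
    for fid in sorted(manual):
        ind = catalog.get(fid)
        if ind is None or fid not in active_ids:
            raise TriageError(f"manual flag names unknown/inactive indicator {fid!r}")
        if not ind.is_manual:
            raise TriageError(
                f"manual flag {fid!r} targets a non-manual indicator")
    matches: list[IndicatorMatch] = []
    for ind in active:
        if ind.predicate is None:
            continue
        if ind.is_manual:
            if ind.id in manual:
                matches.append(IndicatorMatch(
                    indicator_id=ind.id, tier=_effective_tier(ind),
                    evidence="raised by assessor", mode="manual"))
            continue
        evidence = evaluate_predicate(patient, ind.predicate, today=today)
        if evidence is not None:
            matches.append(IndicatorMatch(
                indicator_id=ind.id, tier=_effective_tier(ind),
                evidence=evidence))
    return matches


@dataclass(frozen=True)
class TriagePolicy:
    """Classification policy: escalation threshold and override rules.

    ``amber_escalation_threshold=4`` means *more than four* amber
    criteria move the patient to red — the more sensitive of the two
    escalation rules that reached panel agreement (>4 and >5 both did).
    """

    amber_escalation_threshold: int = 4
    allow_override: bool = True
    require_override_comment: bool = True

    def __post_init__(self) -> None:
        if self.amber_escalation_threshold < 1:
            raise TriageError("amber_escalation_threshold must be >= 1")


DEFAULT_POLICY = TriagePolicy()


@dataclass(frozen=True)
class Override:
    target: Tier
    comment: str
    author: str
    original_tier: Tier


@dataclass(frozen=True)
class TriageResult:
    patient_id: str
    tier: Tier
    matches: tuple[IndicatorMatch, ...]
    escalated: bool = False
    override: Override | None = None
    evaluated_at: datetime = field(
        default_factory=lambda: datetime.now(timezone.utc))

    @property
    def n_red(self) -> int:
        return sum(m.tier is Tier.RED for m in self.matches)

    @property
    def n_amber(self) -> int:
        return sum(m.tier is Tier.AMBER for m in self.matches)


def classify(matches: Sequence[IndicatorMatch],
             policy: TriagePolicy = DEFAULT_POLICY,
             patient_id: str = "") -> TriageResult:
    """Classify from matches: any red -> red; more than ``threshold``
    ambers -> red (escalated); any amber -> amber; otherwise green."""
    matches = tuple(sorted(matches, key=lambda m: m.indicator_id))
    n_red = sum(m.tier is Tier.RED for m in matches)
    n_amber = sum(m.tier is Tier.AMBER for m in matches)
    if n_red > 0:
        tier, escalated = Tier.RED, False
    elif n_amber > policy.amber_escalation_threshold:
        tier, escalated = Tier.RED, True
    elif n_amber > 0:
        tier, escalated = Tier.AMBER, False
    else:
        tier, escalated = Tier.GREEN, False
    return TriageResult(patient_id=patient_id, tier=tier, matches=matches,
                        escalated=escalated)


def apply_override(result: TriageResult, target: Tier | str, comment: str,
                   author: str,
                   policy: TriagePolicy = DEFAULT_POLICY) -> TriageResult:
    """Clinical-judgement override: replace the tier, keeping an audit trail.

    The comment is compulsory (non-blank) whenever the policy requires
    one; overrides must be enabled by the policy.
    """
    if not policy.allow_override:
        raise TriageError("overrides are disallowed by policy")
    if policy.require_override_comment and not comment.strip():
        raise TriageError("override requires a non-empty comment")
    target = Tier(target)
    if target is Tier.UNASSIGNED:
        raise TriageError("cannot override to the unassigned tier")
    return replace(result, tier=target,
                   override=Override(target=target, comment=comment,
                                     author=author,
                                     original_tier=result.tier))


def triage_to_frame(results: Sequence[TriageResult]):
    """Tabulate triage results (one row per patient)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "patient_id": r.patient_id, "tier": r.tier.value,
            "n_red": r.n_red, "n_amber": r.n_amber,
            "escalated": r.escalated,
            "override": r.override.comment if r.override else "",
            "matched_ids": "|".join(m.indicator_id for m in r.matches),
        })
    return pd.DataFrame(rows, columns=["patient_id", "tier", "n_red", "n_amber",
                                       "escalated", "override", "matched_ids"])
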