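"""Seeded generators for panel ratings and patient cohorts.

Everything downstream is testable without external data: panels with
controllable consensus structure (exact per-score counts or target
distributions, outside-expertise responses, between-round dropout) and
patient cohorts with planted indicator matches whose ground truth is
returned alongside the records.

A single integer seed drives every stream. Streams are split with
``numpy.random.SeedSequence([seed, stream, index])`` where ``stream``
is 0 for panels and 1 for cohorts and ``index`` is the round or patient
number, so per-patient draws are independent of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from .catalog import IndicatorCatalog, RiskIndicator
from .consensus import Dimension, OUTSIDE_EXPERTISE, RatingMatrix
from .triage import Medication, LabResult, PatientRecord, match_indicators


class GenerationError(ValueError):
    pass


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, index]))


# ---------------------------------------------------------------------------
# panel ratings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ItemSpec:
    """Rating structure for one item: exact counts or a target distribution.

    ``exact_counts`` maps score (1-7) to the number of panellists giving
    that score; the remainder of the panel answers outside-expertise.
    ``distribution`` maps score to probability (normalised internally).
    """

    exact_counts: Mapping[int, int] | None = None
    distribution: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if (self.exact_counts is None) == (self.distribution is None):
            raise GenerationError(
                "item spec needs exactly one of exact_counts / distribution")
        source = self.exact_counts or self.distribution
        for score in source:
            if not 1 <= int(score) <= 7:
                raise GenerationError(f"score {score} outside 1..7")
        if self.exact_counts is not None:
            if any(c < 0 for c in self.exact_counts.values()):
                raise GenerationError("exact counts must be non-negative")
        else:
            if any(p < 0 for p in self.distribution.values()):
                raise GenerationError("probabilities must be non-negative")


@dataclass(frozen=True)
class PanelSpec:
    n_panellists: int
    items: Mapping[str, ItemSpec]
    dimension: Dimension = Dimension.IMPORTANCE
    oe_probability: float = 0.0
    dropout: int = 0           # panellists lost between round 1 and round 2
    study: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_panellists <= 0:
            raise GenerationError("n_panellists must be positive")
        if not 0 <= self.oe_probability <= 1:
            raise GenerationError("oe_probability must be in [0, 1]")
        if not 0 <= self.dropout < self.n_panellists:
            raise GenerationError("dropout must be in [0, n_panellists)")
        for item, ispec in self.items.items():
            if ispec.exact_counts is not None:
                if sum(ispec.exact_counts.values()) > self.n_panellists:
                    raise GenerationError(
                        f"item {item!r}: exact counts exceed the panel size")


def generate_panel(spec: PanelSpec, round: int = 1) -> RatingMatrix:
    """Generate one round's rating matrix.

    Round 2 uses the same panellist ids minus ``dropout`` members
    (chosen by the seeded stream). In exact-count mode the leftover
    panellists answer outside-expertise, so band summaries reproduce the
    specified counts exactly; exact counts refer to the round's panel
    size (round 2 counts must fit ``n_panellists - dropout``).
    """
    if round not in (1, 2):
        raise GenerationError("round must be 1 or 2")
    rng = _rng(spec.seed, 0, round)
    panellists = [f"p{i + 1:03d}" for i in range(spec.n_panellists)]
    if round == 2 and spec.dropout:
        drop_rng = _rng(spec.seed, 0, 99)
        dropped = set(drop_rng.choice(spec.n_panellists, size=spec.dropout,
                                      replace=False))
        panellists = [p for i, p in enumerate(panellists) if i not in dropped]
    n = len(panellists)

    matrix = RatingMatrix(study=spec.study, round=round)
    for item in spec.items:
        ispec = spec.items[item]
        if ispec.exact_counts is not None:
            total = sum(ispec.exact_counts.values())
            if total > n:
                raise GenerationError(
                    f"item {item!r}: exact counts ({total}) exceed round-{round} "
                    f"panel size ({n})")
            responses: list = []
            for score in sorted(ispec.exact_counts):
                responses.extend([int(score)] * ispec.exact_counts[score])
            responses.extend([OUTSIDE_EXPERTISE] * (n - total))
            order = rng.permutation(n)
            assigned = [responses[order[i]] for i in range(n)]
        else:
            scores = sorted(ispec.distribution)
            probs = np.array([ispec.distribution[s] for s in scores], float)
            if probs.sum() <= 0:
                raise GenerationError(f"item {item!r}: degenerate distribution")
            probs /= probs.sum()
            draws = rng.choice(scores, size=n, p=probs)
            oe = rng.random(n) < spec.oe_probability
            assigned = [OUTSIDE_EXPERTISE if oe[i] else int(draws[i])
                        for i in range(n)]
        for p, response in zip(panellists, assigned):
            matrix.add(p, item, spec.dimension, response)
    return matrix


# ---------------------------------------------------------------------------
# patient cohorts
# ---------------------------------------------------------------------------

#: medications guaranteed not to satisfy any shipped catalog predicate
DEFAULT_FORMULARY = ("paracetamol", "senna", "lactulose", "cetirizine",
                     "omeprazole", "simvastatin")

_TODAY = date(2024, 6, 3)  # fixed reference date (a Monday) for reproducibility


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int
    planting_probability: float | Mapping[str, float] = 0.0
    exact_planted: Sequence[Sequence[str]] | None = None
    formulary: Sequence[str] = DEFAULT_FORMULARY
    age_range: tuple[float, float] = (18.0, 70.0)
    allow_manual_flags: bool = True
    max_retries: int = 5
    today: date = _TODAY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise GenerationError("n_patients must be positive")
        if self.exact_planted is not None and len(self.exact_planted) != self.n_patients:
            raise GenerationError("exact_planted must list one set per patient")
        probs = (self.planting_probability.values()
                 if isinstance(self.planting_probability, Mapping)
                 else [self.planting_probability])
        if any(not 0 <= p <= 1 for p in probs):
            raise GenerationError("planting probabilities must be in [0, 1]")


def _age_is_safe(age: float, predicates: list[dict]) -> bool:
    from .triage import evaluate_predicate
    probe = PatientRecord(patient_id="probe", age=age)
    return all(evaluate_predicate(probe, p) is None for p in predicates)


def _plant(record: dict, spec_: dict, rng: np.random.Generator,
           today: date) -> None:
    """Mutate a draft record so the predicate is satisfied."""
    ptype = spec_["type"]
    meds: list[Medication] = record["medications"]
    if ptype == "medication_name_in":
        meds.append(Medication(name=spec_["names"][0], med_class="planted",
                               regular=True))
    elif ptype == "medication_class_in":
        cls = spec_["classes"][0]
        meds.append(Medication(name=f"{cls}_agent", med_class=cls, regular=True))
    elif ptype == "regular_med_count_ge":
        classes = spec_.get("classes", [])
        cls = classes[0] if classes else "benign"
        have = sum(1 for m in meds if m.regular
                   and (not classes or m.med_class == cls))
        for k in range(int(spec_["min_count"]) - have):
            meds.append(Medication(name=f"{cls}_{k + 1}", med_class=cls,
                                   regular=True))
    elif ptype == "missed_dose_of":
        target = (spec_.get("names") or [None])[0]
        cls = (spec_.get("classes") or ["benign"])[0]
        name = target or f"{cls}_missed"
        meds.append(Medication(name=name, med_class=cls, regular=True,
                               missed_doses=int(spec_.get("min_missed", 1))))
    elif ptype == "lab_compare":
        op = spec_["op"]
        if op == "between":
            value = (float(spec_["low"]) + float(spec_["high"])) / 2.0
        elif op in ("lt", "le"):
            value = float(spec_["value"]) - max(1.0, abs(spec_["value"]) * 0.2)
        else:
            value = float(spec_["value"]) + max(1.0, abs(spec_["value"]) * 0.2)
        record["labs"].append(LabResult(name=spec_["lab"], value=value,
                                        units=spec_["units"], date=today))
    elif ptype == "age_compare":
        years = float(spec_["years"])
        if spec_["op"] in ("gt", "ge"):
            record["age"] = years + 1 + float(rng.integers(0, 5))
        else:
            record["age"] = max(1.0, years - 1 - float(rng.integers(0, 5)))
    elif ptype == "flag_present":
        record["flags"][spec_["flag"]] = True
    elif ptype == "days_since_event_ge":
        record[spec_["event"]] = today - timedelta(days=int(spec_["days"]))
    else:  # pragma: no cover - manual handled by the flag channel
        raise GenerationError(f"cannot plant predicate type {ptype!r}")


def _select_planted(spec: CohortSpec, active: list[RiskIndicator],
                    idx: int, rng: np.random.Generator) -> list[str]:
    if spec.exact_planted is not None:
        return list(spec.exact_planted[idx])
    chosen = []
    age_taken = False
    labs_taken: set = set()
    for ind in active:
        p = (spec.planting_probability.get(ind.id, 0.0)
             if isinstance(spec.planting_probability, Mapping)
             else spec.planting_probability)
        if p and rng.random() < p:
            pred = ind.predicate or {}
            if pred.get("type") == "age_compare":
                if age_taken:     # a patient has one age; plant at most one
                    continue
                age_taken = True
            if pred.get("type") == "lab_compare":
                if pred["lab"] in labs_taken:  # one value per lab per patient
                    continue
                labs_taken.add(pred["lab"])
            chosen.append(ind.id)
    return chosen


def generate_cohort(spec: CohortSpec, catalog: IndicatorCatalog
                    ) -> tuple[list[PatientRecord], dict[str, list[str]],
                               dict[str, list[str]]]:
    """Generate patients with planted indicator matches.

    Returns ``(records, ground_truth, manual_flags)`` where
    ``ground_truth[pid]`` lists exactly the indicator ids the record
    matches and ``manual_flags[pid]`` the manual indicators to raise
    when triaging. Accidental matches are avoided by rejection sampling
    (``max_retries`` rebuilds); if a rebuild cannot avoid one — e.g. a
    planted indicator structurally implies another — the accidental
    match is added to the ground truth rather than dropped silently.
    """
    active = catalog.active()
    by_id = {i.id: i for i in active}
    age_preds = [i.predicate for i in active
                 if i.predicate and i.predicate["type"] == "age_compare"]
    safe_formulary = [n for n in spec.formulary
                      if not _name_in_catalog(n, active)]

    records: list[PatientRecord] = []
    ground_truth: dict[str, list[str]] = {}
    manual_out: dict[str, list[str]] = {}

    for idx in range(spec.n_patients):
        rng = _rng(spec.seed, 1, idx)
        pid = f"pt{idx + 1:04d}"
        planted = _select_planted(spec, active, idx, rng)
        unknown = [x for x in planted if x not in by_id]
        if unknown:
            raise GenerationError(f"planted ids not in active catalog: {unknown}")
        manual_planted = [x for x in planted if by_id[x].is_manual]
        if manual_planted and not spec.allow_manual_flags:
            raise GenerationError(
                f"cannot plant manual indicators {manual_planted} with the "
                "manual-flag channel disabled")
        auto_planted = [x for x in planted if not by_id[x].is_manual]

        final_record = None
        truth: list[str] = []
        for attempt in range(spec.max_retries + 1):
            record = _draft_record(pid, spec, rng, age_preds, safe_formulary)
            for ind_id in auto_planted:
                _plant(record, by_id[ind_id].predicate, rng, spec.today)
            candidate = PatientRecord(**record)
            matches = match_indicators(candidate, catalog,
                                       manual_flags=manual_planted,
                                       today=spec.today)
            matched_ids = [m.indicator_id for m in matches]
            unmatched = set(planted) - set(matched_ids)
            if unmatched:
                raise GenerationError(
                    f"patient {pid}: planted indicators {sorted(unmatched)} "
                    "not satisfiable by construction")
            extras = set(matched_ids) - set(planted)
            final_record = candidate
            truth = sorted(set(planted) | extras, key=lambda x: (len(x), x))
            if not extras or attempt == spec.max_retries:
                if not extras:
                    truth = sorted(set(planted), key=lambda x: (len(x), x))
                break
        records.append(final_record)
        ground_truth[pid] = truth
        manual_out[pid] = sorted(manual_planted)
    return records, ground_truth, manual_out


def _name_in_catalog(name: str, active: list[RiskIndicator]) -> bool:
    low = name.lower()
    for ind in active:
        p = ind.predicate or {}
        if low in [n.lower() for n in p.get("names", [])]:
            return True
    return False


def _draft_record(pid: str, spec: CohortSpec, rng: np.random.Generator,
                  age_preds: list[dict], formulary: list[str]) -> dict:
    lo, hi = spec.age_range
    for _ in range(100):
        age = float(np.round(rng.uniform(lo, hi), 1))
        if _age_is_safe(age, age_preds):
            break
    else:
        raise GenerationError("could not draw an age outside all age predicates")
    n_benign = int(rng.integers(0, min(4, len(formulary) + 1)))
    names = rng.choice(len(formulary), size=n_benign, replace=False) \
        if n_benign else []
    meds = [Medication(name=formulary[i], med_class="benign", regular=True)
            for i in names]
    return {
        "patient_id": pid,
        "age": age,
        "ward": "acute",
        "admitted": spec.today - timedelta(days=int(rng.integers(1, 30))),
        "medications": meds,
        "labs": [],
        "flags": {},
        "last_review": spec.today - timedelta(days=int(rng.integers(0, 7))),
    }
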