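"""Machine-readable registry of drug-related-problem risk indicators.

A catalog entry records one risk indicator (a patient, drug or
organisational characteristic associated with drug-related problems),
its editorial status and its traffic-light risk tier. The catalog
supports the editorial operations used while assembling a prioritization
tool: taking the union of indicator lists from different sources,
merging near-duplicate indicators into a representative, and excluding
indicators.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class Tier(str, Enum):
    """Traffic-light risk tier: red = high, amber = medium, green = low."""

    RED = "red"
    AMBER = "amber"
    GREEN = "green"
    UNASSIGNED = "unassigned"

    @property
    def severity(self) -> int:
        return {"green": 0, "amber": 1, "red": 2, "unassigned": -1}[self.value]


class Group(str, Enum):
    HIGH_RISK_MEDICINE = "high_risk_medicine"
    PATIENT_RELATED = "patient_related"
    DRUG_RELATED = "drug_related"
    HOSPITAL_RELATED = "hospital_related"


class Source(str, Enum):
    SYSTEMATIC_REVIEW = "systematic_review"
    PRACTICE_SURVEY = "practice_survey"
    PANEL_ROUND2_ADDITION = "panel_round2_addition"
    STAKEHOLDER = "stakeholder"


STATUS_ACTIVE = "active"
STATUS_MODIFIED = "modified"
STATUS_EXCLUDED = "excluded"
_MERGED_PREFIX = "merged_into:"

#: statuses under which an indicator still counts toward the live tool
_LIVE = frozenset({STATUS_ACTIVE, STATUS_MODIFIED})


class CatalogError(ValueError):
    """Invalid catalog content (schema violation, duplicate id, bad reference)."""


@dataclass(frozen=True)
class RiskIndicator:
    """One catalog entry.

    ``status`` is one of ``active``, ``modified``, ``excluded`` or
    ``merged_into:<id>``; only active/modified indicators carry a tier
    other than ``unassigned`` and take part in matching.
    """

    id: str
    text: str
    group: Group
    sources: tuple[Source, ...]
    status: str = STATUS_ACTIVE
    tier: Tier = Tier.UNASSIGNED
    predicate: dict | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.id or not str(self.id).strip():
            raise CatalogError("indicator id must be non-empty")
        if not self.sources:
            raise CatalogError(f"indicator {self.id!r}: at least one source required")
        if not (self.status in (STATUS_ACTIVE, STATUS_MODIFIED, STATUS_EXCLUDED)
                or self.status.startswith(_MERGED_PREFIX)):
            raise CatalogError(f"indicator {self.id!r}: unknown status {self.status!r}")
        if self.tier is not Tier.UNASSIGNED and not self.is_active:
            raise CatalogError(
                f"indicator {self.id!r}: tier {self.tier.value!r} on non-active entry")

    @property
    def is_active(self) -> bool:
        return self.status in _LIVE

    @property
    def merged_target(self) -> str | None:
        if self.status.startswith(_MERGED_PREFIX):
            return self.status[len(_MERGED_PREFIX):]
        return None

    @property
    def is_manual(self) -> bool:
        """True when matching requires explicit clinical judgement (a flag)."""
        return bool(self.predicate) and self.predicate.get("type") == "manual"


def slugify(text: str) -> str:
    """Default id for an indicator: lower-cased words joined by underscores."""
    out = "".join(c if c.isalnum() else " " for c in text.lower())
    return "_".join(out.split())[:60]


_CSV_COLUMNS = ["id", "text", "group", "sources", "status", "tier", "predicate", "notes"]


@dataclass
class IndicatorCatalog:
    """An ordered, id-unique collection of :class:`RiskIndicator`."""

    version: str = "0"
    created: date = field(default_factory=date.today)
    indicators: list[RiskIndicator] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ind in self.indicators:
            if ind.id in seen:
                raise CatalogError(f"duplicate indicator id {ind.id!r}")
            seen.add(ind.id)
        for ind in self.indicators:
            target = ind.merged_target
            if target is not None:
                tgt = self.get(target)
                if tgt is None or not tgt.is_active:
                    raise CatalogError(
                        f"indicator {ind.id!r} merged into missing/non-active {target!r}")

    # -- access -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.indicators)

    def __iter__(self):
        return iter(self.indicators)

    def get(self, id: str) -> RiskIndicator | None:
        for ind in self.indicators:
            if ind.id == id:
                return ind
        return None

    def active(self) -> list[RiskIndicator]:
        return [i for i in self.indicators if i.is_active]

    @property
    def n_active(self) -> int:
        return len(self.active())

    def status_counts(self) -> dict[str, int]:
        out = {"active": 0, "merged": 0, "excluded": 0}
        for ind in self.indicators:
            if ind.is_active:
                out["active"] += 1
            elif ind.merged_target is not None:
                out["merged"] += 1
            else:
                out["excluded"] += 1
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "created": self.created.isoformat(),
            "indicators": [
                {
                    "id": i.id,
                    "text": i.text,
                    "group": i.group.value,
                    "sources": [s.value for s in i.sources],
                    "status": i.status,
                    "tier": i.tier.value,
                    "predicate": i.predicate,
                    "notes": i.notes,
                }
                for i in self.indicators
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "IndicatorCatalog":
        try:
            raw = payload["indicators"]
        except KeyError as exc:
            raise CatalogError("catalog payload missing 'indicators'") from exc
        inds = []
        for row, entry in enumerate(raw, start=1):
            try:
                inds.append(RiskIndicator(
                    id=str(entry["id"]),
                    text=str(entry["text"]),
                    group=Group(entry["group"]),
                    sources=tuple(Source(s) for s in entry["sources"]),
                    status=str(entry.get("status", STATUS_ACTIVE)),
                    tier=Tier(entry.get("tier", "unassigned")),
                    predicate=entry.get("predicate"),
                    notes=str(entry.get("notes", "")),
                ))
            except (KeyError, ValueError) as exc:
                if isinstance(exc, CatalogError):
                    raise
                raise CatalogError(f"indicator row {row}: {exc}") from exc
        return cls(
            version=str(payload.get("version", "0")),
            created=date.fromisoformat(payload["created"]) if "created" in payload
            else date.today(),
            indicators=inds,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, ensure_ascii=False) + "\n"

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.DictWriter(buf, fieldnames=_CSV_COLUMNS, lineterminator="\n")
        w.writeheader()
        for i in self.indicators:
            w.writerow({
                "id": i.id,
                "text": i.text,
                "group": i.group.value,
                "sources": "|".join(s.value for s in i.sources),
                "status": i.status,
                "tier": i.tier.value,
                "predicate": json.dumps(i.predicate, ensure_ascii=False)
                if i.predicate is not None else "",
                "notes": i.notes,
            })
        return buf.getvalue()


def load_catalog(path: str | Path, format: str | None = None) -> IndicatorCatalog:
    """Read a catalog from ``path`` (JSON or CSV, inferred from the suffix)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    text = path.read_text(encoding="utf-8")
    if fmt == "json":
        return IndicatorCatalog.from_dict(json.loads(text))
    if fmt == "csv":
        reader = csv.DictReader(io.StringIO(text))
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise CatalogError(f"catalog CSV missing columns: {sorted(missing)}")
        payload = {"version": "0", "indicators": []}
        for row in reader:
            payload["indicators"].append({
                "id": row["id"],
                "text": row["text"],
                "group": row["group"],
                "sources": row["sources"].split("|"),
                "status": row["status"],
                "tier": row["tier"],
                "predicate": json.loads(row["predicate"]) if row["predicate"] else None,
                "notes": row["notes"],
            })
        return IndicatorCatalog.from_dict(payload)
    raise CatalogError(f"unknown catalog format {fmt!r}")


def save_catalog(catalog: IndicatorCatalog, path: str | Path,
                 format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        path.write_text(catalog.to_json(), encoding="utf-8")
    elif fmt == "csv":
        path.write_text(catalog.to_csv(), encoding="utf-8")
    else:
        raise CatalogError(f"unknown catalog format {fmt!r}")
    return path


def union_sources(a: Iterable[RiskIndicator], b: Iterable[RiskIndicator],
                  version: str = "union") -> IndicatorCatalog:
    """Union two indicator lists, matching entries by id.

    Indicators present in both lists appear once, carrying the source
    annotations of both; the active count is ``|a| + |b| - |shared|``.
    """
    merged: dict[str, RiskIndicator] = {}
    for ind in a:
        if ind.id in merged:
            raise CatalogError(f"duplicate indicator id {ind.id!r} within first list")
    for ind in a:
        merged[ind.id] = ind
    seen_b: set[str] = set()
    for ind in b:
        if ind.id in seen_b:
            raise CatalogError(f"duplicate indicator id {ind.id!r} within second list")
        seen_b.add(ind.id)
        if ind.id in merged:
            prior = merged[ind.id]
            extra = tuple(s for s in ind.sources if s not in prior.sources)
            merged[ind.id] = replace(prior, sources=prior.sources + extra)
        else:
            merged[ind.id] = ind
    return IndicatorCatalog(version=version, indicators=list(merged.values()))


@dataclass(frozen=True)
class MergeGroup:
    """One merge: the listed ids are absorbed into ``representative``."""

    representative: str
    absorbed: tuple[str, ...]
    note: str = ""


def apply_merge_plan(catalog: IndicatorCatalog,
                     plan: Sequence[MergeGroup],
                     exclusions: Sequence[str] = (),
                     exclusion_note: str = "") -> IndicatorCatalog:
    """Apply editorial merges and exclusions, returning a new catalog.

    Each absorbed indicator gets status ``merged_into:<representative>``
    and drops its tier; each excluded id gets status ``excluded``. The
    active count therefore decreases by (absorbed + excluded).
    """
    new: dict[str, RiskIndicator] = {i.id: i for i in catalog.indicators}

    def _require_active(id: str, role: str) -> RiskIndicator:
        ind = new.get(id)
        if ind is None:
            raise CatalogError(f"merge plan references unknown id {id!r} ({role})")
        if not ind.is_active:
            raise CatalogError(
                f"merge plan references non-active id {id!r} ({role}, status {ind.status!r})")
        return ind

    for group in plan:
        rep = _require_active(group.representative, "representative")
        if group.representative in group.absorbed:
            raise CatalogError(
                f"representative {rep.id!r} cannot absorb itself")
        for aid in group.absorbed:
            ind = _require_active(aid, "absorbed")
            note = f"merged into {rep.id}"
            if group.note:
                note += f" ({group.note})"
            new[aid] = replace(
                ind, status=_MERGED_PREFIX + rep.id, tier=Tier.UNASSIGNED,
                notes=(ind.notes + "; " if ind.notes else "") + note)
    for eid in exclusions:
        ind = _require_active(eid, "exclusion")
        note = "excluded" + (f" ({exclusion_note})" if exclusion_note else "")
        new[eid] = replace(
            ind, status=STATUS_EXCLUDED, tier=Tier.UNASSIGNED,
            notes=(ind.notes + "; " if ind.notes else "") + note)
    return IndicatorCatalog(version=catalog.version, created=catalog.created,
                            indicators=list(new.values()))
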