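"""Modified-Delphi consensus engine.

A Delphi round collects 7-point Likert ratings from an expert panel,
with an explicit "outside my expertise" opt-out. This module turns raw
ratings into per-item band summaries (median plus the percentage of
valid ratings falling in score bands), applies the study's percent-
agreement consensus rules, and aggregates ranking questions.

The consensus rules are:

* **inclusion** — an indicator enters the tool if >=75% of valid ratings
  are 6-7 (important/very important) or >=85% are 5-7;
* **risk tier** — red if >=75% rate 6-7, amber if >=75% rate 3-5, green
  if >=75% rate 1-2, with an optional stakeholder fallback to amber when
  no band reaches 75% but a majority rated 3-7;
* **agreement** — a statement is agreed if >=75% rate 6-7 or >=85% rate
  5-7.

All thresholds are inclusive (>=) and configurable via
:class:`ConsensusRule`. "Outside my expertise" and missing responses are
excluded from every denominator.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import Tier

#: sentinel for an explicit "outside my expertise" response
OUTSIDE_EXPERTISE = "OE"

LIKERT_MIN, LIKERT_MAX = 1, 7


class Dimension(str, Enum):
    IMPORTANCE = "importance"
    RISK = "risk"
    AGREEMENT = "agreement"


class ConsensusError(ValueError):
    """Invalid input to a consensus operation."""


def parse_response(raw) -> int | str | None:
    """Parse a raw response cell into an int 1-7, OUTSIDE_EXPERTISE or None."""
    if raw is None:
        return None
    if isinstance(raw, str):
        raw = raw.strip()
        if raw == "" or raw.lower() in ("na", "nan"):
            return None
        if raw.upper() == OUTSIDE_EXPERTISE:
            return OUTSIDE_EXPERTISE
    if isinstance(raw, float) and raw != raw:  # NaN
        return None
    value = int(raw)
    if not LIKERT_MIN <= value <= LIKERT_MAX:
        raise ConsensusError(f"Likert response out of range: {raw!r}")
    return value


@dataclass
class RatingMatrix:
    """Ratings for one study round, keyed (panellist, item, dimension).

    ``entries`` values are ints 1-7, :data:`OUTSIDE_EXPERTISE`, or None
    for an explicit missing response; absent keys are also missing.
    """

    study: str
    round: int
    entries: dict[tuple[str, str, Dimension], int | str | None] = field(
        default_factory=dict)

    def add(self, panellist: str, item: str, dimension: Dimension | str,
            response) -> None:
        dim = Dimension(dimension)
        key = (str(panellist), str(item), dim)
        if key in self.entries:
            raise ConsensusError(
                f"duplicate rating for panellist={panellist!r} item={item!r} "
                f"dimension={dim.value}")
        self.entries[key] = parse_response(response)

    @property
    def panellists(self) -> list[str]:
        return sorted({k[0] for k in self.entries})

    @property
    def items(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, item, _ in self.entries:
            seen.setdefault(item, None)
        return list(seen)

    def responses(self, item: str, dimension: Dimension | str) -> list:
        dim = Dimension(dimension)
        return [v for (p, i, d), v in self.entries.items()
                if i == item and d is dim]

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {"study": self.study, "round": self.round, "panellist": p,
             "item": i, "dimension": d.value,
             "response": "" if v is None else str(v)}
            for (p, i, d), v in self.entries.items()
        ]
        return pd.DataFrame(
            rows, columns=["study", "round", "panellist", "item",
                           "dimension", "response"])


def read_ratings_csv(path: str | Path) -> dict[tuple[str, int], RatingMatrix]:
    """Read long-format ratings and split them into per-round matrices."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"study", "round", "panellist", "item", "dimension", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ConsensusError(f"ratings CSV missing columns: {sorted(missing)}")
    out: dict[tuple[str, int], RatingMatrix] = {}
    for rec in df.itertuples(index=False):
        key = (rec.study, int(rec.round))
        matrix = out.setdefault(key, RatingMatrix(study=rec.study, round=key[1]))
        matrix.add(rec.panellist, rec.item, rec.dimension, rec.response)
    return out


def write_ratings_csv(matrices: Iterable[RatingMatrix], path: str | Path) -> Path:
    frames = [m.to_long_frame() for m in matrices]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["study", "round", "panellist", "item", "dimension", "response"])
    path = Path(path)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# band summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandSummary:
    """Per item x dimension x round descriptive summary.

    Percentages are of ``n_valid`` (ratings 1-7 only). Summaries built
    from raw ratings carry exact counts; summaries transcribed from a
    published table carry only the printed one-decimal percentages, with
    the unprinted fields None.
    """

    item: str
    dimension: Dimension
    round: int
    n_valid: int | None = None
    median: float | None = None
    counts: tuple[int, ...] | None = None  # ratings 1..7
    pct_1_2: float | None = None
    pct_3_5: float | None = None
    pct_5_7: float | None = None
    pct_6_7: float | None = None

    def __post_init__(self) -> None:
        if self.counts is not None:
            if len(self.counts) != 7 or any(c < 0 for c in self.counts):
                raise ConsensusError("counts must be 7 non-negative integers")
            if self.n_valid is not None and sum(self.counts) != self.n_valid:
                raise ConsensusError("counts do not sum to n_valid")
        present = [self.pct_1_2, self.pct_3_5, self.pct_6_7]
        if all(p is not None for p in present):
            total = sum(present)
            # printed one-decimal values may drift by rounding
            if abs(total - 100.0) > 0.15:
                raise ConsensusError(
                    f"{self.item!r}: band percentages sum to {total:.2f}, not 100")
        if (self.pct_5_7 is not None and self.pct_6_7 is not None
                and self.pct_5_7 < self.pct_6_7 - 1e-9):
            raise ConsensusError(f"{self.item!r}: pct_5_7 < pct_6_7")

    @classmethod
    def from_counts(cls, item: str, dimension: Dimension | str, round: int,
                    counts: Sequence[int]) -> "BandSummary":
        counts = tuple(int(c) for c in counts)
        n = sum(counts)
        if n == 0:
            raise ConsensusError(
                f"item {item!r}: no valid responses, summary undefined")
        values: list[int] = []
        for score, c in zip(range(1, 8), counts):
            values.extend([score] * c)
        pct = lambda lo, hi: 100.0 * sum(counts[lo - 1:hi]) / n
        return cls(
            item=str(item), dimension=Dimension(dimension), round=int(round),
            n_valid=n, median=float(statistics.median(values)), counts=counts,
            pct_1_2=pct(1, 2), pct_3_5=pct(3, 5), pct_5_7=pct(5, 7),
            pct_6_7=pct(6, 7))


def summarize(matrix: RatingMatrix, item: str,
              dimension: Dimension | str) -> BandSummary:
    """Summarise one item's ratings on one dimension.

    Outside-expertise and missing responses are excluded from the
    denominator; the median uses the midpoint convention for even n.
    Raises :class:`ConsensusError` when no valid response exists.
    """
    dim = Dimension(dimension)
    if item not in matrix.items:
        raise ConsensusError(f"item {item!r} not present in matrix")
    counts = [0] * 7
    for v in matrix.responses(item, dim):
        if isinstance(v, int):
            counts[v - 1] += 1
    return BandSummary.from_counts(item, dim, matrix.round, counts)


# ---------------------------------------------------------------------------
# consensus rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusRule:
    """Percent-agreement thresholds (inclusive) for the three decisions."""

    include_t67: float = 75.0
    include_t57: float = 85.0
    tier_band_t: float = 75.0
    majority_fallback: bool = True
    agree_t67: float = 75.0
    agree_t57: float = 85.0

    def __post_init__(self) -> None:
        for name in ("include_t67", "include_t57", "tier_band_t",
                     "agree_t67", "agree_t57"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ConsensusError(f"{name} must be in (0, 100], got {v}")


DEFAULT_RULE = ConsensusRule()


def _require(summary: BandSummary, dim: Dimension, op: str) -> None:
    if summary.dimension is not dim:
        raise ConsensusError(
            f"{op} requires a {dim.value} summary, got {summary.dimension.value}")


def include_indicator(summary: BandSummary,
                      rule: ConsensusRule = DEFAULT_RULE) -> bool:
    """Inclusion rule: >=75% rated 6-7 or >=85% rated 5-7 (importance)."""
    _require(summary, Dimension.IMPORTANCE, "include_indicator")
    if summary.pct_6_7 is None or summary.pct_5_7 is None:
        raise ConsensusError(f"{summary.item!r}: missing 6-7 or 5-7 percentage")
    return (summary.pct_6_7 >= rule.include_t67
            or summary.pct_5_7 >= rule.include_t57)


def assign_tier(summary: BandSummary,
                rule: ConsensusRule = DEFAULT_RULE) -> Tier:
    """Risk-tier rule on a risk summary; bands 6-7 / 3-5 / 1-2 at 75%.

    When no band reaches the threshold and ``majority_fallback`` is set,
    an item whose 3-7 mass exceeds 50% is deemed amber (the stakeholder
    fallback for "majority rated medium or high risk").
    """
    _require(summary, Dimension.RISK, "assign_tier")
    t = rule.tier_band_t
    p12 = summary.pct_1_2
    if p12 is None and summary.pct_3_5 is not None and summary.pct_6_7 is not None:
        p12 = max(0.0, 100.0 - summary.pct_3_5 - summary.pct_6_7)
    if summary.pct_6_7 is not None and summary.pct_6_7 >= t:
        return Tier.RED
    if summary.pct_3_5 is not None and summary.pct_3_5 >= t:
        return Tier.AMBER
    if p12 is not None and p12 >= t:
        return Tier.GREEN
    if (rule.majority_fallback and summary.pct_3_5 is not None
            and summary.pct_6_7 is not None
            and summary.pct_3_5 + summary.pct_6_7 > 50.0):
        return Tier.AMBER
    return Tier.UNASSIGNED


def statement_agreed(summary: BandSummary,
                     rule: ConsensusRule = DEFAULT_RULE) -> bool:
    """Agreement rule: >=75% rated 6-7 or >=85% rated 5-7 (agreement)."""
    _require(summary, Dimension.AGREEMENT, "statement_agreed")
    if summary.pct_6_7 is None or summary.pct_5_7 is None:
        raise ConsensusError(f"{summary.item!r}: missing 6-7 or 5-7 percentage")
    return (summary.pct_6_7 >= rule.agree_t67
            or summary.pct_5_7 >= rule.agree_t57)


# ---------------------------------------------------------------------------
# round reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ItemDecision:
    item: str
    summary: BandSummary
    included: bool
    tier: Tier | None = None


@dataclass(frozen=True)
class ConsensusReport:
    study: str
    round: int
    decision: str  # "inclusion" | "agreement"
    decisions: tuple[ItemDecision, ...]

    @property
    def n_items(self) -> int:
        return len(self.decisions)

    @property
    def n_included(self) -> int:
        return sum(d.included for d in self.decisions)

    @property
    def proportion_included(self) -> float:
        return self.n_included / self.n_items

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.decisions:
            s = d.summary
            rows.append({
                "item": d.item, "round": s.round, "dimension": s.dimension.value,
                "n_valid": s.n_valid, "median": s.median,
                "pct_1_2": s.pct_1_2, "pct_3_5": s.pct_3_5,
                "pct_5_7": s.pct_5_7, "pct_6_7": s.pct_6_7,
                "included": d.included,
                "tier": d.tier.value if d.tier is not None else "",
            })
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "study": self.study, "round": self.round, "decision": self.decision,
            "n_items": self.n_items, "n_included": self.n_included,
            "proportion_included": self.proportion_included,
            "items": self.to_frame().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, default=str) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def run_round(summaries: Iterable[BandSummary],
              rule: ConsensusRule = DEFAULT_RULE,
              decision: str = "inclusion",
              risk_summaries: Mapping[str, BandSummary] | None = None,
              study: str = "", round: int | None = None) -> ConsensusReport:
    """Apply a consensus decision to every summary of a round.

    ``decision`` is ``"inclusion"`` (importance summaries, optionally
    paired with ``risk_summaries`` to attach a tier to included items)
    or ``"agreement"`` (agreement summaries). Items without a summary
    for the round — e.g. indicators added in round 2 — are simply not
    passed in, and so never inflate a denominator.
    """
    summaries = list(summaries)
    if decision == "inclusion":
        want = Dimension.IMPORTANCE
        judge = lambda s: include_indicator(s, rule)
    elif decision == "agreement":
        want = Dimension.AGREEMENT
        judge = lambda s: statement_agreed(s, rule)
    else:
        raise ConsensusError(f"unknown decision type {decision!r}")
    dims = {s.dimension for s in summaries}
    if dims - {want}:
        raise ConsensusError(
            f"{decision} round got mixed dimensions: {sorted(d.value for d in dims)}")
    decisions = []
    for s in summaries:
        included = judge(s)
        tier = None
        if decision == "inclusion" and included and risk_summaries is not None:
            rs = risk_summaries.get(s.item)
            tier = assign_tier(rs, rule) if rs is not None else Tier.UNASSIGNED
        decisions.append(ItemDecision(item=s.item, summary=s,
                                      included=included, tier=tier))
    rnd = round if round is not None else (summaries[0].round if summaries else 0)
    return ConsensusReport(study=study, round=rnd, decision=decision,
                           decisions=tuple(decisions))


# ---------------------------------------------------------------------------
# ranking questions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankingTally:
    """Counts of rank positions per option for a forced-ranking question.

    ``counts[option]`` is the number of rankers placing the option at
    rank 1, 2, ... (most to least preferred).
    """

    counts: Mapping[str, tuple[int, ...]]
    n_rankers: int | None = None
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.counts.values()}
        if len(lengths) > 1:
            raise ConsensusError("all options must tally the same number of ranks")
        if self.n_rankers is not None:
            for pos in range(next(iter(lengths), 0)):
                col = sum(v[pos] for v in self.counts.values())
                if col > self.n_rankers:
                    raise ConsensusError(
                        f"rank column {pos + 1} sums to {col} > n_rankers")

    @property
    def options(self) -> list[str]:
        return list(self.counts)


def winner_by_first_choice(tally: RankingTally) -> tuple[str, int]:
    """Plurality winner on rank-1 votes, with a cascading tie-break.

    Ties on first choices are broken by rank-2 counts, then rank-3 and
    so on; a residual tie falls back to lexicographic option id, making
    the result total and deterministic.
    """
    if not tally.counts:
        raise ConsensusError("empty ranking tally")
    def key(opt: str):
        return tuple(-c for c in tally.counts[opt]) + (opt,)
    winner = min(tally.options, key=key)
    return winner, tally.counts[winner][0]
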