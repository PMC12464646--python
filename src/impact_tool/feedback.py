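"""Controlled feedback documents for the second Delphi round.

Between rounds each panellist receives, for every item: their own
round-1 rating, the group median, the full 1-7 score breakdown, an
optional narrative summary of free-text comments (authored by the
research team, never generated here), and an annotation when the item
is new or reworded. Only the recipient's own ratings appear — other
panellists stay anonymous.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import Mapping, Sequence

from .consensus import (BandSummary, ConsensusError, Dimension,
                        OUTSIDE_EXPERTISE, RatingMatrix)

NEW_INDICATOR_ANNOTATION = "*Newly added indicator"
MODIFIED_PREFIX = "Modified from: "

NOT_RATED = "not rated"


class FeedbackError(ValueError):
    pass


@dataclass(frozen=True)
class FeedbackBlock:
    item: str
    text: str
    own_response: str          # "1".."7", "outside my expertise", or "not rated"
    median: float | None       # None for newly added items (no prior round)
    breakdown: tuple[int, ...]  # counts for scores 1..7
    narrative: str = ""
    annotation: str = ""       # "", NEW_INDICATOR_ANNOTATION, or "Modified from: ..."

    def __post_init__(self) -> None:
        if len(self.breakdown) != 7:
            raise FeedbackError("breakdown must cover scores 1..7")


@dataclass(frozen=True)
class FeedbackDocument:
    panellist: str
    round: int
    blocks: tuple[FeedbackBlock, ...]
    preamble: str = ""


def _own_response_text(value) -> str:
    if value is None:
        return NOT_RATED
    if value == OUTSIDE_EXPERTISE:
        return "outside my expertise"
    return str(value)


def build_feedback(matrix: RatingMatrix,
                   summaries: Mapping[str, BandSummary],
                   panellist: str,
                   dimension: Dimension | str,
                   item_texts: Mapping[str, str] | None = None,
                   annotations: Mapping[str, str] | None = None,
                   narratives: Mapping[str, str] | None = None,
                   item_order: Sequence[str] | None = None,
                   preamble: str = "") -> FeedbackDocument:
    """Assemble one panellist's feedback document.

    ``summaries`` must cover every previously rated item; newly added
    items (those carrying the new-indicator annotation) have no prior
    round, so they appear with "not rated" and an empty breakdown.
    Ordering follows ``item_order`` (catalog order) when given, else the
    matrix's item order.
    """
    dim = Dimension(dimension)
    if panellist not in matrix.panellists:
        raise FeedbackError(f"panellist {panellist!r} absent from the matrix")
    annotations = annotations or {}
    narratives = narratives or {}
    item_texts = item_texts or {}
    order = list(item_order) if item_order is not None else matrix.items
    missing = [i for i in order if i not in summaries
               and annotations.get(i) != NEW_INDICATOR_ANNOTATION]
    if missing:
        raise FeedbackError(f"summaries missing for items: {missing}")

    blocks = []
    matrix_items = set(matrix.items)
    for item in order:
        s = summaries.get(item)
        if s is not None and s.counts is None:
            raise ConsensusError(
                f"item {item!r}: feedback needs a counts-bearing summary")
        own = (matrix.entries.get((panellist, item, dim))
               if item in matrix_items else None)
        blocks.append(FeedbackBlock(
            item=item,
            text=item_texts.get(item, item),
            own_response=_own_response_text(own),
            median=s.median if s is not None else None,
            breakdown=s.counts if s is not None else (0,) * 7,
            narrative=narratives.get(item, ""),
            annotation=annotations.get(item, ""),
        ))
    return FeedbackDocument(panellist=panellist, round=matrix.round + 1,
                            blocks=tuple(blocks), preamble=preamble)


def render_feedback(doc: FeedbackDocument, format: str = "markdown") -> str:
    """Render a feedback document as diffable text (markdown or CSV)."""
    if format == "markdown":
        return _render_markdown(doc)
    if format == "csv":
        return _render_csv(doc)
    raise FeedbackError(f"unknown feedback format {format!r}")


def _render_markdown(doc: FeedbackDocument) -> str:
    out = [f"# Round {doc.round} feedback — panellist {doc.panellist}", ""]
    if doc.preamble:
        out += [doc.preamble, ""]
    for b in doc.blocks:
        out.append(f"## {b.text}")
        if b.annotation:
            out.append(b.annotation)
        out.append("")
        out.append(f"- Your previous rating: **{b.own_response}**")
        median = f"{b.median:g}" if b.median is not None else "—"
        out.append(f"- Group median: **{median}**")
        out.append("")
        out.append("| Score | 1 | 2 | 3 | 4 | 5 | 6 | 7 |")
        out.append("|---|---|---|---|---|---|---|---|")
        out.append("| Panellists | " + " | ".join(str(c) for c in b.breakdown)
                    + " |")
        if b.narrative:
            out += ["", f"> {b.narrative}"]
        out.append("")
    return "\n".join(out)


def _render_csv(doc: FeedbackDocument) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["item", "your_rating", "median",
                "n1", "n2", "n3", "n4", "n5", "n6", "n7", "annotation"])
    for b in doc.blocks:
        w.writerow([b.item, b.own_response,
                    f"{b.median:g}" if b.median is not None else "",
                    *b.breakdown, b.annotation])
    return buf.getvalue()


def feedback_filename(doc: FeedbackDocument, format: str = "markdown") -> str:
    ext = {"markdown": "md", "csv": "csv"}.get(format)
    if ext is None:
        raise FeedbackError(f"unknown feedback format {format!r}")
    return f"feedback_{doc.panellist}_{doc.round}.{ext}"
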