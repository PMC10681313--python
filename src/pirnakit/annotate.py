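"""Hierarchical genomic annotation of collapsed reads.

Each read is assigned to exactly one category by sequential priority:
categories are consulted in catalog order (piRNA clusters, coding RNA,
non-coding RNA, repeats, introns) and the first one with at least one
alignment wins; reads aligning nowhere are assigned to the "other" sink.
Annotation is strand-agnostic — a hit on either strand assigns the
category; strand is only used by the ping-pong and coverage analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AlignmentHit, SeedIndex
from .catalog import OTHER_CATEGORY
from .errors import DataError
from .preprocess import CollapsedRead


@dataclass
class AnnotatedRead:
    """A collapsed read with its winning category and that category's hits."""

    read: CollapsedRead
    assigned_category: str
    hits: list[AlignmentHit]


def annotate(read, index: SeedIndex, max_mm: int = 1) -> AnnotatedRead:
    """Assign ``read`` to its first-priority aligning category.

    Hits are restricted to the winning category (empty iff "other").
    """
    if isinstance(read, str):
        read = CollapsedRead(read, 1)
    hits = index.align(read.sequence, max_mm)
    if not hits:
        return AnnotatedRead(read, OTHER_CATEGORY, [])
    # hits come back sorted by category priority, so the first is the winner
    winner = hits[0].category_name
    return AnnotatedRead(read, winner, [h for h in hits if h.category_name == winner])


def annotate_library(collapsed, index: SeedIndex, max_mm: int = 1):
    return [annotate(cr, index, max_mm) for cr in collapsed]


def annotation_composition(annotated, categories=None) -> dict[str, float]:
    """Per-category fractions of total read count.

    Weighted by collapsed-read multiplicities; fractions sum to 1. When
    ``categories`` (an ordered list, typically the catalog order) is given,
    every listed category appears in the result, with 0.0 where absent, and
    "other" is always included.
    """
    annotated = list(annotated)
    if not annotated:
        raise DataError("cannot compute composition of an empty read set")
    totals: dict[str, float] = {}
    if categories is not None:
        for cat in list(categories) + [OTHER_CATEGORY]:
            totals[cat] = 0.0
    grand = 0
    for ar in annotated:
        totals[ar.assigned_category] = (
            totals.get(ar.assigned_category, 0.0) + ar.read.count
        )
        grand += ar.read.count
    if grand == 0:
        raise DataError("total read count is zero")
    return {cat: value / grand for cat, value in totals.items()}
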