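"""Classification of reads at an insertion locus: junction-spanning,
insert-internal, and flank, with a summary comparing the edited locus to a
native copy of the same sequence."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .model import GenomicInterval

__all__ = [
    "JunctionReport",
    "classify_read",
    "classify_placements",
    "junction_support_summary",
]

CATEGORIES = ("left_junction", "right_junction", "spanning_both", "internal", "flank")


@dataclass
class JunctionReport:
    left_breakpoint: int
    right_breakpoint: int
    min_overhang: int
    edited_counts: dict[str, int]
    native_counts: Optional[dict[str, int]] = None
    min_support: int = 3

    @property
    def junction_support(self) -> int:
        return (
            self.edited_counts["left_junction"]
            + self.edited_counts["right_junction"]
            + self.edited_counts["spanning_both"]
        )

    @property
    def confirmed(self) -> bool:
        return self.junction_support >= self.min_support


def _classify_span(
    start: int, end: int, insert: GenomicInterval, k: int
) -> str:
    left, right = insert.start, insert.end
    spans_left = start <= left - k and end >= left + k
    spans_right = start <= right - k and end >= right + k
    if spans_left and spans_right:
        return "spanning_both"
    if spans_left:
        return "left_junction"
    if spans_right:
        return "right_junction"
    if start >= left and end <= right:
        return "internal"
    return "flank"


def classify_read(
    chrom: str,
    start: int,
    end: int,
    insert: GenomicInterval,
    min_overhang: int = 5,
) -> str:
    """Category of a single read against the insert's junction breakpoints.

    A junction is "spanned" when the read covers it with at least
    ``min_overhang`` bases on each side; a read covering both junctions is
    ``spanning_both``; reads fully inside the insert are ``internal``;
    everything else (including other chromosomes) is ``flank``.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    if chrom != insert.chrom:
        return "flank"
    return _classify_span(start, end, insert, min_overhang)


def classify_placements(
    placements: pd.DataFrame,
    insert: GenomicInterval,
    min_overhang: int = 5,
    pair_mode: bool = True,
) -> pd.Series:
    """Vector of categories, one per placement row.

    With ``pair_mode`` a read pair supports a junction when either mate
    spans it directly (the mate coordinates, when present, are classified
    too and the more junction-specific category wins).
    """
    rank = {c: i for i, c in enumerate(CATEGORIES)}  # lower = more specific
    cats = []
    for row in placements.itertuples(index=False):
        cat = classify_read(row.chrom, row.start, row.end, insert, min_overhang)
        if pair_mode and row.mate_start is not None and not pd.isna(row.mate_start):
            mate_cat = classify_read(
                row.chrom, int(row.mate_start), int(row.mate_end), insert, min_overhang
            )
            if rank[mate_cat] < rank[cat]:
                cat = mate_cat
        cats.append(cat)
    return pd.Series(cats, index=placements.index, name="category")


def junction_support_summary(
    placements: pd.DataFrame,
    insert: GenomicInterval,
    native_copy: Optional[GenomicInterval] = None,
    min_overhang: int = 5,
    min_support: int = 3,
) -> JunctionReport:
    """Per-category read counts at the edited locus (and the native copy).

    The edited-locus signal is flagged "confirmed" when junction-spanning
    support reaches ``min_support`` reads.
    """
    cats = classify_placements(placements, insert, min_overhang)
    edited = {c: int((cats == c).sum()) for c in CATEGORIES}
    native = None
    if native_copy is not None:
        ncats = classify_placements(placements, native_copy, min_overhang)
        native = {c: int((ncats == c).sum()) for c in CATEGORIES}
    return JunctionReport(
        left_breakpoint=insert.start,
        right_breakpoint=insert.end,
        min_overhang=min_overhang,
        edited_counts=edited,
        native_counts=native,
        min_support=min_support,
    )
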