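"""Personalized and insertion-edited genome construction with exact
coordinate maps, plus in-silico restriction digestion and viewpoint design.
"""

from __future__ import annotations

import bisect
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import GenomeSequence, GenomicInterval, PhasedVariant

__all__ = [
    "EditSpec",
    "CoordinateMap",
    "build_personalized_genomes",
    "build_edited_genome",
    "dpnII_digest",
    "select_viewpoints",
]


@dataclass(frozen=True)
class EditSpec:
    """An insertion/replacement edit: ``insert`` replaces ``target``.

    A zero-length target is a pure insertion at a point.
    """

    insert: str
    target: GenomicInterval
    landing_pad_id: str = "LP"

    def __post_init__(self) -> None:
        if not self.insert:
            raise ValueError("insert sequence must be non-empty")


class CoordinateMap:
    """Piecewise-affine bijection between two genomes outside indel gaps.

    Stored as per-chromosome sorted block triples ``(src_start, src_end,
    dst_start)``; bases inside a block map by offset, bases in no block
    (deleted / inserted sequence) map to ``None``.
    """

    def __init__(self) -> None:
        self._blocks: dict[str, list[tuple[int, int, int]]] = {}

    def add_block(self, chrom: str, src_start: int, src_end: int, dst_start: int) -> None:
        if src_end <= src_start:
            return
        blocks = self._blocks.setdefault(chrom, [])
        if blocks and src_start < blocks[-1][1]:
            raise ValueError("blocks must be added in sorted, non-overlapping order")
        blocks.append((src_start, src_end, dst_start))

    def blocks(self, chrom: str) -> list[tuple[GenomicInterval, GenomicInterval]]:
        out = []
        for s0, s1, d0 in self._blocks.get(chrom, []):
            out.append(
                (GenomicInterval(chrom, s0, s1), GenomicInterval(chrom, d0, d0 + (s1 - s0)))
            )
        return out

    def forward(self, chrom: str, pos: int) -> Optional[int]:
        """Map a source-genome position to the destination genome."""
        blocks = self._blocks.get(chrom)
        if not blocks:
            return None
        i = bisect.bisect_right(blocks, (pos, float("inf"), float("inf"))) - 1
        if i < 0:
            return None
        s0, s1, d0 = blocks[i]
        if s0 <= pos < s1:
            return d0 + (pos - s0)
        return None

    def inverted(self) -> "CoordinateMap":
        inv = CoordinateMap()
        for chrom, blocks in self._blocks.items():
            for s0, s1, d0 in sorted(blocks, key=lambda b: b[2]):
                inv.add_block(chrom, d0, d0 + (s1 - s0), s0)
        return inv

    def backward(self, chrom: str, pos: int) -> Optional[int]:
        return self.inverted().forward(chrom, pos)


def _apply_haplotype(
    reference: GenomeSequence, variants: Sequence[PhasedVariant], hap: int, label: str
) -> tuple[GenomeSequence, CoordinateMap]:
    cmap = CoordinateMap()
    chroms: dict[str, str] = {}
    by_chrom: dict[str, list[PhasedVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom, seq in reference.chroms.items():
        vs = sorted(by_chrom.get(chrom, []), key=lambda v: v.pos)
        prev_end = -1
        pieces: list[str] = []
        ref_cursor = 0
        alt_cursor = 0
        for v in vs:
            if v.pos <= prev_end:
                raise ValueError(f"overlapping variants at {chrom}:{v.pos + 1}")
            ref_span = len(v.ref_allele)
            observed = seq[v.pos : v.pos + ref_span]
            if observed != v.ref_allele:
                raise ValueError(
                    f"ref allele mismatch at {chrom}:{v.pos + 1}: "
                    f"VCF says {v.ref_allele!r}, genome has {observed!r}"
                )
            allele = v.allele(hap)
            same_length = len(allele) == ref_span
            # block covering the gap before this variant; SNV-length alleles
            # stay mappable, indel alleles are excluded from the map
            block_end = v.pos + ref_span if same_length else v.pos
            cmap.add_block(chrom, ref_cursor, block_end, alt_cursor)
            pieces.append(seq[ref_cursor : v.pos])
            pieces.append(allele)
            alt_cursor += (v.pos - ref_cursor) + len(allele)
            ref_cursor = v.pos + ref_span
            prev_end = v.pos + ref_span - 1
        cmap.add_block(chrom, ref_cursor, len(seq), alt_cursor)
        pieces.append(seq[ref_cursor:])
        chroms[chrom] = "".join(pieces)
    return GenomeSequence(chroms, label=label), cmap


def build_personalized_genomes(
    reference: GenomeSequence, variants: Sequence[PhasedVariant]
) -> tuple[GenomeSequence, GenomeSequence, CoordinateMap, CoordinateMap]:
    """Apply phased alleles to the reference, one genome per haplotype.

    Returns ``(hap1, hap2, map_hap1, map_hap2)`` where each map translates
    reference coordinates to that haplotype's coordinates.  Unphased
    heterozygotes are skipped (their haplotype assignment is undefined).
    """
    usable = [v for v in variants if v.phased or not v.is_het]
    hap1, map1 = _apply_haplotype(reference, usable, 0, "hap1")
    hap2, map2 = _apply_haplotype(reference, usable, 1, "hap2")
    return hap1, hap2, map1, map2


def build_edited_genome(
    reference: GenomeSequence, edit: EditSpec
) -> tuple[GenomeSequence, CoordinateMap, tuple[int, int]]:
    """Cut-and-paste ``edit.insert`` over ``edit.target``.

    Returns the edited genome, the reference->edited coordinate map (the
    insert itself is unmappable), and the (left, right) junction breakpoints
    in edited coordinates.
    """
    t = edit.target
    if t.chrom not in reference:
        raise ValueError(f"edit target chromosome {t.chrom!r} not in genome")
    seq = reference[t.chrom]
    if t.end > len(seq):
        raise ValueError(
            f"edit target {t.chrom}:{t.start}-{t.end} exceeds chromosome "
            f"length {len(seq)}"
        )
    edited_seq = seq[: t.start] + edit.insert + seq[t.end :]
    chroms = dict(reference.chroms)
    chroms[t.chrom] = edited_seq
    cmap = CoordinateMap()
    for chrom, s in reference.chroms.items():
        if chrom != t.chrom:
            cmap.add_block(chrom, 0, len(s), 0)
    cmap.add_block(t.chrom, 0, t.start, 0)
    shift = len(edit.insert) - t.length
    cmap.add_block(t.chrom, t.end, len(seq), t.end + shift)
    left = t.start
    right = t.start + len(edit.insert)
    return GenomeSequence(chroms, label="edited"), cmap, (left, right)


def dpnII_digest(
    sequence: str, chrom: str = "seq", site: str = "GATC"
) -> list[GenomicInterval]:
    """Fragment a sequence at every occurrence of the recognition site.

    The cut is placed at the START of each site occurrence (blunt in-silico
    convention), so fragments tile the sequence exactly.
    """
    seq = sequence.upper()
    cuts = sorted({m.start() for m in re.finditer(site, seq)} - {0})
    bounds = [0] + cuts + [len(seq)]
    return [
        GenomicInterval(chrom, a, b)
        for a, b in zip(bounds[:-1], bounds[1:])
        if b > a
    ]


def select_viewpoints(
    fragments: Sequence[GenomicInterval],
    min_len: int,
    max_len: int,
    n: int,
    locus: GenomicInterval,
) -> list[GenomicInterval]:
    """Pick ``n`` size-qualified fragments spread evenly across the locus.

    Qualification is inclusive: ``min_len <= length <= max_len``.  Among the
    qualifying fragments the returned subset minimizes the squared deviation
    of adjacent midpoint gaps from the ideal spacing ``locus.length / n``
    (with boundary terms anchoring the first and last picks to the outermost
    ideal window centers), computed by dynamic programming — a deterministic
    "most evenly spaced" rule.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not fragments:
        raise ValueError("empty fragment list")
    qualifying = sorted(
        (
            f
            for f in fragments
            if min_len <= f.length <= max_len and f.overlaps(locus)
        ),
        key=lambda f: (f.start + f.end),
    )
    if len(qualifying) <= n:
        if len(qualifying) < n:
            warnings.warn(
                f"only {len(qualifying)} qualifying fragments for {n} viewpoints"
            )
        return sorted(qualifying, key=lambda f: f.start)
    centers = [(f.start + f.end) / 2 for f in qualifying]
    m = len(centers)
    t = locus.length / n
    ideal_first = locus.start + t / 2
    ideal_last = locus.start + (n - 0.5) * t
    # dp[j][i]: best cost of picking j fragments with the j-th at index i
    inf = float("inf")
    dp = [[inf] * m for _ in range(n)]
    back: list[list[int]] = [[-1] * m for _ in range(n)]
    for i in range(m):
        dp[0][i] = (centers[i] - ideal_first) ** 2
    for j in range(1, n):
        for i in range(j, m):
            best_cost, best_k = inf, -1
            for k in range(j - 1, i):
                cost = dp[j - 1][k] + (centers[i] - centers[k] - t) ** 2
                if cost < best_cost:
                    best_cost, best_k = cost, k
            dp[j][i] = best_cost
            back[j][i] = best_k
    end = min(
        range(n - 1, m),
        key=lambda i: dp[n - 1][i] + (ideal_last - centers[i]) ** 2,
    )
    picks = [end]
    for j in range(n - 1, 0, -1):
        picks.append(back[j][picks[-1]])
    chosen = [qualifying[i] for i in reversed(picks)]
    return sorted(chosen, key=lambda f: f.start)
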