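"""Core domain types shared across the pipeline.

Coordinate convention: every interval in memory is 0-based, half-open
``[start, end)``.  BED and bedGraph records are native to this convention;
VCF positions and human-readable ``chrom:start-end`` region strings are
1-based inclusive and are converted exactly once, at the parsing boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeSequence",
    "PhasedVariant",
    "CoverageTrack",
    "PWM",
    "ReadPlacement",
    "parse_interval",
    "format_interval",
]

_REGION_RE = re.compile(r"^([\w.]+):([\d,]+)-([\d,]+)$")

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open.

    ``strand`` is ``"+"``, ``"-"`` or ``None`` (unset); ``name`` is an
    optional free-text label.
    """

    chrom: str
    start: int
    end: int
    strand: Optional[str] = field(default=None, compare=False)
    name: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start > self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start <= end"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def with_name(self, name: str) -> "GenomicInterval":
        return replace(self, name=name)


def parse_interval(text: str) -> GenomicInterval:
    """Parse a printed region string like ``"chr11:32,188,452-32,249,902"``.

    Printed coordinates are 1-based inclusive; the result is 0-based
    half-open, so the length of ``chrom:a-b`` is ``b - a + 1``.
    """
    cleaned = text.strip().replace("−", "-").replace(" ", "")
    m = _REGION_RE.match(cleaned)
    if m is None:
        raise ValueError(f"malformed region string: {text!r}")
    chrom = m.group(1)
    start1 = int(m.group(2).replace(",", ""))
    end1 = int(m.group(3).replace(",", ""))
    if start1 < 1:
        raise ValueError(f"region start must be >= 1, got {start1} in {text!r}")
    if start1 > end1:
        raise ValueError(f"region start {start1} > end {end1} in {text!r}")
    return GenomicInterval(chrom, start1 - 1, end1)


def format_interval(iv: GenomicInterval, commas: bool = False) -> str:
    """Inverse of :func:`parse_interval` (emits 1-based inclusive coords)."""
    start1, end1 = iv.start + 1, iv.end
    if commas:
        return f"{iv.chrom}:{start1:,}-{end1:,}"
    return f"{iv.chrom}:{start1}-{end1}"


@dataclass
class GenomeSequence:
    """A labelled set of chromosome sequences over the {A,C,G,T,N} alphabet."""

    chroms: dict[str, str]
    label: str = "reference"

    def __post_init__(self) -> None:
        for name, seq in self.chroms.items():
            if not seq:
                raise ValueError(f"chromosome {name} has empty sequence")
            bad = set(seq.upper()) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name} contains invalid characters: {sorted(bad)}"
                )

    def __getitem__(self, chrom: str) -> str:
        return self.chroms[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def fetch(self, iv: GenomicInterval) -> str:
        return self.chroms[iv.chrom][iv.start : iv.end]


@dataclass(frozen=True)
class PhasedVariant:
    """A biallelic variant with an ordered diploid genotype.

    ``genotype`` holds the allele index (0 = ref, 1 = alt) for (hap1, hap2);
    the order is only meaningful when ``phased`` is true.
    """

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    genotype: tuple[int, int]
    phased: bool = True
    variant_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.ref_allele) < 1 or len(self.alt_allele) < 1:
            raise ValueError("alleles must be non-empty")
        if any(g not in (0, 1) for g in self.genotype):
            raise ValueError(f"genotype entries must be 0 or 1: {self.genotype}")

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    def allele(self, hap: int) -> str:
        """Sequence carried by haplotype ``hap`` (0 or 1)."""
        return self.alt_allele if self.genotype[hap] == 1 else self.ref_allele

    @property
    def key(self) -> str:
        return self.variant_id or f"{self.chrom}:{self.pos + 1}:{self.ref_allele}>{self.alt_allele}"


@dataclass
class CoverageTrack:
    """Binned per-chromosome coverage with explicit normalization state."""

    bin_size: int
    values: dict[str, np.ndarray]
    normalization: str = "raw"  # "raw" | "RPKM"
    total_mapped_reads: int = 0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.normalization not in ("raw", "RPKM"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    def to_rpkm(self) -> "CoverageTrack":
        if self.normalization == "RPKM":
            return self
        if self.total_mapped_reads <= 0:
            raise ValueError("RPKM requires total_mapped_reads > 0")
        scale = 1e9 / (self.bin_size * self.total_mapped_reads)
        return CoverageTrack(
            self.bin_size,
            {c: v * scale for c, v in self.values.items()},
            normalization="RPKM",
            total_mapped_reads=self.total_mapped_reads,
        )

    def to_raw(self) -> "CoverageTrack":
        if self.normalization == "raw":
            return self
        scale = 1e9 / (self.bin_size * self.total_mapped_reads)
        return CoverageTrack(
            self.bin_size,
            {c: v / scale for c, v in self.values.items()},
            normalization="raw",
            total_mapped_reads=self.total_mapped_reads,
        )

    def region_sum(self, iv: GenomicInterval) -> float:
        """Sum of bin values over bins whose start falls inside the interval."""
        v = self.values[iv.chrom]
        b0 = iv.start // self.bin_size
        b1 = -(-iv.end // self.bin_size)
        return float(v[b0:b1].sum())

    def chrom_length_bins(self, chrom: str) -> int:
        return len(self.values[chrom])


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    """Position weight matrix over A/C/G/T with per-column probabilities."""

    motif_id: str
    matrix: np.ndarray  # shape (4, W), columns sum to ~1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A, C, G, T)")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")
        # pseudocount then renormalize, so columns sum to 1 +/- 1e-6
        m = self.matrix + self.pseudocount
        self.matrix = m / m.sum(axis=0, keepdims=True)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """log2(p_base / background_base), shape (4, W)."""
        return np.log2(self.matrix / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class ReadPlacement:
    """A single read (optionally with its mate) placed on a genome."""

    read_id: str
    genome: str
    chrom: str
    start: int
    end: int
    mate_start: Optional[int] = None
    mate_end: Optional[int] = None
    source: str = "target"  # "target" | "spikein"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"read {self.read_id}: start {self.start} must be < end {self.end}"
            )
        if (self.mate_start is None) != (self.mate_end is None):
            raise ValueError(f"read {self.read_id}: mate_start/mate_end must both be set")
        if self.source not in ("target", "spikein"):
            raise ValueError(f"read {self.read_id}: unknown source {self.source!r}")
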