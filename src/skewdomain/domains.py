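"""Region coverage quantification, inside/outside domain ratios, threshold
peak calling, rule-based CRE classification and neutral-region scanning."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import CoverageTrack, GenomicInterval

__all__ = [
    "RegionCoverage",
    "NeutralCriteria",
    "RatioResult",
    "region_coverage",
    "coverage_ratio",
    "call_peaks",
    "classify_cre",
    "scan_neutral_regions",
]

CRE_CLASSES = (
    "promoter",
    "enhancer",
    "CTCF",
    "promoter+CTCF",
    "enhancer+CTCF",
    "unclassified",
)


@dataclass
class RegionCoverage:
    region: GenomicInterval
    sample_id: str
    raw: float
    rpkm: Optional[float] = None

    @property
    def rpkm_per_kb(self) -> Optional[float]:
        if self.rpkm is None:
            return None
        return self.rpkm / (self.region.length / 1000)


@dataclass
class RatioResult:
    inside: GenomicInterval
    outside: GenomicInterval
    per_replicate: list[float]
    undefined: bool = False

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_replicate))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_replicate, ddof=1)) if len(self.per_replicate) > 1 else 0.0


@dataclass
class NeutralCriteria:
    """Inputs for the neutral-but-activatable region scan."""

    compartment_a: Sequence[GenomicInterval]
    exclusion_tracks: dict[str, CoverageTrack]  # mark name -> track
    genes: Sequence[GenomicInterval] = ()
    signal_threshold: float = 0.0  # per-bin value strictly above -> excluded
    merge_distance: int = 1000
    min_length: int = 100_000

    def __post_init__(self) -> None:
        if self.signal_threshold < 0:
            raise ValueError("signal_threshold must be >= 0")
        if self.min_length <= 0:
            raise ValueError("min_length must be > 0")


def _count_overlapping(df: pd.DataFrame, region: GenomicInterval) -> int:
    sub = df[df["chrom"] == region.chrom]
    return int(((sub["start"] < region.end) & (sub["end"] > region.start)).sum())


def region_coverage(
    data: Union[pd.DataFrame, CoverageTrack],
    regions: Sequence[GenomicInterval],
    sample_id: str = "sample",
    total_mapped: Optional[int] = None,
    known_chroms: Optional[set[str]] = None,
) -> list[RegionCoverage]:
    """Raw coverage per region: overlapping-read count (placements) or sum
    of bin values (track).  RPKM is filled when a read total is available."""
    if isinstance(data, CoverageTrack):
        chroms = set(data.values)
        if total_mapped is None and data.total_mapped_reads > 0:
            total_mapped = data.total_mapped_reads
    else:
        chroms = known_chroms if known_chroms is not None else set(data["chrom"].unique())
        if total_mapped is None:
            total_mapped = len(data)
    out = []
    for region in regions:
        if region.chrom not in chroms:
            raise ValueError(f"region on unknown chromosome {region.chrom!r}")
        if isinstance(data, CoverageTrack):
            raw = data.region_sum(region)
        else:
            raw = _count_overlapping(data, region)
        rpkm = None
        if total_mapped and total_mapped > 0:
            rpkm = raw * 1e9 / (region.length * total_mapped)
        out.append(RegionCoverage(region, sample_id, float(raw), rpkm))
    return out


def coverage_ratio(
    replicates: Sequence[Union[pd.DataFrame, CoverageTrack]],
    inside: GenomicInterval,
    outside: GenomicInterval,
) -> RatioResult:
    """Length-normalized inside/outside coverage ratio, one value per
    replicate.  A replicate with zero outside coverage marks the result
    undefined (its value is reported as NaN)."""
    values = []
    undefined = False
    for rep in replicates:
        cov_in = region_coverage(rep, [inside])[0].raw
        cov_out = region_coverage(rep, [outside])[0].raw
        dens_in = cov_in / inside.length
        dens_out = cov_out / outside.length
        if dens_out == 0:
            undefined = True
            values.append(float("nan"))
        else:
            values.append(dens_in / dens_out)
    return RatioResult(inside=inside, outside=outside, per_replicate=values,
                       undefined=undefined)


def call_peaks(
    track: CoverageTrack,
    threshold_multiplier: float = 5.0,
    merge_distance: int = 200,
    min_width: int = 150,
) -> list[GenomicInterval]:
    """Threshold peak caller: bins above m x genome-wide median are merged
    when within ``merge_distance`` bp and filtered at ``min_width`` bp.

    The median is taken over all bins of all chromosomes; if it is 0 the
    threshold falls back to m x mean so fully sparse tracks still work.
    """
    if threshold_multiplier <= 1:
        raise ValueError("threshold multiplier must be > 1")
    allv = np.concatenate([v for v in track.values.values()]) if track.values else np.array([])
    if allv.size == 0 or allv.max() == 0:
        return []
    med = float(np.median(allv))
    base = med if med > 0 else float(allv.mean())
    cutoff = threshold_multiplier * base
    bs = track.bin_size
    peaks: list[GenomicInterval] = []
    for chrom, v in track.values.items():
        above = np.flatnonzero(v > cutoff)
        if above.size == 0:
            continue
        runs: list[list[int]] = [[above[0], above[0]]]
        for b in above[1:]:
            if (b - runs[-1][1] - 1) * bs <= merge_distance:
                runs[-1][1] = b
            else:
                runs.append([b, b])
        for b0, b1 in runs:
            iv = GenomicInterval(chrom, b0 * bs, (b1 + 1) * bs)
            if iv.length >= min_width:
                peaks.append(iv)
    return peaks


def classify_cre(
    signals: dict[str, float],
    threshold: float = 1.0,
) -> str:
    """Rule-based CRE class from mean RPKM of the four marks over a site.

    Rules in order: CTCF-only when both K4 marks are below threshold and
    CTCF above; promoter when K4me3 dominates and passes; enhancer when
    K4me1 dominates and passes; '+CTCF' appended when CTCF also passes.
    """
    required = {"H3K4me3", "H3K4me1", "H3K27ac", "CTCF"}
    missing = required - set(signals)
    if missing:
        raise ValueError(f"missing signals: {sorted(missing)}")
    if any(v < 0 for v in signals.values()):
        raise ValueError("signals must be non-negative")
    k4me3, k4me1, ctcf = signals["H3K4me3"], signals["H3K4me1"], signals["CTCF"]
    if k4me3 <= threshold and k4me1 <= threshold and ctcf > threshold:
        return "CTCF"
    if k4me3 >= k4me1 and k4me3 > threshold:
        return "promoter+CTCF" if ctcf > threshold else "promoter"
    if k4me1 > k4me3 and k4me1 > threshold:
        return "enhancer+CTCF" if ctcf > threshold else "enhancer"
    return "unclassified"


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def scan_neutral_regions(
    criteria: NeutralCriteria,
    chromosome: str,
) -> list[GenomicInterval]:
    """Find long intervals in the A compartment devoid of any signal.

    Exclusion mask = bins above threshold in any exclusion track (padded by
    the merge distance) plus gene bodies; candidates are the A-compartment
    remainder on the requested chromosome, filtered at the minimum length
    and returned longest first.
    """
    a_ivs = [iv for iv in criteria.compartment_a if iv.chrom == chromosome]
    if not a_ivs:
        warnings.warn(f"no A-compartment intervals on {chromosome}")
        return []
    mask: list[tuple[int, int]] = []
    pad = criteria.merge_distance
    for name, track in criteria.exclusion_tracks.items():
        if chromosome not in track.values:
            continue
        v = track.values[chromosome]
        bs = track.bin_size
        above = np.flatnonzero(v > criteria.signal_threshold)
        for b in above:
            mask.append((max(0, b * bs - pad), (b + 1) * bs + pad))
    for g in criteria.genes:
        if g.chrom == chromosome:
            mask.append((g.start, g.end))
    mask = _merge_intervals(mask)
    out: list[GenomicInterval] = []
    for a in a_ivs:
        cursor = a.start
        for m0, m1 in mask:
            if m1 <= a.start or m0 >= a.end:
                continue
            if m0 > cursor:
                out.append(GenomicInterval(chromosome, cursor, min(m0, a.end)))
            cursor = max(cursor, m1)
        if cursor < a.end:
            out.append(GenomicInterval(chromosome, cursor, a.end))
    out = [iv for iv in out if iv.length >= criteria.min_length]
    return sorted(out, key=lambda iv: iv.length, reverse=True)
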