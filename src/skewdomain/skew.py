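"""Haplotype-resolved read counting, allelic-skew testing, extreme-skew
region selection and the genotype-group meta-analysis.

Sign convention: hap1 carries the REF allele after phasing normalization;
"up" means a read-count excess on the reference haplotype (skew fraction
s > 0.5).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import GenomicInterval, PhasedVariant

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeCounts",
    "SkewResult",
    "RegionCandidate",
    "ExtremeRegion",
    "MetaResult",
    "PairedTest",
    "CorrelationResult",
    "count_haplotype_reads",
    "zero_bias_sites",
    "binomial_two_sided_p",
    "skew_test",
    "consistent_skew_variants",
    "select_extreme_regions",
    "genotype_group_meta",
    "cross_assay_skew_correlation",
]

GENOTYPE_CLASSES = ("hom-ref", "het", "hom-alt")


@dataclass
class HaplotypeCounts:
    variant_id: str
    assay: str
    donor: str
    count_hap1: int
    count_hap2: int
    zeroed: bool = False
    in_peak: bool = True

    def __post_init__(self) -> None:
        if self.count_hap1 < 0 or self.count_hap2 < 0:
            raise ValueError("haplotype counts must be >= 0")
        if self.zeroed and (self.count_hap1 or self.count_hap2):
            raise ValueError("zeroed counts must both be 0")

    @property
    def total(self) -> int:
        return self.count_hap1 + self.count_hap2


@dataclass
class SkewResult:
    variant_id: str
    assay: str
    donor: str
    skew: Optional[float]  # count_hap1 / total; None when total == 0
    p_value: Optional[float]
    direction: str  # "up" | "down" | "none"
    n_total: int


@dataclass
class RegionCandidate:
    """A peak region with its putative causal variant, per-donor genotype
    class and per-donor accessibility skew result (het donors only)."""

    region: GenomicInterval
    causal_variant_id: str
    genotype_class: dict[str, str]
    skew: dict[str, SkewResult] = field(default_factory=dict)


@dataclass
class ExtremeRegion:
    region: GenomicInterval
    causal_variant_id: str
    genotype_class: dict[str, str]  # donor -> hom-ref | het | hom-alt
    coverage: dict[str, float] = field(default_factory=dict)  # donor -> value


@dataclass
class PairedTest:
    class_a: str
    class_b: str
    n_pairs: int
    t_stat: Optional[float]
    p_value: Optional[float]
    zero_variance: bool = False


@dataclass
class MetaResult:
    group_means: dict[str, float]
    points: pd.DataFrame  # region index, genotype class, value
    pairwise: list[PairedTest]


@dataclass
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int


# ---------------------------------------------------------------------------
# Counting

def _overlap_counts(df: pd.DataFrame, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Number of reads overlapping each position (start <= pos < end)."""
    sub = df[df["chrom"] == chrom]
    starts = np.sort(sub["start"].to_numpy())
    ends = np.sort(sub["end"].to_numpy())
    return np.searchsorted(starts, positions, side="right") - np.searchsorted(
        ends, positions, side="right"
    )


def count_haplotype_reads(
    placements_by_genome: dict[str, pd.DataFrame],
    variants: Sequence[PhasedVariant],
    peaks: Sequence[GenomicInterval],
    assay: str,
    donor: str,
) -> list[HaplotypeCounts]:
    """Per-haplotype read depth at each heterozygous variant.

    ``placements_by_genome`` must contain keys ``"hap1"`` and ``"hap2"``
    (reads assigned to each personalized-genome alignment).  Variants
    outside every peak are reported with ``in_peak=False``; unphased or
    homozygous variants yield no record.
    """
    for key in ("hap1", "hap2"):
        if key not in placements_by_genome:
            raise ValueError(f"missing placements for alignment target {key!r}")
    hets = []
    for v in variants:
        if not v.is_het:
            continue
        if not v.phased:
            logger.info("skipping unphased heterozygote %s", v.key)
            continue
        hets.append(v)
    out: list[HaplotypeCounts] = []
    by_chrom: dict[str, list[PhasedVariant]] = {}
    for v in hets:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom, vs in by_chrom.items():
        pos = np.array([v.pos for v in vs])
        c1 = _overlap_counts(placements_by_genome["hap1"], chrom, pos)
        c2 = _overlap_counts(placements_by_genome["hap2"], chrom, pos)
        for v, a, b in zip(vs, c1, c2):
            in_peak = any(p.contains(v.chrom, v.pos) for p in peaks)
            out.append(
                HaplotypeCounts(
                    variant_id=v.key, assay=assay, donor=donor,
                    count_hap1=int(a), count_hap2=int(b), in_peak=in_peak,
                )
            )
    return out


def zero_bias_sites(
    counts: Sequence[HaplotypeCounts],
    depths: dict[str, tuple[int, int, int]],
    tolerance: float = 0.2,
) -> list[HaplotypeCounts]:
    """Zero out sites with alignment-bias fingerprints.

    ``depths`` maps variant id to total depth under the (reference, hap1,
    hap2) alignments.  A site is zeroed when the two personalized depths
    differ by more than ``tolerance`` x their mean, or when the reference
    alignment sees nothing while a personalized alignment does.
    """
    if not (0 < tolerance <= 1):
        raise ValueError(f"tolerance must be in (0, 1], got {tolerance}")
    out = []
    for c in counts:
        d_ref, d1, d2 = depths.get(c.variant_id, (0, 0, 0))
        mean = (d1 + d2) / 2
        biased = False
        if mean == 0:
            biased = True
        elif abs(d1 - d2) > tolerance * mean:
            biased = True
        elif d_ref == 0 and (d1 > 0 or d2 > 0):
            biased = True
        if biased:
            out.append(
                HaplotypeCounts(c.variant_id, c.assay, c.donor, 0, 0,
                                zeroed=True, in_peak=c.in_peak)
            )
        else:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# Skew testing

_TIE_REL_TOL = 1e-12


def binomial_two_sided_p(k: int, n: int, p: float = 0.5) -> float:
    """Exact two-sided binomial p: sum of outcome probabilities <= P(k).

    For the balanced null (p = 0.5, n <= 50) the pmf is computed exactly in
    floats (integer binomial coefficients times a power of two) and summed
    with ``math.fsum``, making the result bit-reproducible.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        raise ValueError("n must be >= 1")
    if p == 0.5 and n <= 50:
        scale = 2.0 ** -n
        pmf = [math.comb(n, i) * scale for i in range(n + 1)]
    else:
        pmf = stats.binom.pmf(np.arange(n + 1), n, p).tolist()
    obs = pmf[k]
    total = math.fsum(x for x in pmf if x <= obs * (1 + _TIE_REL_TOL))
    return min(1.0, total)


def betabinomial_two_sided_p(k: int, n: int, rho: float) -> float:
    """Two-sided beta-binomial p at mean 0.5 with overdispersion ``rho``."""
    if not (0 < rho < 1):
        raise ValueError("rho must be in (0, 1)")
    a = (1 - rho) / (2 * rho)
    pmf = stats.betabinom.pmf(np.arange(n + 1), n, a, a)
    obs = pmf[k]
    total = float(pmf[pmf <= obs * (1 + 1e-9)].sum())
    return min(1.0, total)


def skew_test(
    counts: HaplotypeCounts,
    method: str = "binomial",
    rho: float = 0.1,
    alpha: float = 0.05,
) -> SkewResult:
    """Test the balanced-haplotype null on one site's counts.

    Direction is "up" (hap1/ref excess) or "down" only when p <= alpha;
    zero-total or zeroed sites yield an undefined result.
    """
    n = counts.total
    if counts.zeroed or n == 0:
        return SkewResult(counts.variant_id, counts.assay, counts.donor,
                          None, None, "none", 0)
    s = counts.count_hap1 / n
    if method == "binomial":
        p = binomial_two_sided_p(counts.count_hap1, n)
    elif method == "betabinomial":
        p = betabinomial_two_sided_p(counts.count_hap1, n, rho)
    else:
        raise ValueError(f"unknown skew test method {method!r}")
    if p <= alpha and s > 0.5:
        direction = "up"
    elif p <= alpha and s < 0.5:
        direction = "down"
    else:
        direction = "none"
    return SkewResult(counts.variant_id, counts.assay, counts.donor, s, p, direction, n)


def estimate_overdispersion(counts: Sequence[HaplotypeCounts]) -> float:
    """Method-of-moments overdispersion across balanced-context sites.

    Fits rho from the excess of Var(s) over binomial expectation at p=0.5;
    clipped to [1e-6, 0.99].
    """
    usable = [c for c in counts if c.total >= 2 and not c.zeroed]
    if len(usable) < 3:
        raise ValueError("need >= 3 informative sites to estimate overdispersion")
    num = 0.0
    den = 0.0
    for c in usable:
        n = c.total
        s = c.count_hap1 / n
        num += (s - 0.5) ** 2 - 0.25 / n
        den += 0.25 * (n - 1) / n
    rho = num / den if den > 0 else 0.0
    return float(np.clip(rho, 1e-6, 0.99))


def consistent_skew_variants(
    results: Sequence[SkewResult], alpha: float = 0.05
) -> list[str]:
    """Variant ids whose significant skew direction agrees wherever seen."""
    by_variant: dict[str, set[str]] = {}
    for r in results:
        if r.p_value is None or r.p_value > alpha or r.skew is None:
            continue
        d = "up" if r.skew > 0.5 else ("down" if r.skew < 0.5 else "none")
        if d == "none":
            continue
        by_variant.setdefault(r.variant_id, set()).add(d)
    return sorted(v for v, dirs in by_variant.items() if len(dirs) == 1)


def select_extreme_regions(
    candidates: Sequence[RegionCandidate],
    p_threshold: float = 1e-4,
) -> list[ExtremeRegion]:
    """Regions whose causal variant shows extreme accessibility skew.

    A region is selected when (a) at least one donor is heterozygous and
    every heterozygous donor's skew p-value is below ``p_threshold``, and
    (b) the donors span at least two distinct genotype classes.
    """
    out = []
    for cand in candidates:
        classes = set(cand.genotype_class.values())
        if not classes <= set(GENOTYPE_CLASSES):
            raise ValueError(f"unknown genotype class in {classes}")
        if len(classes) < 2 or "het" not in classes:
            continue
        het_donors = [d for d, g in cand.genotype_class.items() if g == "het"]
        ok = True
        for d in het_donors:
            r = cand.skew.get(d)
            if r is None or r.p_value is None or r.p_value >= p_threshold:
                ok = False
                break
        if ok:
            out.append(
                ExtremeRegion(
                    region=cand.region,
                    causal_variant_id=cand.causal_variant_id,
                    genotype_class=dict(cand.genotype_class),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Meta-analysis

def genotype_group_meta(
    regions: Sequence[ExtremeRegion],
) -> MetaResult:
    """Group per-region normalized coverage by genotype class and compare.

    Each region's ``coverage`` maps donor -> RPKM-per-kb value; donors in
    the same class within a region are averaged so each region contributes
    at most one point per class.  Classes are compared pairwise with the
    paired t-test, pairing on region and dropping regions missing a class.
    """
    rows = []
    for i, reg in enumerate(regions):
        per_class: dict[str, list[float]] = {}
        for donor, value in reg.coverage.items():
            cls = reg.genotype_class.get(donor)
            if cls is None:
                raise ValueError(f"region {i}: donor {donor!r} has no genotype class")
            per_class.setdefault(cls, []).append(value)
        for cls, vals in per_class.items():
            rows.append({"region": i, "class": cls, "value": float(np.mean(vals))})
    points = pd.DataFrame(rows, columns=["region", "class", "value"])
    group_means = {
        cls: float(g["value"].mean()) for cls, g in points.groupby("class")
    }
    pairwise: list[PairedTest] = []
    present = [c for c in GENOTYPE_CLASSES if c in group_means]
    wide = points.pivot(index="region", columns="class", values="value")
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            a, b = present[i], present[j]
            paired = wide[[a, b]].dropna()
            n = len(paired)
            if n < 2:
                pairwise.append(PairedTest(a, b, n, None, None))
                continue
            diffs = paired[a].to_numpy() - paired[b].to_numpy()
            if np.std(diffs, ddof=1) == 0:
                if np.all(diffs == 0):
                    pairwise.append(PairedTest(a, b, n, 0.0, 1.0))
                else:
                    pairwise.append(
                        PairedTest(a, b, n, math.inf * np.sign(diffs[0]),
                                   float(np.nextafter(0, 1)), zero_variance=True)
                    )
                continue
            t, p = stats.ttest_rel(paired[a], paired[b])
            pairwise.append(PairedTest(a, b, n, float(t), float(p)))
    return MetaResult(group_means=group_means, points=points, pairwise=pairwise)


def rpkm_per_kb(raw_count: float, region_length: int, total_mapped: int) -> float:
    """RPKM further divided by region length in kb."""
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be > 0")
    rpkm = raw_count * 1e9 / (region_length * total_mapped)
    return rpkm / (region_length / 1000)


# ---------------------------------------------------------------------------
# Cross-assay correlation

def cross_assay_skew_correlation(
    results_a: Sequence[SkewResult],
    results_b: Sequence[SkewResult],
    n_boot: int = 1000,
    seed: int = 0,
) -> Optional[CorrelationResult]:
    """Spearman correlation of signed skew (s - 0.5) across matched variants.

    95% CI by case bootstrap.  Returns None with fewer than 3 matches.
    """
    a_by_id = {(r.variant_id, r.donor): r for r in results_a if r.skew is not None}
    pairs = []
    for r in results_b:
        if r.skew is None:
            continue
        other = a_by_id.get((r.variant_id, r.donor))
        if other is not None:
            pairs.append((other.skew - 0.5, r.skew - 0.5))
    if len(pairs) < 3:
        return None
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(pairs)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(x[idx])) < 2 or len(np.unique(y[idx])) < 2:
            continue
        boots.append(stats.spearmanr(x[idx], y[idx]).statistic)
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
    return CorrelationResult(rho=rho, ci_low=float(lo), ci_high=float(hi), n=n)
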