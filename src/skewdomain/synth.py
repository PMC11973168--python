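"""Synthetic diploid cohort generator.

Emits everything the downstream stages consume: a reference genome, phased
donor variants, regulatory elements with per-haplotype activity, activity-
coupled per-assay counts and coverage, spike-in read mixtures, and reads
from an insertion-edited locus.  Element activity drives accessibility and
active-mark counts directly; the cohesin count couples linearly to activity
(baseline + coupling x activity).

All randomness flows from the config seed; identical configs give identical
outputs.  Haplotype of origin and junction truth are tagged at generation
and must only be used for truth-set evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .edit import EditSpec
from .model import GenomeSequence, GenomicInterval, PhasedVariant
from .skew import HaplotypeCounts
from .model import CoverageTrack

__all__ = [
    "SyntheticConfig",
    "RegulatoryElement",
    "Donor",
    "simulate_diploid_donors",
    "simulate_counts",
    "simulate_spikein_mixture",
    "simulate_spikein_totals",
    "simulate_edited_reads",
    "ASSAYS",
]

ASSAYS = ("ATAC", "RAD21", "H3K4me1", "H3K4me3", "H3K27ac", "CTCF")

ELEMENT_CLASSES = ("promoter", "enhancer", "CTCF", "promoter+CTCF", "enhancer+CTCF")


@dataclass(frozen=True)
class SyntheticConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrS": 200_000}
    )
    n_donors: int = 3
    snv_density: float = 1e-3  # per bp, outside causal sites
    n_elements: int = 20
    element_width: int = 400
    element_spacing: int = 5000  # start-to-start
    activity: float = 1.0  # base per-haplotype activity, in [0, 1]
    coupling: float = 50.0  # cohesin count per unit activity (kappa)
    baseline: float = 5.0  # cohesin baseline count per element (beta)
    depth: float = 100.0  # expected reads per fully active element (d)
    spikein_fraction: float = 0.04
    background: float = 0.2  # expected background reads per bin
    bin_size: int = 100
    noise: str = "poisson"  # "poisson" | "negbinom"
    dispersion: float = 0.1
    damage_factor: float = 0.0  # activity multiplier per damaging allele
    element_class: str = "enhancer"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.activity <= 1):
            raise ValueError("activity must be in [0, 1]")
        if self.coupling < 0 or self.baseline < 0 or self.depth < 0:
            raise ValueError("rates must be non-negative")
        if not (0 <= self.spikein_fraction < 1):
            raise ValueError("spike-in fraction must be in [0, 1)")
        if self.noise not in ("poisson", "negbinom"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not (0 <= self.damage_factor <= 1):
            raise ValueError("damage factor must be in [0, 1]")


@dataclass(frozen=True)
class RegulatoryElement:
    interval: GenomicInterval
    element_class: str
    activity: tuple[float, float]  # per haplotype
    causal_variant_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.element_class!r}")
        if not all(0 <= a <= 1 for a in self.activity):
            raise ValueError("activities must lie in [0, 1]")


@dataclass
class Donor:
    donor_id: str
    variants: list[PhasedVariant]
    elements: list[RegulatoryElement]

    def genotype_class(self, variant_id: str) -> str:
        for v in self.variants:
            if v.key == variant_id or v.variant_id == variant_id:
                total = sum(v.genotype)
                return ("hom-ref", "het", "hom-alt")[total]
        raise KeyError(variant_id)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, noise: str, dispersion: float
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if noise == "poisson":
        return rng.poisson(mean)
    # negative binomial with Var = mu + dispersion * mu^2
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_diploid_donors(
    config: SyntheticConfig,
    forced_genotypes: Optional[Sequence[Sequence[str]]] = None,
) -> tuple[GenomeSequence, list[Donor], list[GenomicInterval]]:
    """Generate the reference, phased donors, and element intervals.

    Each element carries one causal SNV at its midpoint whose alt allele
    multiplies that haplotype's activity by the damage factor.  Background
    SNVs are scattered at the configured density.  ``forced_genotypes``
    optionally fixes each donor's genotype class at every causal variant,
    e.g. ``[["hom-ref"] * n, ["het"] * n, ["hom-alt"] * n]``.
    """
    if config.element_width > config.element_spacing:
        raise ValueError("element width exceeds spacing; elements would overlap")
    rng = np.random.default_rng(config.seed)
    reference = GenomeSequence(
        {c: _random_sequence(rng, n) for c, n in config.chrom_lengths.items()},
        label="reference",
    )
    chrom = next(iter(config.chrom_lengths))
    chrom_len = config.chrom_lengths[chrom]
    needed = config.n_elements * config.element_spacing
    if needed > chrom_len:
        raise ValueError(
            f"{config.n_elements} elements at spacing {config.element_spacing} "
            f"exceed chromosome length {chrom_len}"
        )
    offset = (chrom_len - needed) // 2
    intervals = [
        GenomicInterval(
            chrom,
            offset + i * config.element_spacing,
            offset + i * config.element_spacing + config.element_width,
            name=f"elem{i}",
        )
        for i in range(config.n_elements)
    ]
    causal_pos = [iv.start + iv.length // 2 for iv in intervals]
    causal_set = set(causal_pos)

    # shared background SNV positions (genotypes drawn per donor)
    n_bg = rng.poisson(config.snv_density * chrom_len)
    bg_pos = sorted(
        set(rng.choice(chrom_len, size=n_bg, replace=False).tolist()) - causal_set
    ) if n_bg else []

    def alt_base(pos: int) -> str:
        ref = reference[chrom][pos]
        choices = [b for b in "ACGT" if b != ref]
        return choices[rng.integers(0, 3)]

    all_pos = sorted(set(bg_pos) | causal_set)
    alts = {pos: alt_base(pos) for pos in all_pos}

    class_to_gt = {"hom-ref": (0, 0), "het": (0, 1), "hom-alt": (1, 1)}
    donors: list[Donor] = []
    for d in range(config.n_donors):
        variants: list[PhasedVariant] = []
        causal_gt: dict[int, tuple[int, int]] = {}
        for i, pos in enumerate(causal_pos):
            if forced_genotypes is not None:
                gt = class_to_gt[forced_genotypes[d][i]]
            else:
                gt = (int(rng.integers(0, 2)), int(rng.integers(0, 2)))
            causal_gt[pos] = gt
        for pos in all_pos:
            if pos in causal_gt:
                gt = causal_gt[pos]
            else:
                gt = (int(rng.integers(0, 2)), int(rng.integers(0, 2)))
            variants.append(
                PhasedVariant(
                    chrom=chrom,
                    pos=pos,
                    ref_allele=reference[chrom][pos],
                    alt_allele=alts[pos],
                    genotype=gt,
                    phased=True,
                    variant_id=f"var_{chrom}_{pos}",
                )
            )
        elements = []
        for iv, pos in zip(intervals, causal_pos):
            gt = causal_gt[pos]
            a = tuple(
                config.activity * (config.damage_factor if gt[h] == 1 else 1.0)
                for h in (0, 1)
            )
            elements.append(
                RegulatoryElement(
                    interval=iv,
                    element_class=config.element_class,
                    activity=a,  # type: ignore[arg-type]
                    causal_variant_id=f"var_{chrom}_{pos}",
                )
            )
        donors.append(Donor(donor_id=f"donor{d + 1}", variants=variants,
                            elements=elements))
    return reference, donors, intervals


def _element_means(
    elements: Sequence[RegulatoryElement], assay: str, config: SyntheticConfig
) -> np.ndarray:
    """Expected per-haplotype counts, shape (n_elements, 2)."""
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}")
    act = np.array([e.activity for e in elements], dtype=float)
    if assay == "RAD21":
        return config.baseline + config.coupling * act
    return config.depth * act


def simulate_counts(
    elements: Sequence[RegulatoryElement],
    assay: str,
    config: SyntheticConfig,
    donor: str = "donor1",
    seed: Optional[int] = None,
) -> tuple[list[HaplotypeCounts], CoverageTrack]:
    """Draw per-haplotype counts per element plus a binned coverage track.

    Accessibility and chromatin-mark counts have mean depth x activity per
    haplotype; cohesin counts have mean baseline + coupling x activity.
    Element reads are placed uniformly within the element; background bins
    draw at the configured background rate.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    for e in elements:
        chrom_len = config.chrom_lengths.get(e.interval.chrom)
        if chrom_len is None or e.interval.end > chrom_len:
            raise ValueError(f"element {e.interval} outside genome bounds")
    means = _element_means(elements, assay, config)
    counts = _draw_counts(rng, means, config.noise, config.dispersion)
    records = []
    bs = config.bin_size
    values = {
        c: np.zeros(-(-n // bs)) for c, n in config.chrom_lengths.items()
    }
    for e, (c1, c2) in zip(elements, counts):
        records.append(
            HaplotypeCounts(
                variant_id=e.causal_variant_id or e.interval.name or str(e.interval),
                assay=assay,
                donor=donor,
                count_hap1=int(c1),
                count_hap2=int(c2),
            )
        )
        total = int(c1 + c2)
        if total:
            pos = rng.integers(e.interval.start, e.interval.end, size=total)
            np.add.at(values[e.interval.chrom], pos // bs, 1)
    if config.background > 0:
        for c in values:
            values[c] += rng.poisson(config.background, size=len(values[c]))
    n_reads = int(sum(v.sum() for v in values.values()))
    track = CoverageTrack(
        bin_size=bs, values=values, normalization="raw",
        total_mapped_reads=n_reads,
    )
    return records, track


def _uniform_placements(
    rng: np.random.Generator,
    n: int,
    chrom_lengths: dict[str, int],
    genome: str,
    source: str,
    read_length: int,
    id_start: int = 0,
) -> pd.DataFrame:
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    which = rng.choice(len(chroms), size=n, p=probs)
    starts = np.empty(n, dtype=np.int64)
    for i, c in enumerate(chroms):
        m = which == i
        hi = max(1, chrom_lengths[c] - read_length)
        starts[m] = rng.integers(0, hi, size=int(m.sum()))
    return pd.DataFrame(
        {
            "read_id": np.arange(id_start, id_start + n),
            "genome": genome,
            "chrom": np.array(chroms, dtype=object)[which],
            "start": starts,
            "end": starts + read_length,
            "mate_start": pd.array([pd.NA] * n, dtype="Int64"),
            "mate_end": pd.array([pd.NA] * n, dtype="Int64"),
            "source": source,
        }
    )


def _draw_mixture_totals(
    rng: np.random.Generator, target_depth: int, spikein_fraction: float,
    efficiency: float,
) -> tuple[int, int, int, int]:
    """(target_chip, spikein_chip, target_input, spikein_input) totals."""
    n_spike_chip = int(rng.poisson(target_depth * spikein_fraction * efficiency))
    n_target_chip = int(rng.poisson(target_depth * (1 - spikein_fraction)))
    n_spike_input = int(rng.binomial(target_depth, spikein_fraction))
    n_target_input = target_depth - n_spike_input
    return n_target_chip, n_spike_chip, n_target_input, n_spike_input


def simulate_spikein_totals(
    target_depth: int,
    spikein_fraction: float,
    efficiencies: Sequence[float],
    seed: int = 0,
) -> list[tuple[str, int, int, int, int]]:
    """Per-sample read totals only (no placement tables); same statistical
    model as :func:`simulate_spikein_mixture`, usable at high depth."""
    if not (0 < spikein_fraction < 1):
        raise ValueError("spike-in fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for i, eff in enumerate(efficiencies):
        tc, sc, ti, si = _draw_mixture_totals(
            rng, target_depth, spikein_fraction, eff
        )
        out.append((f"sample{i + 1}", tc, sc, ti, si))
    return out


def simulate_spikein_mixture(
    target_depth: int,
    spikein_fraction: float,
    efficiencies: Sequence[float],
    chrom_lengths_target: dict[str, int],
    chrom_lengths_spikein: dict[str, int],
    seed: int = 0,
    read_length: int = 75,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-sample ChIP and Input read-placement tables with a spike-in mix.

    The spike-in ChIP total scales with each sample's IP efficiency (the
    technical variation calibration must remove); Input totals depend only
    on library size and the mixing fraction.  Returns
    ``{sample_id: {"chip": table, "input": table}}``.
    """
    if not (0 < spikein_fraction < 1):
        raise ValueError("spike-in fraction must be in (0, 1)")
    if any(e <= 0 for e in efficiencies):
        raise ValueError("IP efficiencies must be > 0")
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for i, eff in enumerate(efficiencies):
        sample = f"sample{i + 1}"
        n_target_chip, n_spike_chip, n_target_input, n_spike_input = (
            _draw_mixture_totals(rng, target_depth, spikein_fraction, eff)
        )
        chip = pd.concat(
            [
                _uniform_placements(rng, n_target_chip, chrom_lengths_target,
                                    "target", "target", read_length),
                _uniform_placements(rng, n_spike_chip, chrom_lengths_spikein,
                                    "spikein", "spikein", read_length,
                                    id_start=n_target_chip),
            ],
            ignore_index=True,
        )
        inp = pd.concat(
            [
                _uniform_placements(rng, n_target_input, chrom_lengths_target,
                                    "target", "target", read_length),
                _uniform_placements(rng, n_spike_input, chrom_lengths_spikein,
                                    "spikein", "spikein", read_length,
                                    id_start=n_target_input),
            ],
            ignore_index=True,
        )
        out[sample] = {"chip": chip, "input": inp}
    return out


def simulate_edited_reads(
    edit: EditSpec,
    edited_chrom_length: int,
    depth: int,
    read_length: int,
    seed: int = 0,
    locus: Optional[GenomicInterval] = None,
) -> pd.DataFrame:
    """Uniform single-end reads over the edited locus with junction truth tags.

    The returned table carries a ``truth_junction`` column in
    {"left", "right", "both", "none"} marking reads that overlap a junction
    breakpoint at generation time; the pipeline must only consult it for
    truth-set evaluation.
    """
    left = edit.target.start
    right = edit.target.start + len(edit.insert)
    if edit.target.start > edited_chrom_length or right > edited_chrom_length:
        raise ValueError("edit outside genome bounds")
    chrom = edit.target.chrom
    if locus is None:
        locus = GenomicInterval(chrom, 0, edited_chrom_length)
    if locus.length < read_length:
        raise ValueError("locus shorter than read length")
    rng = np.random.default_rng(seed)
    if depth == 0:
        from .io import empty_placements

        df = empty_placements()
        df["truth_junction"] = pd.Series(dtype=object)
        return df
    starts = rng.integers(locus.start, locus.end - read_length + 1, size=depth)
    ends = starts + read_length
    covers_left = (starts < left) & (ends > left)
    covers_right = (starts < right) & (ends > right)
    truth = np.where(
        covers_left & covers_right, "both",
        np.where(covers_left, "left", np.where(covers_right, "right", "none")),
    )
    df = pd.DataFrame(
        {
            "read_id": np.arange(depth),
            "genome": "edited",
            "chrom": chrom,
            "start": starts.astype(np.int64),
            "end": ends.astype(np.int64),
            "mate_start": pd.array([pd.NA] * depth, dtype="Int64"),
            "mate_end": pd.array([pd.NA] * depth, dtype="Int64"),
            "source": "target",
        }
    )
    df["truth_junction"] = truth
    return df
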