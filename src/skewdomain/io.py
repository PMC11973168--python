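"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: FASTA, BED3/BED6, bedGraph, a phased-genotype VCF subset, MEME
minimal motif format, and the read-placement TSV (the SAM-like table used
in place of alignments).  Read-placement tables are pandas DataFrames with
columns ``read_id, genome, chrom, start, end, mate_start, mate_end, source``.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .model import CoverageTrack, GenomeSequence, GenomicInterval, PWM, PhasedVariant

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

PLACEMENT_COLUMNS = [
    "read_id",
    "genome",
    "chrom",
    "start",
    "end",
    "mate_start",
    "mate_end",
    "source",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike, label: str = "reference") -> GenomeSequence:
    chroms: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    chroms[name] = "".join(parts)
                name = line[1:].split()[0]
                if name in chroms:
                    raise ValueError(f"duplicate chromosome name {name!r} in {path}")
                parts = []
            elif line:
                parts.append(line.upper())
    if name is not None:
        chroms[name] = "".join(parts)
    if not chroms:
        raise ValueError(f"no sequences found in {path}")
    return GenomeSequence(chroms, label=label)


def write_fasta(genome: GenomeSequence, path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6 (0-based half-open, native convention)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED record needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            out.append(GenomicInterval(chrom, start, end, strand=strand, name=name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is None and iv.strand is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name is not None else "."
                strand = iv.strand if iv.strand is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path: PathLike, bin_size: int = 1) -> CoverageTrack:
    """Read a bedGraph into a fixed-bin track.

    Record spans must align to the bin grid; the chromosome length is taken
    as the largest end seen.
    """
    raw: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            start, end, value = int(start), int(end), float(value)
            if start % bin_size or end % bin_size:
                raise ValueError(
                    f"{path}:{ln}: span [{start},{end}) not aligned to bin size {bin_size}"
                )
            d = raw.setdefault(chrom, {})
            for b in range(start // bin_size, end // bin_size):
                d[b] = value
    values = {}
    for chrom, d in raw.items():
        n = max(d) + 1
        v = np.zeros(n)
        for b, x in d.items():
            v[b] = x
        values[chrom] = v
    return CoverageTrack(bin_size=bin_size, values=values)


def write_bedgraph(track: CoverageTrack, path: PathLike) -> None:
    """Write run-length-merged bedGraph; zero runs are omitted."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom, v in track.values.items():
            i = 0
            n = len(v)
            while i < n:
                j = i
                while j < n and v[j] == v[i]:
                    j += 1
                if v[i] != 0:
                    val = v[i]
                    text = f"{int(val)}" if float(val).is_integer() else f"{val:.6g}"
                    fh.write(f"{chrom}\t{i * bs}\t{j * bs}\t{text}\n")
                i = j


# ---------------------------------------------------------------------------
# VCF (phased-genotype subset)

def read_phased_vcf(path: PathLike) -> list[PhasedVariant]:
    """Read a simplified VCF: CHROM POS ID REF ALT [QUAL FILTER INFO] FORMAT sample.

    Only the GT field of the first sample is used.  Symbolic ALT alleles
    (``<...>``) and multi-allelic records are skipped with a logged warning.
    POS is converted from 1-based to 0-based.
    """
    out: list[PhasedVariant] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                # minimal layout: CHROM POS ID REF ALT FORMAT sample
                raise ValueError(f"{path}:{ln}: too few columns for a VCF record")
            chrom, pos1, vid, ref, alt = fields[:5]
            # locate the FORMAT column (contains GT) and the sample after it
            fmt_idx = None
            for i in range(5, len(fields) - 1):
                if "GT" in fields[i].split(":"):
                    fmt_idx = i
                    break
            if fmt_idx is None:
                raise ValueError(f"{path}:{ln}: no GT genotype column found")
            if alt.startswith("<") or "," in alt:
                logger.warning("%s:%d: skipping unsupported ALT %r", path, ln, alt)
                continue
            fmt = fields[fmt_idx].split(":")
            sample = fields[fmt_idx + 1].split(":")
            gt = sample[fmt.index("GT")]
            phased = "|" in gt
            sep = "|" if phased else "/"
            alleles = gt.split(sep)
            if len(alleles) != 2 or not all(a in ("0", "1") for a in alleles):
                logger.warning("%s:%d: skipping genotype %r", path, ln, gt)
                continue
            out.append(
                PhasedVariant(
                    chrom=chrom,
                    pos=int(pos1) - 1,
                    ref_allele=ref,
                    alt_allele=alt,
                    genotype=(int(alleles[0]), int(alleles[1])),
                    phased=phased,
                    variant_id=None if vid == "." else vid,
                )
            )
    return out


def write_phased_vcf(variants: Iterable[PhasedVariant], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in variants:
            sep = "|" if v.phased else "/"
            gt = f"{v.genotype[0]}{sep}{v.genotype[1]}"
            vid = v.variant_id or "."
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t{vid}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\t.\t.\tGT\t{gt}\n"
            )


# ---------------------------------------------------------------------------
# MEME minimal motif format

def read_pwm(path: PathLike, pseudocount: float = 1e-3) -> list[PWM]:
    """Read all motifs from a MEME minimal-format file."""
    motifs: list[PWM] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = lines[i + 1].split()
            freqs = {vals[j]: float(vals[j + 1]) for j in range(0, len(vals), 2)}
            if set(freqs) != set("ACGT"):
                raise ValueError(f"non-ACGT background alphabet in {path}")
            background = np.array([freqs[b] for b in "ACGT"])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            # find the letter-probability header
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {motif_id}: no letter-probability matrix")
            header = lines[i]
            if "alength= 4" not in header.replace("=", "= ").replace("=  ", "= "):
                # tolerate "alength=4" and "alength= 4"
                if "alength" in header and "4" not in header.split("alength")[1][:4]:
                    raise ValueError(f"motif {motif_id}: alphabet length must be 4")
            i += 1
            rows = []
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) != 4:
                    break
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    break
                i += 1
            if not rows:
                raise ValueError(f"motif {motif_id}: empty matrix")
            mat = np.array(rows).T  # (4, W)
            colsums = mat.sum(axis=0)
            if np.any(np.abs(colsums - 1.0) > 0.05):
                warnings.warn(
                    f"motif {motif_id}: matrix columns deviate from sum 1 "
                    f"(max deviation {np.abs(colsums - 1).max():.3f})"
                )
            motifs.append(
                PWM(motif_id=motif_id, matrix=mat, background=background,
                    pseudocount=pseudocount)
            )
            continue
        i += 1
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


def write_pwm(motifs: Iterable[PWM], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        first = True
        for pwm in motifs:
            if first:
                fh.write("Background letter frequencies\n")
                bg = " ".join(
                    f"{b} {f:.5f}" for b, f in zip("ACGT", pwm.background)
                )
                fh.write(bg + "\n\n")
                first = False
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width}\n"
            )
            for col in pwm.matrix.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Read-placement TSV

def empty_placements() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series(dtype=object),
            "genome": pd.Series(dtype=object),
            "chrom": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "mate_start": pd.Series(dtype="Int64"),
            "mate_end": pd.Series(dtype="Int64"),
            "source": pd.Series(dtype=object),
        }
    )


def validate_placements(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLACEMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"placement table missing columns: {missing}")
    if len(df) and (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"placement row {bad}: start >= end")
    if len(df) and not df["source"].isin(["target", "spikein"]).all():
        raise ValueError("placement 'source' must be 'target' or 'spikein'")
    return df


def read_placements(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "read_id": object,
            "genome": object,
            "chrom": object,
            "start": np.int64,
            "end": np.int64,
            "mate_start": "Int64",
            "mate_end": "Int64",
            "source": object,
        },
    )
    return validate_placements(df)


def write_placements(df: pd.DataFrame, path: PathLike) -> None:
    validate_placements(df)
    df.to_csv(path, sep="\t", index=False)
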