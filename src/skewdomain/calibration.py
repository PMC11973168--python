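"""Spike-in calibrated ChIP normalization.

Per-sample down-sampling factor:

    raw = (1 / spikein_ChIP_reads) * (spikein_Input_reads / target_Input_reads)

then a bulk coefficient ``alpha = 1 / max(raw)`` rescales the cohort so the
largest factor is exactly 1; each ChIP library is randomly subsampled by its
final factor.  The Input ratio term corrects for per-sample variation in the
spike-in mixing fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import CoverageTrack

__all__ = [
    "CalibrationSample",
    "CalibrationSet",
    "compute_downsampling_factors",
    "subsample_reads",
    "input_correction",
    "rpkm_track",
]


@dataclass
class CalibrationSample:
    sample_id: str
    target_chip: int
    spikein_chip: int
    target_input: int
    spikein_input: int
    raw_factor: Optional[float] = None
    final_factor: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("target_chip", "spikein_chip", "target_input", "spikein_input"):
            if getattr(self, name) < 0:
                raise ValueError(f"sample {self.sample_id}: {name} must be >= 0")

    @property
    def mixing_ratio(self) -> float:
        """Input-library spike-in : target read ratio (mixing diagnostic)."""
        return self.spikein_input / self.target_input


@dataclass
class CalibrationSet:
    samples: list[CalibrationSample]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [s.sample_id for s in self.samples],
                "target_chip": [s.target_chip for s in self.samples],
                "spikein_chip": [s.spikein_chip for s in self.samples],
                "target_input": [s.target_input for s in self.samples],
                "spikein_input": [s.spikein_input for s in self.samples],
                "raw_factor": [s.raw_factor for s in self.samples],
                "alpha": self.alpha,
                "final_factor": [s.final_factor for s in self.samples],
            }
        )


def compute_downsampling_factors(
    samples: Sequence[CalibrationSample],
) -> CalibrationSet:
    """Fill raw and final factors; the max final factor is exactly 1."""
    if not samples:
        raise ValueError("no samples")
    for s in samples:
        if s.spikein_chip <= 0:
            raise ValueError(f"sample {s.sample_id}: spike-in ChIP total is 0, factor undefined")
        if s.target_input <= 0:
            raise ValueError(f"sample {s.sample_id}: target Input total is 0, factor undefined")
    out = []
    for s in samples:
        raw = (1.0 / s.spikein_chip) * (s.spikein_input / s.target_input)
        out.append(
            CalibrationSample(
                s.sample_id, s.target_chip, s.spikein_chip,
                s.target_input, s.spikein_input, raw_factor=raw,
            )
        )
    max_raw = max(s.raw_factor for s in out)
    alpha = 1.0 / max_raw
    for s in out:
        s.final_factor = 1.0 if s.raw_factor == max_raw else alpha * s.raw_factor
    return CalibrationSet(samples=out, alpha=alpha)


def subsample_reads(
    placements: pd.DataFrame,
    factor: float,
    seed: int,
    exact: bool = False,
) -> pd.DataFrame:
    """Randomly retain reads at the given rate.

    Default mode keeps each read independently with probability ``factor``
    (streaming semantics); ``exact=True`` instead draws exactly
    ``round(factor * n)`` reads without replacement.
    """
    if not (0 < factor <= 1):
        raise ValueError(f"subsampling factor must be in (0, 1], got {factor}")
    if factor == 1.0 or len(placements) == 0:
        return placements.copy()
    rng = np.random.default_rng(seed)
    n = len(placements)
    if exact:
        k = int(round(factor * n))
        idx = np.sort(rng.choice(n, size=k, replace=False))
        return placements.iloc[idx].reset_index(drop=True)
    keep = rng.random(n) < factor
    return placements.loc[keep].reset_index(drop=True)


def input_correction(
    samples: Sequence[CalibrationSample], max_deviation: float = 0.5
) -> pd.DataFrame:
    """Diagnostic report of per-sample spike-in mixing ratios.

    The Input-ratio term of the down-sampling factor already applies the
    correction; this reports each sample's ratio and flags those deviating
    from the cohort median by more than ``max_deviation`` (fractional).
    """
    ratios = [s.mixing_ratio for s in samples]
    flags = [False] * len(samples)
    if len(samples) > 1:
        med = float(np.median(ratios))
        flags = [abs(r - med) > max_deviation * med for r in ratios]
    return pd.DataFrame(
        {
            "sample": [s.sample_id for s in samples],
            "mixing_ratio": ratios,
            "flagged": flags,
        }
    )


def rpkm_track(
    placements: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = 1,
    source: str = "target",
) -> CoverageTrack:
    """Bin read start positions and normalize to RPKM.

    RPKM = raw_count * 1e9 / (bin_size * total_mapped_reads); the total is
    the number of placements of the requested source.
    """
    sel = placements[placements["source"] == source]
    total = len(sel)
    if total == 0:
        raise ValueError("zero mapped reads; RPKM undefined")
    values = {}
    for chrom, length in chrom_lengths.items():
        nbins = -(-length // bin_size)
        sub = sel[sel["chrom"] == chrom]
        counts = np.bincount(
            (sub["start"].to_numpy() // bin_size).astype(np.int64),
            minlength=nbins,
        )[:nbins].astype(float)
        values[chrom] = counts
    raw = CoverageTrack(
        bin_size=bin_size, values=values, normalization="raw",
        total_mapped_reads=total,
    )
    return raw.to_rpkm()
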