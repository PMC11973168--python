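"""PWM scanning with strand annotation and allele-set motif enrichment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import GenomicInterval, PWM

__all__ = [
    "MotifHit",
    "AlleleSequenceSet",
    "scan_pwm",
    "annotate_ctcf_orientation",
    "allele_motif_enrichment",
    "reverse_complement",
    "benjamini_hochberg",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str  # "+" | "-"
    score: float  # sum over positions of log2(p_base / background_base)
    motif_id: str


@dataclass
class AlleleSequenceSet:
    """Positionally paired sequences from one allele set (up- or down-skewed)."""

    label: str  # "up" | "down"
    sequences: list[str]

    def __post_init__(self) -> None:
        if self.label not in ("up", "down"):
            raise ValueError(f"set label must be 'up' or 'down', got {self.label!r}")


def _strand_scores(seq: str, pwm: PWM) -> np.ndarray:
    """Log-odds score of every window on the given sequence (one strand)."""
    w = pwm.width
    n = len(seq) - w + 1
    lods = pwm.log_odds()
    # N (or any unknown base) contributes the worst per-column score so it
    # can never create a spurious hit
    scores = np.zeros(n)
    min_col = lods.min(axis=0)
    for j in range(w):
        col = lods[:, j]
        idx = np.array([_BASE_INDEX.get(b, -1) for b in seq[j : j + n]])
        contrib = np.where(idx >= 0, col[np.clip(idx, 0, 3)], min_col[j])
        scores += contrib
    return scores


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold_fraction: float = 0.8,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Score every window on both strands; report hits at
    score >= threshold_fraction x maximum-achievable score.

    The reverse strand scores the reverse complement of each window.
    ``offset`` shifts hit coordinates (e.g. a peak's genomic start).
    """
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold fraction must be in (0, 1]")
    seq = sequence.upper()
    w = pwm.width
    if len(seq) < w:
        return []
    max_score = pwm.max_score()
    cutoff = threshold_fraction * max_score
    if max_score == 0:
        warnings.warn(
            f"motif {pwm.motif_id}: degenerate PWM with max score 0; "
            "all windows reported"
        )
    fwd = _strand_scores(seq, pwm)
    rev_full = _strand_scores(reverse_complement(seq), pwm)
    # window starting at i on the forward sequence corresponds to window
    # starting at len(seq) - w - i on the reverse complement
    rev = rev_full[::-1]
    hits = []
    for i in range(len(fwd)):
        iv = GenomicInterval(chrom, offset + i, offset + i + w)
        if fwd[i] >= cutoff:
            hits.append(MotifHit(iv, "+", float(fwd[i]), pwm.motif_id))
        if rev[i] >= cutoff:
            hits.append(MotifHit(iv, "-", float(rev[i]), pwm.motif_id))
    return hits


def annotate_ctcf_orientation(
    peaks: Sequence[GenomicInterval],
    hits: Sequence[MotifHit],
    ambiguity_fraction: float = 0.05,
) -> list[tuple[GenomicInterval, str]]:
    """Label each peak +, -, "ambiguous" or "none" from its motif hits.

    Ambiguous = best hits on the two strands score within
    ``ambiguity_fraction`` of each other.
    """
    out = []
    for peak in peaks:
        best: dict[str, float] = {}
        for h in hits:
            if peak.overlaps(h.interval):
                if h.strand not in best or h.score > best[h.strand]:
                    best[h.strand] = h.score
        if not best:
            out.append((peak, "none"))
        elif len(best) == 1:
            out.append((peak, next(iter(best))))
        else:
            hi, lo = max(best.values()), min(best.values())
            scale = max(abs(hi), abs(lo), 1e-12)
            if (hi - lo) / scale <= ambiguity_fraction:
                out.append((peak, "ambiguous"))
            else:
                out.append((peak, "+" if best["+"] > best["-"] else "-"))
    return out


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(q, 0, 1)
    return out


def allele_motif_enrichment(
    up: AlleleSequenceSet,
    down: AlleleSequenceSet,
    pwms: Sequence[PWM],
    threshold_fraction: float = 0.8,
) -> pd.DataFrame:
    """Presence/absence motif enrichment of the up set against the down set.

    For each motif, counts sequences containing >= 1 hit in each set and
    runs a two-sided exact (hypergeometric) test on the resulting 2x2 table;
    q-values are Benjamini-Hochberg across motifs.
    """
    if not up.sequences or not down.sequences:
        raise ValueError("sequence sets must be non-empty")
    if len(up.sequences) != len(down.sequences):
        raise ValueError(
            "up/down sets must be positionally paired (same number of sequences)"
        )
    rows = []
    for pwm in pwms:
        up_n = sum(
            1 for s in up.sequences if scan_pwm(s, pwm, threshold_fraction)
        )
        down_n = sum(
            1 for s in down.sequences if scan_pwm(s, pwm, threshold_fraction)
        )
        table = [
            [up_n, len(up.sequences) - up_n],
            [down_n, len(down.sequences) - down_n],
        ]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append(
            {
                "motif": pwm.motif_id,
                "up_count": up_n,
                "up_total": len(up.sequences),
                "down_count": down_n,
                "down_total": len(down.sequences),
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df
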