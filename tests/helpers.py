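"""Shared test construction utilities (not fixtures)."""

import numpy as np
import pandas as pd

from skewdomain.model import PWM


def make_placements(rows):
    """rows: list of (read_id, genome, chrom, start, end) or full 8-tuples."""
    full = []
    for r in rows:
        if len(r) == 5:
            full.append((*r, pd.NA, pd.NA, "target"))
        else:
            full.append(r)
    df = pd.DataFrame(
        full,
        columns=[
            "read_id", "genome", "chrom", "start", "end",
            "mate_start", "mate_end", "source",
        ],
    )
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["mate_start"] = df["mate_start"].astype("Int64")
    df["mate_end"] = df["mate_end"].astype("Int64")
    return df


def uniform_reads_df(rng, n, chrom, chrom_len, read_length=75, genome="hap1"):
    starts = rng.integers(0, chrom_len - read_length, size=n)
    return make_placements(
        [(f"r{i}", genome, chrom, int(s), int(s) + read_length)
         for i, s in enumerate(starts)]
    )


def consensus_pwm(consensus, motif_id="consensus", certainty=1.0):
    """PWM putting weight `certainty` on each consensus base."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = len(consensus)
    mat = np.full((4, w), (1 - certainty) / 3)
    for j, b in enumerate(consensus):
        mat[idx[b], j] = certainty
    return PWM(motif_id=motif_id, matrix=mat)
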