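"""Cross-sample super-enhancer recurrence: consensus regions, occupancy, ranking.

Super-enhancers from all samples are merged by single-linkage overlap into
consensus regions; a binary occupancy matrix records which samples carry an
SE in each consensus region. Regions recurring in at least 80% of samples
and longer than 2,500 bp are kept and ranked — the surface on which the
top recurrent SE locus is read off.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UsageError
from .genomic_io import ScoredInterval
from .se_calling import SELandscape

__all__ = [
    "OccurrenceMatrix",
    "merge_landscapes",
    "occupancy",
    "filter_rank",
]

DEFAULT_MIN_FREQ = 0.8
DEFAULT_MIN_LEN = 2_500


@dataclass
class OccurrenceMatrix:
    """Consensus regions x samples binary presence table.

    ``occupancy[i, j]`` is 1 when sample j has at least one SE overlapping
    consensus region i by >= 1 bp. ``frequency`` is the row mean;
    ``mean_signal`` averages the overlapping SE signals over occupied samples.
    """

    consensus: list[ScoredInterval]
    samples: list[str]
    occupancy: np.ndarray  # (n_consensus, n_samples) of 0/1
    frequency: np.ndarray
    mean_signal: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{c.chrom}:{c.start}-{c.end}" for c in self.consensus]
        return pd.DataFrame(self.occupancy, index=idx, columns=self.samples)


def merge_landscapes(landscapes: list[SELandscape]) -> list[ScoredInterval]:
    """Single-linkage union of all samples' super-enhancers.

    SEs overlapping by >= 1 bp merge transitively into one consensus interval
    spanning their union. Output is sorted by (chrom, start) and pairwise
    non-overlapping.
    """
    if len(landscapes) < 2:
        raise UsageError("need >= 2 landscapes to build a consensus")
    ses = [r.interval for ls in landscapes for r in ls.superenhancers]
    if not ses:
        raise UsageError("no super-enhancers in any landscape")
    ses.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[ScoredInterval] = []
    cur = ses[0]
    cur_end = cur.end
    for iv in ses[1:]:
        if iv.chrom == cur.chrom and iv.start < cur_end:  # >= 1 bp overlap
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(ScoredInterval(cur.chrom, cur.start, cur_end))
            cur, cur_end = iv, iv.end
    merged.append(ScoredInterval(cur.chrom, cur.start, cur_end))
    return merged


def occupancy(consensus: list[ScoredInterval], landscapes: list[SELandscape]) -> OccurrenceMatrix:
    """Fill the 0/1 occupancy matrix, per-region frequency and mean signal."""
    samples = [ls.sample_id for ls in landscapes]
    n, m = len(consensus), len(landscapes)
    occ = np.zeros((n, m), dtype=np.int8)
    sig_sum = np.zeros(n)
    sig_n = np.zeros(n)
    for j, ls in enumerate(landscapes):
        for se in ls.superenhancers:
            for i, region in enumerate(consensus):
                if region.overlaps(se.interval):
                    occ[i, j] = 1
                    sig_sum[i] += se.signal
                    sig_n[i] += 1
    freq = occ.mean(axis=1)
    with np.errstate(invalid="ignore"):
        mean_signal = np.where(sig_n > 0, sig_sum / np.maximum(sig_n, 1), 0.0)
    return OccurrenceMatrix(
        consensus=consensus,
        samples=samples,
        occupancy=occ,
        frequency=freq,
        mean_signal=mean_signal,
    )


def filter_rank(
    matrix: OccurrenceMatrix,
    min_freq: float = DEFAULT_MIN_FREQ,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[ScoredInterval]:
    """Keep consensus regions with frequency >= ``min_freq`` and length > ``min_len``.

    Survivors are ranked by (frequency desc, mean signal desc, length desc),
    with (chrom, start) as the final deterministic tie-break. The returned
    intervals carry the mean signal and a name of the form ``freq=...``.
    """
    rows = [
        (i, c)
        for i, c in enumerate(matrix.consensus)
        if matrix.frequency[i] >= min_freq and c.length > min_len
    ]
    rows.sort(
        key=lambda t: (
            -matrix.frequency[t[0]],
            -matrix.mean_signal[t[0]],
            -t[1].length,
            t[1].chrom,
            t[1].start,
        )
    )
    return [
        ScoredInterval(
            c.chrom,
            c.start,
            c.end,
            name=f"freq={matrix.frequency[i]:.3f}",
            signal=float(matrix.mean_signal[i]),
        )
        for i, c in rows
    ]


def write_recurrence(
    ranked: list[ScoredInterval],
    matrix: OccurrenceMatrix,
    ranked_path: str | Path,
    matrix_path: str | Path | None = None,
) -> None:
    """Write the ranked recurrent regions and, optionally, the 0/1 matrix.

    The output header records the ranking key, which is a package convention
    (frequency, then mean signal, then length).
    """
    with open(ranked_path, "w") as fh:
        fh.write("# ranking key: frequency desc, mean_signal desc, length desc\n")
        fh.write("rank\tchrom\tstart\tend\tlength\tfrequency\tmean_signal\n")
        freq_by_key = {
            (c.chrom, c.start, c.end): matrix.frequency[i]
            for i, c in enumerate(matrix.consensus)
        }
        for rank, iv in enumerate(ranked, start=1):
            freq = freq_by_key[(iv.chrom, iv.start, iv.end)]
            fh.write(
                f"{rank}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.length}\t"
                f"{freq:.4f}\t{iv.signal:.2f}\n"
            )
    if matrix_path is not None:
        matrix.to_frame().to_csv(matrix_path, sep="\t", index_label="region")
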