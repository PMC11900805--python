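"""PWM scanning with log-odds scores and exact null-distribution p-values.

Scores are log2 likelihood ratios of the motif model against a 0-order
background. The null score distribution is computed exactly (up to a
configurable discretization) by dynamic programming: per-position score
distributions under the background model are convolved across the motif
width, giving ``pvalue(s) = P(null score >= s)`` as a right-continuous
step function — the construction FIMO uses. Both strands are scanned and
windows containing N are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .genomic_io import Pwm, ScoredInterval

__all__ = [
    "MotifHit",
    "log_odds",
    "ScoreDistribution",
    "score_pvalues",
    "scan",
    "revcomp",
    "estimate_background",
    "UNIFORM_BACKGROUND",
]

UNIFORM_BACKGROUND = np.full(4, 0.25)
DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_GRANULARITY = 1000

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifHit:
    """A motif match: TF name, genomic window (with matched strand), score, p-value."""

    tf: str
    interval: ScoredInterval
    score: float
    pvalue: float


def revcomp(sequence: str) -> str:
    """Reverse complement over the A,C,G,T,N alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


def estimate_background(sequence: str) -> np.ndarray:
    """0-order background from base frequencies, symmetrized over strands."""
    enc = encode(sequence)
    enc = enc[enc >= 0]
    if len(enc) == 0:
        return UNIFORM_BACKGROUND.copy()
    counts = np.bincount(enc, minlength=4).astype(float)
    counts = counts + counts[::-1]  # A<->T, C<->G symmetry
    return counts / counts.sum()


def encode(sequence: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and anything else (N) to -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
        lut[ord(base.lower())] = idx
    return lut[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def log_odds(pwm: Pwm, background: np.ndarray | None = None) -> np.ndarray:
    """Per-position log2(p_ib / bg_b) score matrix of shape (width, 4)."""
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if abs(bg.sum() - 1.0) > 1e-6:
        raise UsageError(f"background must sum to 1, got {bg.sum():.6f}")
    if np.any(bg <= 0):
        raise UsageError("background frequencies must all be positive")
    return np.log2(pwm.matrix / bg)


class ScoreDistribution:
    """Exact null distribution of a PWM's log-odds score on a score lattice.

    Scores are discretized per matrix cell to ``granularity`` bins spanning
    the achievable score range; the pmf of the discretized window score under
    the background model is built by convolving per-position distributions.
    Window scores evaluated on the same cell lattice (``lattice_scores`` /
    ``pvalue_lattice``) get exact tail probabilities; ``pvalue`` maps an
    arbitrary continuous score onto the lattice and is exact up to the
    accumulated cell rounding (at most ``width/2`` bins). The lookup is
    right-continuous and monotonically non-increasing in the score.
    """

    def __init__(self, score_matrix: np.ndarray, background: np.ndarray,
                 granularity: int = DEFAULT_GRANULARITY):
        if granularity < 10:
            raise UsageError(f"granularity must be >= 10, got {granularity}")
        sm = np.asarray(score_matrix, dtype=float)
        if not np.all(np.isfinite(sm)):
            raise UsageError("score matrix contains non-finite entries")
        bg = np.asarray(background, dtype=float)

        min_sum = sm.min(axis=1).sum()
        max_sum = sm.max(axis=1).sum()
        span = max_sum - min_sum
        self.binwidth = span / granularity if span > 0 else 1.0

        self.cells = self._discretize(sm)  # (w, 4) ints, the scoring lattice
        # DP convolution over positions
        dist = np.array([1.0])
        offset = 0
        for i in range(sm.shape[0]):
            row = self.cells[i]
            row_lo = int(row.min())
            step = np.zeros(int(row.max()) - row_lo + 1)
            for b in range(4):
                step[row[b] - row_lo] += bg[b]
            dist = np.convolve(dist, step)
            offset += row_lo
        self._offset = offset  # integer value of dist[0]
        # right tail: P(score_int >= k)
        self._tail = np.cumsum(dist[::-1])[::-1]

    def _discretize(self, scores: np.ndarray) -> np.ndarray:
        return np.floor(scores / self.binwidth + 0.5).astype(np.int64)

    def lattice_scores(self, windows: np.ndarray) -> np.ndarray:
        """Integer lattice scores of encoded windows (shape (n, width))."""
        w = self.cells.shape[0]
        return self.cells[np.arange(w)[None, :], windows].sum(axis=1)

    def pvalue_lattice(self, k: int | np.ndarray) -> float | np.ndarray:
        """Exact P(null lattice score >= k)."""
        k = np.asarray(k)
        idx = k - self._offset
        out = self._tail[np.clip(idx, 0, len(self._tail) - 1)]
        out = np.where(idx < 0, 1.0, out)
        out = np.where(idx >= len(self._tail), 0.0, out)
        if np.ndim(k) == 0:
            return float(out)
        return out

    def pvalue(self, score: float | np.ndarray) -> float | np.ndarray:
        """P(null score >= score) for a continuous score, via the lattice."""
        k = np.floor(np.asarray(score, dtype=float) / self.binwidth + 0.5).astype(
            np.int64
        )
        return self.pvalue_lattice(k)


def score_pvalues(
    score_matrix: np.ndarray,
    background: np.ndarray | None = None,
    granularity: int = DEFAULT_GRANULARITY,
) -> ScoreDistribution:
    """Build the exact score -> p-value lookup for a log-odds matrix."""
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    return ScoreDistribution(score_matrix, bg, granularity=granularity)


def _window_scores(
    enc: np.ndarray, lodds: np.ndarray, dist: "ScoreDistribution"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous scores, exact lattice p-values, and a validity mask
    (False where a window holds N) for every window of ``enc``."""
    w = lodds.shape[0]
    n_win = len(enc) - w + 1
    if n_win <= 0:
        empty = np.empty(0)
        return empty, empty, np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = np.all(windows >= 0, axis=1)
    # N windows (-1) are masked out; %4 keeps the index lookup in range
    scores = lodds[np.arange(w)[None, :], windows % 4].sum(axis=1)
    pvals = dist.pvalue_lattice(dist.lattice_scores(windows % 4))
    return scores, pvals, valid


def scan(
    sequence: str,
    pwm: Pwm,
    background: np.ndarray | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    granularity: int = DEFAULT_GRANULARITY,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands of ``sequence`` for matches to ``pwm``.

    Every window on the + strand, and the reverse complement of every window
    on the - strand, is scored; windows containing N are skipped. Hits with
    ``pvalue <= p_threshold`` are returned sorted by position then strand;
    overlapping hits are all reported. ``chrom``/``offset`` place hit
    coordinates in a larger reference frame. A sequence shorter than the
    motif yields an empty list.
    """
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    enc = encode(sequence)
    w = pwm.width
    hits: list[MotifHit] = []
    if len(enc) < w:
        return hits

    lodds_fwd = log_odds(pwm, bg)
    lodds_rev = log_odds(pwm.reverse_complement(), bg)
    dist_fwd = score_pvalues(lodds_fwd, bg, granularity=granularity)
    dist_rev = score_pvalues(lodds_rev, bg, granularity=granularity)

    for lodds, dist, strand in (
        (lodds_fwd, dist_fwd, "+"),
        (lodds_rev, dist_rev, "-"),
    ):
        scores, pvals, valid = _window_scores(enc, lodds, dist)
        if not len(scores):
            continue
        keep = valid & (pvals <= p_threshold)
        for i in np.flatnonzero(keep):
            iv = ScoredInterval(
                chrom, offset + int(i), offset + int(i) + w, strand=strand
            )
            hits.append(MotifHit(pwm.name, iv, float(scores[i]), float(pvals[i])))

    hits.sort(key=lambda h: (h.interval.start, h.interval.strand))
    return hits
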