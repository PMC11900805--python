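"""Readers, writers and domain types for the genomic formats the pipeline consumes.

All coordinates are internally 0-based half-open (the BED convention).
Coordinates printed in browser style (``chr20:53592377-53594956``) are treated
as 1-based inclusive and converted on entry via :func:`parse_locus`.

Chromosome names are compared as exact strings; no ``chr`` prefix
normalization is performed. :func:`check_chrom_styles` can be used to fail
fast on mixed naming styles, which otherwise cause silent empty overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError

__all__ = [
    "ScoredInterval",
    "CoverageTrack",
    "TssRecord",
    "Pwm",
    "CountMatrix",
    "read_intervals",
    "write_intervals",
    "read_coverage",
    "read_pwms",
    "read_counts",
    "read_tss",
    "write_tss",
    "parse_locus",
    "format_locus",
    "check_chrom_styles",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoredInterval:
    """A genomic interval with an optional signal value.

    The atom of peaks, stitched regions and super-enhancers. ``start`` is
    0-based inclusive, ``end`` 0-based exclusive. ``signal`` is a
    non-negative real (peak signal or coverage area) or ``None`` when unset.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    signal: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end {self.end} <= start {self.start}")
        if self.signal is not None and self.signal < 0:
            raise ValueError(f"negative signal: {self.signal}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "ScoredInterval") -> bool:
        """True when the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def with_signal(self, signal: float) -> "ScoredInterval":
        return replace(self, signal=signal)


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: gene symbol, chromosome, 0-based position, strand."""

    gene: str
    chrom: str
    tss: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS position: {self.tss}")


class CoverageTrack:
    """Per-chromosome step function of sequencing depth.

    Steps are stored as sorted, non-overlapping ``(start, end, depth)``
    triples per chromosome (0-based half-open). Gaps have implicit depth 0,
    so a chromosome absent from the track simply contributes zero signal.
    """

    def __init__(self, steps: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, triples in steps.items():
            if not len(triples):
                continue
            arr = np.asarray(sorted(triples), dtype=float)
            starts, ends, depths = arr[:, 0], arr[:, 1], arr[:, 2]
            if np.any(depths < 0):
                raise FormatError(f"negative depth on {chrom}")
            if np.any(ends <= starts):
                raise FormatError(f"empty or inverted step on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"overlapping coverage steps on {chrom}")
            self._steps[chrom] = (
                starts.astype(np.int64),
                ends.astype(np.int64),
                depths,
            )

    @property
    def chroms(self) -> list[str]:
        return sorted(self._steps)

    def steps(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._steps:
            return []
        starts, ends, depths = self._steps[chrom]
        return [(int(s), int(e), float(d)) for s, e, d in zip(starts, ends, depths)]

    def total_mass(self) -> float:
        """Sum of depth x length over all steps."""
        return float(
            sum(
                np.sum((e - s) * d)
                for s, e, d in self._steps.values()
            )
        )

    def area(self, chrom: str, start: int, end: int) -> float:
        """Integral of depth over [start, end); 0 for chromosomes not in the track."""
        if chrom not in self._steps or end <= start:
            return 0.0
        starts, ends, depths = self._steps[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * depths[lo:hi]))

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                for start, end, depth in self.steps(chrom):
                    fh.write(f"{chrom}\t{start}\t{end}\t{depth:g}\n")


@dataclass
class Pwm:
    """A position weight matrix: per-position base probabilities in A,C,G,T order.

    ``matrix`` has shape (width, 4) and rows summing to 1 after the
    pseudocount regularization applied at construction.
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"PWM matrix must be width x 4, got {m.shape}")
        m = m + self.pseudocount
        m = m / m.sum(axis=1, keepdims=True)
        self.matrix = m

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    def consensus(self) -> str:
        """Most probable base at each position."""
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        rc = Pwm.__new__(Pwm)
        rc.name = self.name
        rc.matrix = self.matrix[::-1, ::-1].copy()
        rc.pseudocount = self.pseudocount
        return rc


class CountMatrix:
    """Gene x sample integer count matrix with a per-sample condition label."""

    def __init__(self, counts: pd.DataFrame, condition: Mapping[str, str]):
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene label: {dup}")
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise FormatError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        missing = [s for s in counts.columns if s not in condition]
        if missing:
            raise FormatError(f"samples missing from condition map: {missing}")
        self.counts = counts.astype(np.int64)
        self.condition = pd.Series(
            {s: condition[s] for s in counts.columns}, name="condition"
        )

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, grp in self.condition.items():
            out.setdefault(grp, []).append(sample)
        return out


# ---------------------------------------------------------------------------
# interval I/O
# ---------------------------------------------------------------------------

_DIALECT_COLUMNS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}


def read_intervals(path: str | Path, dialect: str = "bed6") -> list[ScoredInterval]:
    """Read a BED3/BED6/narrowPeak file into :class:`ScoredInterval` records.

    narrowPeak signal is taken from column 7 (``signalValue``), the MACS
    semantics, not the capped BED score in column 5. Track and comment lines
    are skipped. Coordinates are taken verbatim (BED is already 0-based
    half-open).
    """
    if dialect not in _DIALECT_COLUMNS:
        raise UsageError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECT_COLUMNS)}"
        )
    ncol = _DIALECT_COLUMNS[dialect]
    out: list[ScoredInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncol:
                raise FormatError(
                    f"{path}: line {lineno}: expected {ncol} columns for "
                    f"{dialect}, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start or start < 0:
                raise FormatError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            name = None
            signal = None
            strand = "."
            if dialect in ("bed6", "narrowPeak"):
                name = fields[3] if fields[3] not in (".", "") else None
                strand = fields[5] if fields[5] in ("+", "-", ".") else "."
            if dialect == "bed6":
                if fields[4] not in (".", ""):
                    try:
                        signal = float(fields[4])
                    except ValueError as exc:
                        raise FormatError(
                            f"{path}: line {lineno}: non-numeric score"
                        ) from exc
            elif dialect == "narrowPeak":
                try:
                    signal = float(fields[6])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric signalValue"
                    ) from exc
            if signal is not None and signal < 0:
                raise FormatError(f"{path}: line {lineno}: negative signal")
            out.append(ScoredInterval(chrom, start, end, name, signal, strand))
    return out


def write_intervals(
    intervals: Iterable[ScoredInterval], path: str | Path, dialect: str = "bed6"
) -> None:
    """Write intervals in BED3/BED6/narrowPeak layout (inverse of :func:`read_intervals`)."""
    if dialect not in _DIALECT_COLUMNS:
        raise UsageError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for iv in intervals:
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "bed6":
                score = "." if iv.signal is None else f"{iv.signal:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand}\n"
                )
            else:  # narrowPeak: signalValue in col 7, p/q placeholders -1
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                    f"{iv.strand}\t{0 if iv.signal is None else iv.signal:g}\t"
                    f"-1\t-1\t-1\n"
                )


def read_coverage(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`.

    Input may be unsorted; overlapping steps violate the bedGraph contract
    and raise :class:`FormatError`.
    """
    steps: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                depth = float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad bedGraph line") from exc
            if depth < 0:
                raise FormatError(f"{path}: line {lineno}: negative depth")
            if end <= start:
                raise FormatError(f"{path}: line {lineno}: empty step")
            steps.setdefault(fields[0], []).append((start, end, depth))
    try:
        return CoverageTrack(steps)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# PWM I/O (MEME minimal motif format)
# ---------------------------------------------------------------------------

def read_pwms(path: str | Path, pseudocount: float = 1e-3) -> list[Pwm]:
    """Parse a MEME minimal-format motif file into :class:`Pwm` objects.

    Each letter-probability row must sum to 1 +/- 0.01 before the pseudocount
    regularization is applied.
    """
    text = Path(path).read_text()
    if "MEME version" not in text:
        raise FormatError(f"{path}: missing 'MEME version' header")
    pwms: list[Pwm] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: MOTIF line without a name")
            name = parts[1]
            # advance to the letter-probability matrix header
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {name} has no matrix")
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: motif {name} has no matrix")
            i += 1
            rows: list[list[float]] = []
            while i < len(lines):
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL", "letter-probability")):
                    break
                try:
                    vals = [float(x) for x in s.split()]
                except ValueError:
                    break
                if len(vals) != 4:
                    raise FormatError(
                        f"{path}: motif {name}: expected 4 probabilities per row"
                    )
                if abs(sum(vals) - 1.0) > 0.01:
                    raise FormatError(
                        f"{path}: motif {name}: row sums to {sum(vals):.4f}, not 1"
                    )
                rows.append(vals)
                i += 1
            if not rows:
                raise FormatError(f"{path}: motif {name} has an empty matrix")
            pwms.append(Pwm(name, np.array(rows), pseudocount=pseudocount))
        else:
            i += 1
    if not pwms:
        raise FormatError(f"{path}: no MOTIF blocks found")
    return pwms


def write_pwms(pwms: Iterable[Pwm], path: str | Path) -> None:
    """Write motifs in MEME minimal format (probabilities as stored)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# count matrix and TSS tables
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, condition_map: Mapping[str, str]) -> CountMatrix:
    """Read a genes x samples TSV of integer counts with a condition map."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene label: {dup}")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise FormatError(f"{path}: non-numeric cells in count matrix")
    if not np.issubdtype(vals.dtype, np.integer) and not np.allclose(
        vals, np.round(vals)
    ):
        raise FormatError(f"{path}: non-integer cell in count matrix")
    return CountMatrix(df, condition_map)


def write_counts(cm: CountMatrix, counts_path: str | Path, groups_path: str | Path | None = None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    if groups_path is not None:
        cm.condition.to_csv(groups_path, sep="\t", index_label="sample")


def read_tss(path: str | Path) -> list[TssRecord]:
    """Read a TSS table TSV with columns gene, chrom, tss, strand."""
    out: list[TssRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene":  # header
                continue
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            try:
                pos = int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer TSS") from exc
            out.append(TssRecord(fields[0], fields[1], pos, fields[3]))
    return out


def write_tss(records: Iterable[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\ttss\tstrand\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.chrom}\t{r.tss}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# locus strings and chromosome-style checks
# ---------------------------------------------------------------------------

def parse_locus(locus: str) -> ScoredInterval:
    """Convert a browser-style ``chrom:start-end`` locus to internal coordinates.

    Browser loci are 1-based inclusive; the returned interval is 0-based
    half-open, so ``chr1:1-100`` becomes ``[0, 100)``.
    """
    try:
        chrom, span = locus.split(":")
        s, e = span.replace(",", "").split("-")
        start1, end1 = int(s), int(e)
    except ValueError as exc:
        raise FormatError(f"cannot parse locus {locus!r}") from exc
    if start1 < 1 or end1 < start1:
        raise FormatError(f"invalid 1-based locus {locus!r}")
    return ScoredInterval(chrom, start1 - 1, end1)


def format_locus(interval: ScoredInterval) -> str:
    """Inverse of :func:`parse_locus`: print 1-based inclusive coordinates."""
    return f"{interval.chrom}:{interval.start + 1}-{interval.end}"


def check_chrom_styles(chroms: Iterable[str]) -> None:
    """Raise when chromosome names mix 'chr'-prefixed and bare styles."""
    names = set(chroms)
    prefixed = {c for c in names if c.startswith("chr")}
    if prefixed and prefixed != names:
        raise FormatError(
            "mixed chromosome naming styles: "
            f"{sorted(prefixed)[:3]} vs {sorted(names - prefixed)[:3]}"
        )
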