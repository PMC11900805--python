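"""Seeded synthetic cohort generator with planted ground truth.

Emulates the inputs of an H3K27ac super-enhancer study at desk scale:

* a uniform-random genome with a TSS table,
* per-sample peak calls and coverage in which recurrent super-enhancers
  (clusters of high-signal peaks spanning > 2.5 kb, present in >= 80% of
  samples), private SEs and isolated typical enhancers are planted,
* sharp binding motifs planted so that a chosen set of core TFs forms a
  fully interconnected autoregulatory clique (every TF's motif in every
  clique SE, >= 3 own-motif copies in its own SE) while decoy TFs receive
  at most 2 self hits,
* negative-binomial RNA-seq counts with planted knockdown-responsive genes.

Every stage records its truth in a :class:`GroundTruth` manifest so
recovery (precision/recall/F1) is computable without reading generator
internals. All randomness flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UsageError
from . import motif_scan
from .genomic_io import (
    CountMatrix,
    CoverageTrack,
    Pwm,
    ScoredInterval,
    TssRecord,
    write_counts,
    write_intervals,
    write_pwms,
    write_tss,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Cohort",
    "simulate_cohort",
    "resimulate_counts",
    "write_cohort",
]

BASES = np.array(list("ACGT"))

# default core-TF names echo a myeloid regulatory circuit; purely narrative
DEFAULT_CLIQUE_TFS = ("ZNF217", "ELF1", "MEF2D", "RUNX2", "FOXP1")
DEFAULT_DECOY_TFS = ("DECOY1", "DECOY2", "DECOY3")


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults mirror an 18-sample H3K27ac cohort with a 5-TF core circuit:
    recurrent SEs appear in >= ``recurrence_frac`` of samples and span
    > 2.5 kb; typical enhancers are isolated low-signal peaks; counts are
    NB with dispersion 0.1 and 3 + 3 knockdown design.
    """

    n_samples: int = 18
    n_chroms: int = 2
    chrom_length: int = 800_000
    n_recurrent_ses: int = 12       # >= clique + decoy TFs
    n_private_ses: int = 3
    n_typical_peaks: int = 30       # per sample, isolated low-signal peaks
    recurrence_frac: float = 0.8
    se_peaks_min: int = 3
    se_peaks_max: int = 8
    peak_length: int = 600
    se_gap_max: int = 1_200         # gap between constituent peaks
    noise_depth: float = 1.0        # Poisson mean outside peaks
    typical_depth: float = 20.0     # Poisson-ish mean inside typical peaks
    se_depth: float = 60.0          # inside SE constituent peaks
    anchor_boost: float = 1.5       # depth multiplier for the cohort-top SE
    bin_size: int = 200             # coverage step resolution
    clique_tfs: tuple[str, ...] = DEFAULT_CLIQUE_TFS
    decoy_tfs: tuple[str, ...] = DEFAULT_DECOY_TFS
    motif_width: int = 8
    consensus_prob: float = 0.97
    self_hits_per_tf: int = 3       # > 2, the self-regulation rule
    decoy_self_hits: int = 2        # below the rule on purpose
    n_genes: int = 2000
    n_de_genes: int = 100
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    n_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_recurrent_ses < len(self.clique_tfs) + len(self.decoy_tfs):
            raise UsageError(
                "need at least one recurrent SE per clique and decoy TF"
            )
        if self.self_hits_per_tf < 3:
            raise UsageError("clique TFs need >= 3 self hits to be self-regulated")
        if self.nb_dispersion <= 0:
            raise UsageError("NB dispersion must be > 0")
        if self.n_de_genes > self.n_genes:
            raise UsageError("n_de_genes exceeds n_genes")
        if not (0 < self.recurrence_frac <= 1):
            raise UsageError("recurrence_frac must be in (0, 1]")


@dataclass
class GroundTruth:
    """Planted truth: everything needed to score recovery per stage."""

    anchor_se: str = ""
    recurrent_ses: list[dict] = field(default_factory=list)
    private_ses: list[dict] = field(default_factory=list)
    se_samples: dict[str, list[str]] = field(default_factory=dict)
    planted_motifs: list[dict] = field(default_factory=list)
    clique_tfs: list[str] = field(default_factory=list)
    decoy_tfs: list[str] = field(default_factory=list)
    tf_se: dict[str, str] = field(default_factory=dict)
    de_genes: dict[str, str] = field(default_factory=dict)  # gene -> up/down

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class Cohort:
    """In-memory synthetic cohort: genome, annotations, per-sample data, truth."""

    config: SimConfig
    genome: dict[str, str]
    tss: list[TssRecord]
    peaks: dict[str, list[ScoredInterval]]          # sample -> narrowPeak-style peaks
    coverage: dict[str, CoverageTrack]              # sample -> bedGraph-style track
    pwms: list[Pwm]
    counts: CountMatrix
    truth: GroundTruth
    count_base: np.ndarray | None = None   # per-gene base means
    count_lfc: np.ndarray | None = None    # per-gene planted log2 fold changes

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.peaks)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@dataclass
class _Feature:
    kind: str           # "recurrent" | "private" | "typical"
    name: str
    chrom: str
    peaks: list[tuple[int, int]]

    @property
    def start(self) -> int:
        return self.peaks[0][0]

    @property
    def end(self) -> int:
        return self.peaks[-1][1]


def _plan_layout(config: SimConfig, rng: np.random.Generator) -> list[_Feature]:
    """Place SE peak clusters and typical peaks along the genome.

    Features are separated by more than the 12.5 kb stitching distance so
    each planted feature maps to exactly one stitched region. Placement is
    sequential with random spacing; an error is raised up front if the
    chromosomes cannot hold everything.
    """
    features: list[_Feature] = []
    specs: list[tuple[str, str]] = (
        [("recurrent", f"SE{i}") for i in range(config.n_recurrent_ses)]
        + [("private", f"PRIV{i}") for i in range(config.n_private_ses)]
        + [("typical", f"TYP{i}") for i in range(config.n_typical_peaks)]
    )
    order = rng.permutation(len(specs))
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    separation = 14_000  # > default stitching distance of 12,500
    cursor = {c: 5_000 for c in chroms}
    ci = 0
    for k in order:
        kind, name = specs[k]
        if kind in ("recurrent", "private"):
            # SE0 is the anchor: maximal peak count so, with its depth boost,
            # it is the unambiguous cohort-top region
            if name == "SE0":
                n_peaks = config.se_peaks_max
            else:
                n_peaks = int(rng.integers(config.se_peaks_min, config.se_peaks_max + 1))
            gaps = rng.integers(200, config.se_gap_max + 1, size=n_peaks - 1)
        else:
            n_peaks, gaps = 1, np.array([], dtype=int)
        span = n_peaks * config.peak_length + int(gaps.sum())
        if kind in ("recurrent", "private") and span <= 2_500:
            # stretch gaps so every planted SE passes the length filter
            deficit = 2_501 - span
            extra = deficit // max(1, n_peaks - 1) + 1
            gaps = gaps + extra
            span = n_peaks * config.peak_length + int(gaps.sum())
        placed = False
        for _ in range(len(chroms)):
            chrom = chroms[ci % len(chroms)]
            start = cursor[chrom] + int(rng.integers(0, 4_000))
            if start + span + separation < config.chrom_length - 5_000:
                peaks = []
                pos = start
                for j in range(n_peaks):
                    peaks.append((pos, pos + config.peak_length))
                    if j < n_peaks - 1:
                        pos += config.peak_length + int(gaps[j])
                features.append(_Feature(kind, name, chrom, peaks))
                cursor[chrom] = peaks[-1][1] + separation
                placed = True
                ci += 1
                break
            ci += 1
        if not placed:
            raise UsageError(
                "chromosomes too small for the requested features; increase "
                "chrom_length or reduce feature counts"
            )
    features.sort(key=lambda f: (f.chrom, f.start))
    return features


# ---------------------------------------------------------------------------
# genome + TSS
# ---------------------------------------------------------------------------

def _random_genome(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    genome = {}
    for i in range(config.n_chroms):
        seq = rng.integers(0, 4, size=config.chrom_length)
        genome[f"chr{i + 1}"] = "".join(BASES[seq])
    return genome


def _designate_tf_ses(config: SimConfig, features: list[_Feature]) -> dict[str, _Feature]:
    """Assign one recurrent SE per TF (clique then decoys), by SE index.

    The first clique TF gets the anchor SE0, mirroring a cohort whose top
    recurrent SE sits at the locus of a core circuit TF.
    """
    recurrent = sorted(
        (f for f in features if f.kind == "recurrent"),
        key=lambda f: int(f.name[2:]),
    )
    tf_names = list(config.clique_tfs) + list(config.decoy_tfs)
    return dict(zip(tf_names, recurrent))


def _make_tss(
    config: SimConfig,
    features: list[_Feature],
    tf_feat: dict[str, _Feature],
    rng: np.random.Generator,
) -> list[TssRecord]:
    """One gene per planted SE (placed just outside the SE span, within the
    proximal assignment window) plus scattered background genes. SEs
    designated to a TF carry the TF's own gene symbol, making the circuit
    autoregulatory by construction."""
    gene_for = {feat.name: tf for tf, feat in tf_feat.items()}
    records = []
    se_feats = [f for f in features if f.kind != "typical"]
    for feat in se_feats:
        gene = gene_for.get(feat.name, f"GENE_{feat.name}")
        # just past the SE span: close enough to be the unambiguous nearest
        # TSS, far enough that the last constituent peak is not fully inside
        # the +/- 2 kb TSS exclusion zone
        pos = feat.end + int(rng.integers(1_600, 2_400))
        records.append(TssRecord(gene, feat.chrom, pos, "+"))
    # background genes are kept clear of SE spans so each planted SE has a
    # single well-defined gene assignment
    i = 0
    while i < 20:
        chrom = f"chr{rng.integers(1, config.n_chroms + 1)}"
        pos = int(rng.integers(0, config.chrom_length))
        if any(
            f.chrom == chrom and f.start - 3_000 <= pos < f.end + 3_000
            for f in se_feats
        ):
            continue
        records.append(TssRecord(f"BG{i}", chrom, pos, "-"))
        i += 1
    return records


# ---------------------------------------------------------------------------
# landscapes (peaks + coverage)
# ---------------------------------------------------------------------------

def _sample_membership(
    config: SimConfig,
    features: list[_Feature],
    tf_feat: dict[str, _Feature],
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Which samples carry each recurrent SE.

    SEs designated to circuit TFs (and the anchor) are present in every
    sample — the circuitry is cohort-defining; the remaining recurrent SEs
    appear in a random >= recurrence_frac subset of samples.
    """
    samples = [f"S{i:02d}" for i in range(config.n_samples)]
    membership: dict[str, list[str]] = {}
    designated = {feat.name for feat in tf_feat.values()}
    recurrent = [f for f in features if f.kind == "recurrent"]
    for feat in recurrent:
        if feat.name in designated:
            membership[feat.name] = list(samples)
            continue
        k_min = int(np.ceil(config.recurrence_frac * config.n_samples))
        k = int(rng.integers(k_min, config.n_samples + 1))
        chosen = rng.choice(config.n_samples, size=k, replace=False)
        membership[feat.name] = sorted(samples[j] for j in chosen)
    private = [f for f in features if f.kind == "private"]
    for feat in private:
        owner = samples[int(rng.integers(config.n_samples))]
        membership[feat.name] = [owner]
    return membership


def _build_sample(
    config: SimConfig,
    features: list[_Feature],
    membership: dict[str, list[str]],
    sample: str,
    rng: np.random.Generator,
) -> tuple[list[ScoredInterval], CoverageTrack]:
    peaks: list[ScoredInterval] = []
    depth_boost: list[tuple[str, int, int, float]] = []
    for feat in features:
        if feat.kind == "typical":
            present = True
            mean_depth = config.typical_depth
        else:
            present = sample in membership[feat.name]
            mean_depth = config.se_depth
            if feat.name == "SE0":
                mean_depth *= config.anchor_boost
        if not present:
            continue
        for j, (s, e) in enumerate(feat.peaks):
            depth = float(max(1, rng.poisson(mean_depth)))
            peaks.append(
                ScoredInterval(
                    feat.chrom, s, e, name=f"{sample}_{feat.name}_{j}",
                    signal=depth, strand=".",
                )
            )
            depth_boost.append((feat.chrom, s, e, depth))

    steps: dict[str, list[tuple[int, int, float]]] = {}
    nbins = config.chrom_length // config.bin_size
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        depths = rng.poisson(config.noise_depth, size=nbins).astype(float)
        for bchrom, s, e, d in depth_boost:
            if bchrom != chrom:
                continue
            b0, b1 = s // config.bin_size, -(-e // config.bin_size)
            depths[b0:b1] += d
        chrom_steps = []
        run_start, run_val = 0, depths[0]
        for i in range(1, nbins):
            if depths[i] != run_val:
                if run_val > 0:
                    chrom_steps.append(
                        (run_start * config.bin_size, i * config.bin_size, run_val)
                    )
                run_start, run_val = i, depths[i]
        if run_val > 0:
            chrom_steps.append(
                (run_start * config.bin_size, nbins * config.bin_size, run_val)
            )
        steps[chrom] = chrom_steps
    return peaks, CoverageTrack(steps)


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def _sharp_pwm(name: str, word: str, consensus_prob: float) -> Pwm:
    off = (1.0 - consensus_prob) / 3.0
    mat = np.full((len(word), 4), off)
    for i, base in enumerate(word):
        mat[i, "ACGT".index(base)] = consensus_prob
    return Pwm(name, mat, pseudocount=0.0)


def _distinct_words(
    n: int, width: int, rng: np.random.Generator
) -> list[str]:
    """Random motif consensus words, pairwise distinct and not reverse
    complements of one another (so planted instances are unambiguous)."""
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < n:
        word = "".join(BASES[rng.integers(0, 4, size=width)])
        rc = motif_scan.revcomp(word)
        if word in seen or rc in seen or word == rc:
            continue
        seen.add(word)
        seen.add(rc)
        words.append(word)
    return words


def _plant_crc(
    config: SimConfig,
    genome: dict[str, str],
    features: list[_Feature],
    tf_feat: dict[str, _Feature],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> list[Pwm]:
    """Write motif words into designated SE sequences to create the clique.

    Every ordered pair (A, B) of clique TFs gets one A-consensus word in
    B's SE; every clique TF gets ``self_hits_per_tf`` own words in its own
    SE; decoy TFs get exactly ``decoy_self_hits`` own words. Afterwards the
    designated extended regions are scrubbed: background windows that
    incidentally match any motif at the scan threshold are re-drawn, so hit
    counts equal planted counts exactly.
    """
    tf_names = list(tf_feat)
    words = _distinct_words(len(tf_names), config.motif_width, rng)
    pwms = [
        _sharp_pwm(tf, word, config.consensus_prob)
        for tf, word in zip(tf_names, words)
    ]
    word_by_tf = dict(zip(tf_names, words))

    for tf, feat in tf_feat.items():
        truth.tf_se[tf] = feat.name

    seqs = {c: np.frombuffer(s.encode(), dtype=np.uint8).copy()
            for c, s in genome.items()}

    def write_word(chrom: str, pos: int, word: str) -> None:
        seqs[chrom][pos:pos + len(word)] = np.frombuffer(word.encode(), np.uint8)

    flank = 500
    w = config.motif_width
    placements: dict[str, list[tuple[int, int]]] = {}  # feat.name -> spans used
    for target_tf, feat in tf_feat.items():
        sources: list[str] = []
        if target_tf in config.clique_tfs:
            sources += [a for a in config.clique_tfs if a != target_tf]
            sources += [target_tf] * config.self_hits_per_tf
        else:
            sources += [target_tf] * config.decoy_self_hits
        span_start, span_end = feat.start, feat.end
        n_slots = len(sources)
        usable = span_end - span_start - w
        if usable < n_slots * (w + 10):
            raise UsageError(f"SE {feat.name} too short for {n_slots} motif placements")
        slot_stride = usable // n_slots
        spans = []
        for i, source in enumerate(sources):
            jitter = int(rng.integers(0, max(1, slot_stride - w - 2)))
            pos = span_start + i * slot_stride + jitter
            strand = "+" if rng.random() < 0.5 else "-"
            word = word_by_tf[source]
            write_word(feat.chrom, pos, word if strand == "+" else motif_scan.revcomp(word))
            spans.append((pos, pos + w))
            truth.planted_motifs.append(
                {
                    "tf": source,
                    "target_tf": target_tf,
                    "se": feat.name,
                    "chrom": feat.chrom,
                    "position": int(pos),
                    "strand": strand,
                }
            )
        placements[feat.name] = spans

    # scrub incidental matches from every designated extended SE region
    genome_out = {c: a.tobytes().decode() for c, a in seqs.items()}
    for feat in tf_feat.values():
        lo = max(0, feat.start - flank)
        hi = min(len(genome_out[feat.chrom]), feat.end + flank)
        planted = placements[feat.name]
        for _ in range(40):
            region = genome_out[feat.chrom][lo:hi]
            dirty: set[int] = set()
            for pwm in pwms:
                for hit in motif_scan.scan(region, pwm, offset=lo):
                    span = (hit.interval.start, hit.interval.end)
                    if span in planted:
                        continue
                    for p in range(*span):
                        if not any(a <= p < b for a, b in planted):
                            dirty.add(p)
            if not dirty:
                break
            arr = seqs[feat.chrom]
            idx = np.array(sorted(dirty))
            arr[idx] = np.frombuffer(
                "".join(BASES[rng.integers(0, 4, size=len(idx))]).encode(),
                np.uint8,
            )
            genome_out[feat.chrom] = arr.tobytes().decode()
        else:
            raise UsageError("could not scrub incidental motif matches")

    genome.clear()
    genome.update({c: a.tobytes().decode() for c, a in seqs.items()})
    truth.clique_tfs = list(config.clique_tfs)
    truth.decoy_tfs = list(config.decoy_tfs)
    return pwms


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_counts(
    config: SimConfig,
    base: np.ndarray,
    lfc: np.ndarray,
    rng: np.random.Generator,
) -> CountMatrix:
    """Sample the NB count matrix given per-gene base means and fold changes.

    Sample size factors are log-normal (sd 0.2); NB is parameterized as mean
    m, variance m + alpha m^2 (gamma-Poisson mixture).
    """
    n = config.n_genes
    genes = [f"G{i:04d}" for i in range(n)]
    alpha = config.nb_dispersion
    n_per = config.n_per_group
    samples = [f"ctrl_{i}" for i in range(n_per)] + [f"kd_{i}" for i in range(n_per)]
    condition = {s: ("control" if s.startswith("ctrl") else "knockdown")
                 for s in samples}
    sf = np.exp(rng.normal(0.0, 0.2, size=2 * n_per))
    counts = np.zeros((n, 2 * n_per), dtype=np.int64)
    for j in range(2 * n_per):
        mean = base * (2.0 ** lfc if j >= n_per else 1.0) * sf[j]
        lam = rng.gamma(1.0 / alpha, mean * alpha)
        counts[:, j] = rng.poisson(lam)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    return CountMatrix(df, condition)


def _simulate_counts(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
    """NB counts with planted DE genes.

    Per-gene base means are log-uniform in [20, 2000]; planted genes shift
    the knockdown group by ``de_log2fc`` with random sign. Returns the
    matrix plus the per-gene (base mean, log2fc) parameters so independent
    count replicates of the same experiment can be drawn.
    """
    n = config.n_genes
    genes = [f"G{i:04d}" for i in range(n)]
    base = np.exp(rng.uniform(np.log(20), np.log(2000), size=n))
    de_idx = rng.choice(n, size=config.n_de_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    lfc = np.zeros(n)
    lfc[de_idx] = signs * config.de_log2fc
    for i, s in zip(de_idx, signs):
        truth.de_genes[genes[i]] = "up" if s > 0 else "down"
    return _nb_counts(config, base, lfc, rng), base, lfc


def resimulate_counts(cohort: Cohort, seed: int) -> CountMatrix:
    """An independent count replicate of the cohort's knockdown experiment.

    Keeps the gene-level parameters (base means, planted DE genes and their
    directions) and redraws the NB noise and size factors — emulating the
    same perturbation assayed in a second cell line.
    """
    if cohort.count_base is None or cohort.count_lfc is None:
        raise UsageError("cohort carries no count parameters")
    rng = np.random.default_rng(seed)
    return _nb_counts(cohort.config, cohort.count_base, cohort.count_lfc, rng)


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate the full synthetic cohort deterministically from one seed."""
    config = config or SimConfig()
    if seed is not None:
        config.seed = seed
    rng = np.random.default_rng(config.seed)

    features = _plan_layout(config, rng)
    tf_feat = _designate_tf_ses(config, features)
    genome = _random_genome(config, rng)
    tss = _make_tss(config, features, tf_feat, rng)
    membership = _sample_membership(config, features, tf_feat, rng)

    gene_for = {feat.name: tf for tf, feat in tf_feat.items()}
    truth = GroundTruth(anchor_se="SE0")
    for feat in features:
        entry = {
            "name": feat.name,
            "chrom": feat.chrom,
            "start": feat.start,
            "end": feat.end,
            "n_peaks": len(feat.peaks),
            "gene": gene_for.get(feat.name, f"GENE_{feat.name}"),
        }
        if feat.kind == "recurrent":
            truth.recurrent_ses.append(entry)
            truth.se_samples[feat.name] = membership[feat.name]
        elif feat.kind == "private":
            truth.private_ses.append(entry)
            truth.se_samples[feat.name] = membership[feat.name]

    samples = [f"S{i:02d}" for i in range(config.n_samples)]
    peaks: dict[str, list[ScoredInterval]] = {}
    coverage: dict[str, CoverageTrack] = {}
    for sample in samples:
        p, c = _build_sample(config, features, membership, sample, rng)
        peaks[sample], coverage[sample] = p, c

    pwms = _plant_crc(config, genome, features, tf_feat, truth, rng)
    counts, base, lfc = _simulate_counts(config, truth, rng)

    return Cohort(
        config=config, genome=genome, tss=tss, peaks=peaks, coverage=coverage,
        pwms=pwms, counts=counts, truth=truth, count_base=base, count_lfc=lfc,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort to disk in the standard formats.

    Emits genome.fa, tss.tsv, per-sample <S>.narrowPeak and <S>.bedGraph,
    motifs.meme, counts.tsv, groups.tsv and ground_truth.json.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sorted(cohort.genome.items())
    ]
    SeqIO.write(records, out / "genome.fa", "fasta")
    write_tss(cohort.tss, out / "tss.tsv")
    for sample in cohort.sample_ids:
        write_intervals(
            cohort.peaks[sample], out / f"{sample}.narrowPeak", dialect="narrowPeak"
        )
        cohort.coverage[sample].write_bedgraph(out / f"{sample}.bedGraph")
    write_pwms(cohort.pwms, out / "motifs.meme")
    write_counts(cohort.counts, out / "counts.tsv", out / "groups.tsv")
    cohort.truth.to_json(out / "ground_truth.json")
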