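# Methods

`secircuit` implements a regulatory-genomics pipeline for H3K27ac cohorts:
per-sample super-enhancer (SE) calling, cross-sample SE recurrence, core
regulatory circuitry (CRC) construction and scoring, and a simplified
differential-expression stage for nominating knockdown-responsive target
genes. A seeded synthetic-data generator with a ground-truth manifest makes
every stage verifiable by parameter recovery. This note records the models,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic surface does and does not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open (the BED convention).
Browser-style locus strings such as `chr20:53592377-53594956` are treated as
1-based inclusive and converted on entry (`start-1, end`); whether a given
printed locus was actually 1-based is an assumption, recorded here rather
than asserted. narrowPeak signal is read from column 7 (`signalValue`, the
MACS semantics), not the capped BED score in column 5. Chromosome names are
compared as exact strings — no `chr` normalization — because silently empty
overlaps from mixed naming styles are the classic failure mode;
`check_chrom_styles` fails fast instead. PWM probabilities get a pseudocount
of 0.001 per cell before renormalization, so log-odds scores stay finite.

## Super-enhancer calling

The per-sample procedure follows the rank-ordering approach standard for
H3K27ac landscapes:

1. **TSS exclusion** (default t = 2,000 bp): peaks whose *entire* span lies
   within ±t of any TSS are removed *before* stitching, so promoter-proximal
   signal cannot seed stitched regions. Peaks merely overlapping an
   exclusion zone are kept.
2. **Stitching** (default s = 12,500 bp): peaks on one chromosome are merged
   transitively when the gap `next.start − prev.end` is ≤ s (inclusive).
   Each stitched region spans min(start)..max(end) of its chain and keeps
   the source peaks as constituents.
3. **Quantification**: a region's signal is the integral of coverage depth
   over its span (an *area*, not a density), minus the same integral of an
   optional control track, floored at 0. Ranking by area means long regions
   accumulate signal, which the downstream length filter presumes. Whether
   a control is subtracted is a knob; the default is no control.
4. **Cutoff**: signals are sorted ascending; ranks x and signals y are
   min-max scaled to [0, 1]; the cutoff index is `argmax(x − y)` — for a
   convex curve, the point where the tangent slope passes 1. Ties resolve
   to the highest index (fewer SEs; on an exactly linear ramp no region is
   called super). Regions with signal strictly greater than the cutoff
   signal are super-enhancers; ranks (1 = highest) break ties by
   (chrom, start). A constant signal vector is an error, not an answer.
5. **Gene assignment**: an SE takes every gene whose TSS lies inside its
   span; if none do, the single nearest TSS within 50 kb; otherwise no gene.

## Cross-sample recurrence

Super-enhancers from all samples are merged by single-linkage overlap
(≥ 1 bp, transitively) into non-overlapping consensus regions. The
occupancy matrix marks a consensus region present in a sample when any of
that sample's SEs overlaps it by ≥ 1 bp; no reciprocal-fraction requirement
is imposed — this is the simplest reading of a 0/1 occurrence heatmap, and
the overlap rule is a config knob. Regions with frequency ≥ 0.8
(implemented inclusively: "at least 80% of samples") and length strictly
greater than 2,500 bp survive the filter. Survivors are ranked by
(frequency desc, mean SE signal over occupied samples desc, length desc),
with (chrom, start) as the final deterministic tie-break. The ranking key
beyond frequency is a package convention — recorded in output headers —
since "significance" of a recurrent region is not otherwise defined for a
binary occurrence matrix.

## Motif scanning

Scanning is FIMO-style: a PWM is scored as per-position log2 likelihood
ratios against a 0-order background (default uniform; optionally estimated
from the scanned sequence and strand-symmetrized), and every window on both
strands is tested. p-values are exact under the background model: per-cell
scores are discretized onto a lattice of 1,000 bins spanning the achievable
score range, and the null distribution of the window score is built by
convolving per-position distributions. Windows are scored *on the same
lattice*, so their tail probabilities are exact; mapping an arbitrary
continuous score onto the lattice is instead exact only up to the
accumulated per-cell rounding (at most width/2 bins). The p-value lookup is
right-continuous and monotone non-increasing in the score.

Defaults: p ≤ 1e-4 to call a hit (the conventional scanner default; no
threshold is otherwise dictated by the analysis), overlapping hits of one
motif all count (no greedy pruning — a knob, because it changes the
self-regulation rule's counts), windows containing N are skipped silently.

## Core regulatory circuitry

Each motif-bearing TF is tied to exactly one SE — its highest-ranked
assigned SE when several map to the TF's gene (determinism; scanning all is
a knob). SE regions are extended by 500 bp on both sides, clamped to
chromosome bounds, and every TF's motif is scanned against every TF's
extended SE, giving a hit-count table `counts[A][B]`.

* **Edges**: A→B (A ≠ B) when `counts[A][B] ≥ 1`.
* **Self-regulation**: A is self-regulated when `counts[A][A] ≥ 3` — the
  strict reading of "more than two binding motifs". Much CRC work uses
  ≥ 1; the threshold is a knob.
* **Circuits**: all subsets of self-regulated TFs, size 2..8, in which every
  ordered pair is an edge (mutual regulation). Enumeration runs
  Bron–Kerbosch maximal cliques on the undirected mutual-edge projection,
  then expands sub-cliques; this equals a brute-force subset sweep, which
  the tests assert. Whether a "fully interconnected" circuit requires
  mutual pairwise edges or merely a directed loop is a genuine modelling
  choice; mutual-clique semantics were adopted as the stricter and more
  conventional one. The size cap (8) bounds the combinatorial blow-up and
  truncation triggers a warning.
* **Scores**: with occ(t) = number of circuits containing TF t, a circuit C
  scores `Σ_{t∈C} occ(t) / |C|`. Circuit membership (not raw motif hit
  counts) is what occ counts. The identity `Σ_C score(C)·|C| = Σ_t occ(t)²`
  is used as an internal consistency check. Scores are per sample;
  cross-sample aggregation is an extension, not part of the core model.
* **Connectivity table**: per-TF in/out degree, occ and top-circuit
  membership, sorted by occ then total degree — the surface on which
  candidate core TFs are read off.

## Differential expression and target nomination

This stage is deliberately a *simplified* negative-binomial analysis, a
stand-in for a full DESeq2 run: shrinkage, outlier replacement and
independent filtering are **not** reproduced, and exact DEG counts from real
knockdown RNA-seq datasets are neither expected nor used as a validation
target — the synthetic recovery statistics below are the test surface.

* **Size factors**: median-of-ratios against the per-gene geometric mean
  over genes positive in all samples, rescaled to geometric mean 1.
* **Dispersion**: per-gene method-of-moments `(var − mean)/mean²` on
  normalized counts, pooled within gene across the two groups, then
  averaged across genes into one common dispersion, floored at 0.01.
  Negative per-gene estimates are kept in the average so it stays unbiased.
  Sharing one dispersion across genes is what keeps the normal Wald
  reference calibrated at the group sizes this test targets (n = 2–3);
  a per-gene estimate at n = 3 has ~4 df and visibly inflates type-I error.
* **Test**: log2 fold change of normalized group means with a 0.5
  pseudo-count; delta-method standard error from the NB variance
  m + αm²; two-sided normal p-value. Genes with |log2FC| > 0.5 and raw
  p < 0.05 are called up/down. BH-adjusted p-values are reported as an
  extra column, but the filter uses raw p — both are emitted so either
  convention can be applied downstream.
* **Nomination**: per dataset, the top-10 significant genes by p-value;
  genes in every dataset's top list are reported with per-dataset
  directions and a concordance flag.

## Synthetic cohort

The generator emulates the *structure* of an 18-sample H3K27ac cohort
(defaults; all sizes configurable) on a 2 × 800 kb uniform-random genome:

* **Recurrent SEs** (12): clusters of 3–8 peaks of 600 bp with gaps up to
  1.2 kb, each cluster spanning > 2.5 kb. The 8 SEs designated to circuit
  TFs (5 clique + 3 decoys) are present in every sample — the circuitry is
  cohort-defining; the rest appear in a random ≥ 80% subset of samples.
  Features are separated by > 12.5 kb so each maps to one stitched region.
* **Anchor**: one clique-TF SE carries the maximal peak count and a 1.5×
  depth boost, making it the unambiguous cohort-top region — emulating a
  cohort whose strongest recurrent SE sits at the locus of a core TF.
* **Typical enhancers** (30/sample) are isolated 600 bp peaks; depths are
  Poisson with mean 20 (typical) / 60 (SE constituents) over a mean-1
  Poisson noise floor in 200 bp bins — chosen so the rank/signal elbow is
  unambiguous at defaults. Coverage tracks are consistent with the peaks.
* **Genes**: each SE's gene TSS sits ~2 kb past the SE span — close enough
  to be the unambiguous nearest TSS, far enough that no constituent peak is
  swallowed by the ±2 kb TSS exclusion; background TSS are kept clear of SE
  spans so every planted SE has one well-defined gene.
* **Circuit**: sharp PWMs (consensus probability 0.97, width 8, pairwise
  distinct and non-reverse-complementary words). Every ordered clique pair
  (A, B) gets one A-word in B's SE; every clique TF gets 3 own words in its
  own SE; decoys get exactly 2. After planting, the designated extended
  regions are scrubbed: background windows that incidentally match any
  motif at the scan threshold are re-drawn, so hit counts equal planted
  counts exactly and the decoy rule ("2 is not more than 2") is testable.
* **Counts**: NB (gamma–Poisson) with common dispersion 0.1, per-gene base
  means log-uniform in [20, 2000], log-normal size factors (sd 0.2),
  3 + 3 control/knockdown design, 100 of 2,000 genes shifted by |log2FC| = 2
  with random sign. `resimulate_counts` redraws the noise while keeping the
  gene-level parameters — the same perturbation assayed in a second cell
  line.

All randomness flows from a single `numpy` Generator seeded once, so the
whole simulate → call → recur → circuit → test chain is byte-reproducible.
The `GroundTruth` manifest records planted SEs and carriers, motif
placements, clique membership and DE genes with directions — enough to
compute precision/recall for every stage without reading generator
internals.

## What the synthetic surface does not show

Passing recovery tests demonstrates algorithmic correctness and internal
calibration, **not** fidelity to real chromatin data. The generator has no
GC or mappability structure, no fragment-length model, no read-level noise,
no correlated backgrounds between samples, and uniform base composition; a
real cohort's SE landscape is far noisier and its motif background far from
0-order-uniform. Cohort-level outputs of published analyses of this kind —
the specific top SE locus and its gene, exact DEG counts from DESeq2,
survival statistics — depend on the real sequencing datasets and external
tools and are **not** reproducible from this synthetic surface; the
pipeline reports them only when given that data. Hi-C support, GSEA, and
survival analysis are out of scope.

## Problem sizes used in validation

Recovery statistics are computed on 20 independent default cohorts
(18 samples each; per-sample SE-call F1, anchor top-rank rate, clique
recovery), one 2,000-gene null cohort for type-I error, and one default
cohort for power — sizes at which every stage's behaviour is already
stable and the full validation runs in a few minutes on one core.
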