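"""Core regulatory circuitry: TF->TF graph from motif hits, circuits, scoring.

Each candidate TF is tied to one super-enhancer region; regions are extended
by 500 bp on both sides and scanned with every TF's binding motif. An edge
A->B means at least one A-motif hit in B's extended SE; a TF is
self-regulated when its own extended SE carries more than two of its own
motifs. Circuits are sets of self-regulated TFs in which every ordered pair
is an edge (mutual regulation), and each circuit's score is the summed
circuit-membership counts of its members divided by the circuit size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import UsageError
from .genomic_io import Pwm, ScoredInterval
from . import motif_scan

__all__ = [
    "TFGraph",
    "Circuit",
    "extend_regions",
    "tf_se_hit_table",
    "build_graph",
    "enumerate_circuits",
    "score_circuits",
    "tf_connectivity",
    "assign_tf_regions",
    "run_crc",
]

DEFAULT_FLANK = 500
DEFAULT_SELF_MIN_HITS = 3  # "more than two binding motifs"
DEFAULT_MAX_CIRCUIT_SIZE = 8


@dataclass
class TFGraph:
    """Directed TF->TF regulation graph plus the self-regulated subset."""

    counts: pd.DataFrame  # counts.loc[A, B] = A-motif hits in B's extended SE
    graph: nx.DiGraph
    self_regulated: frozenset[str]

    @property
    def nodes(self) -> list[str]:
        return list(self.counts.index)


@dataclass(frozen=True)
class Circuit:
    """A fully interconnected set of >= 2 self-regulated TFs with a score."""

    members: frozenset[str]
    score: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


def extend_regions(
    regions: Sequence[ScoredInterval],
    flank: int = DEFAULT_FLANK,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[ScoredInterval]:
    """Widen each region by ``flank`` bp on both sides, clamped to the chromosome."""
    if flank < 0:
        raise UsageError(f"flank must be >= 0, got {flank}")
    out = []
    for iv in regions:
        limit = None if chrom_lengths is None else chrom_lengths.get(iv.chrom)
        if limit is not None and iv.end > limit:
            raise UsageError(
                f"region {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {limit}"
            )
        start = max(0, iv.start - flank)
        end = iv.end + flank if limit is None else min(limit, iv.end + flank)
        out.append(ScoredInterval(iv.chrom, start, end, name=iv.name,
                                  signal=iv.signal, strand=iv.strand))
    return out


def tf_se_hit_table(
    tf_regions: Mapping[str, ScoredInterval],
    genome: Mapping[str, str],
    pwms: Sequence[Pwm],
    background: np.ndarray | None = None,
    p_threshold: float = motif_scan.DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Count motif hits of every TF in every TF's extended SE.

    Returns a square DataFrame with ``counts.loc[A, B]`` = number of A-motif
    hits (both strands, overlaps included) in B's extended SE sequence.
    TFs lacking an SE region or a motif are dropped with a warning.
    """
    pwm_by_name = {p.name: p for p in pwms}
    tfs = sorted(tf_regions)
    dropped = [t for t in tfs if t not in pwm_by_name]
    missing_seq = [
        t for t in tfs
        if t in pwm_by_name and tf_regions[t].chrom not in genome
    ]
    if dropped or missing_seq:
        warnings.warn(
            f"dropping TFs without a motif {dropped} or without sequence "
            f"{missing_seq}",
            stacklevel=2,
        )
    usable = [t for t in tfs if t not in dropped and t not in missing_seq]
    counts = pd.DataFrame(0, index=usable, columns=usable, dtype=np.int64)
    for target in usable:
        region = tf_regions[target]
        seq = genome[region.chrom][region.start:region.end]
        for source in usable:
            hits = motif_scan.scan(
                seq,
                pwm_by_name[source],
                background=background,
                p_threshold=p_threshold,
                chrom=region.chrom,
                offset=region.start,
            )
            counts.loc[source, target] = len(hits)
    return counts


def build_graph(
    counts: pd.DataFrame, self_min_hits: int = DEFAULT_SELF_MIN_HITS
) -> TFGraph:
    """Turn the hit-count table into a regulation graph.

    A->B (A != B) when counts[A][B] >= 1; A is self-regulated when its own
    extended SE holds at least ``self_min_hits`` of its own motif (default 3,
    the strict reading of "more than two").
    """
    if list(counts.index) != list(counts.columns):
        raise UsageError("hit-count table must be square over one TF list")
    g = nx.DiGraph()
    g.add_nodes_from(counts.index)
    for a in counts.index:
        for b in counts.columns:
            if a != b and counts.loc[a, b] >= 1:
                g.add_edge(a, b)
    self_reg = frozenset(
        t for t in counts.index if counts.loc[t, t] >= self_min_hits
    )
    return TFGraph(counts=counts, graph=g, self_regulated=self_reg)


def enumerate_circuits(
    tf_graph: TFGraph, max_size: int = DEFAULT_MAX_CIRCUIT_SIZE
) -> list[Circuit]:
    """All mutually regulating subsets of self-regulated TFs, size 2..max_size.

    Built by maximal-clique enumeration on the undirected projection of
    mutual edges, followed by sub-clique expansion, so the result equals a
    brute-force sweep over all subsets. Order: size descending, then
    lexicographic by member names. Cliques larger than ``max_size`` are
    truncated (their larger sub-circuits are not emitted) with a warning.
    """
    mutual = nx.Graph()
    mutual.add_nodes_from(tf_graph.self_regulated)
    for a, b in tf_graph.graph.edges:
        if (
            a in tf_graph.self_regulated
            and b in tf_graph.self_regulated
            and tf_graph.graph.has_edge(b, a)
        ):
            mutual.add_edge(a, b)

    subsets: set[frozenset[str]] = set()
    truncated = False
    for clique in nx.find_cliques(mutual):
        if len(clique) > max_size:
            truncated = True
        top = min(len(clique), max_size)
        for k in range(2, top + 1):
            for combo in combinations(sorted(clique), k):
                subsets.add(frozenset(combo))
    if truncated:
        warnings.warn(
            f"clique larger than max_size={max_size}; circuits truncated",
            stacklevel=2,
        )
    circuits = [Circuit(members=s) for s in subsets]
    circuits.sort(key=lambda c: (-c.size, c.sorted_members()))
    return circuits


def score_circuits(circuits: Sequence[Circuit]) -> list[Circuit]:
    """Score and rank circuits.

    With occ(t) = number of circuits containing TF t, a circuit's score is
    sum of occ over its members divided by its size. Ranked by score
    descending, ties by size descending then lexicographic member names.
    """
    occ: dict[str, int] = {}
    for c in circuits:
        for t in c.members:
            occ[t] = occ.get(t, 0) + 1
    scored = [
        Circuit(members=c.members, score=sum(occ[t] for t in c.members) / c.size)
        for c in circuits
    ]
    scored.sort(key=lambda c: (-c.score, -c.size, c.sorted_members()))
    return scored


def assign_tf_regions(
    landscape,
    tss,
    pwms: Sequence[Pwm],
    proximal_window: int | None = None,
) -> dict[str, ScoredInterval]:
    """Tie each motif-bearing TF to its highest-ranked assigned SE.

    SE-to-gene assignment follows the landscape's gene mapping; when several
    SEs map to a TF gene the best-ranked one wins, so every TF has exactly
    one SE region.
    """
    from . import se_calling

    kwargs = {} if proximal_window is None else {"proximal_window": proximal_window}
    assignment = se_calling.assign_genes(landscape, tss, **kwargs)
    pwm_names = {p.name for p in pwms}
    tf_region: dict[str, ScoredInterval] = {}
    for region in sorted(landscape.superenhancers, key=lambda r: r.rank):
        for gene in assignment.get(region.rank, []):
            if gene in pwm_names and gene not in tf_region:
                tf_region[gene] = region.interval
    return tf_region


def run_crc(
    landscape,
    tss,
    genome: Mapping[str, str],
    pwms: Sequence[Pwm],
    flank: int = DEFAULT_FLANK,
    self_min_hits: int = DEFAULT_SELF_MIN_HITS,
    max_size: int = DEFAULT_MAX_CIRCUIT_SIZE,
    background: np.ndarray | None = None,
    p_threshold: float = motif_scan.DEFAULT_P_THRESHOLD,
) -> tuple[TFGraph, list[Circuit], pd.DataFrame]:
    """Full CRC stage for one sample's landscape.

    Returns the TF graph, the scored circuits (ranked) and the per-TF
    connectivity table.
    """
    tf_regions = assign_tf_regions(landscape, tss, pwms)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    extended = {
        tf: extend_regions([iv], flank=flank, chrom_lengths=chrom_lengths)[0]
        for tf, iv in tf_regions.items()
    }
    counts = tf_se_hit_table(
        extended, genome, pwms, background=background, p_threshold=p_threshold
    )
    graph = build_graph(counts, self_min_hits=self_min_hits)
    circuits = score_circuits(enumerate_circuits(graph, max_size=max_size))
    table = tf_connectivity(graph, circuits)
    return graph, circuits, table


def tf_connectivity(
    tf_graph: TFGraph, circuits: Sequence[Circuit]
) -> pd.DataFrame:
    """Per-TF connectivity table: degrees, circuit membership, top-circuit flag.

    Sorted by circuit-membership count (occ) descending, then total degree
    descending — the surface on which candidate core TFs are read off.
    """
    occ = {t: 0 for t in tf_graph.nodes}
    for c in circuits:
        for t in c.members:
            occ[t] = occ.get(t, 0) + 1
    top_members: frozenset[str] = circuits[0].members if circuits else frozenset()
    rows = []
    for t in tf_graph.nodes:
        indeg = tf_graph.graph.in_degree(t) if t in tf_graph.graph else 0
        outdeg = tf_graph.graph.out_degree(t) if t in tf_graph.graph else 0
        rows.append(
            {
                "tf": t,
                "in_degree": indeg,
                "out_degree": outdeg,
                "self_regulated": t in tf_graph.self_regulated,
                "occ": occ.get(t, 0),
                "in_top_circuit": t in top_members,
            }
        )
    df = pd.DataFrame(rows)
    df["_deg"] = df.in_degree + df.out_degree
    df = df.sort_values(
        ["occ", "_deg", "tf"], ascending=[False, False, True]
    ).drop(columns="_deg")
    return df.reset_index(drop=True)
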