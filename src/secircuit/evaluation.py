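"""Recovery metrics against a synthetic cohort's ground-truth manifest.

These helpers run the pipeline stages on a :class:`~secircuit.synthetic_data.Cohort`
and score them against the planted truth: per-sample SE-call F1, whether the
anchor SE ranks first after the recurrence filter, and whether the planted
clique is recovered intact.
"""

from __future__ import annotations

import numpy as np

from . import crc_model, diffexpr_targets, recurrence, se_calling
from .genomic_io import ScoredInterval
from .se_calling import SELandscape
from .synthetic_data import Cohort

__all__ = [
    "call_all_landscapes",
    "se_call_f1",
    "anchor_ranks_first",
    "crc_recovery",
    "de_recovery",
]


def call_all_landscapes(cohort: Cohort) -> list[SELandscape]:
    """Run the SE caller on every sample of the cohort at default parameters."""
    return [
        se_calling.call_landscape(
            cohort.peaks[s], cohort.coverage[s], cohort.tss, sample_id=s
        )
        for s in cohort.sample_ids
    ]


def _planted_intervals(cohort: Cohort, sample: str) -> list[ScoredInterval]:
    out = []
    for entry in cohort.truth.recurrent_ses + cohort.truth.private_ses:
        if sample in cohort.truth.se_samples[entry["name"]]:
            out.append(ScoredInterval(entry["chrom"], entry["start"], entry["end"]))
    return out


def se_call_f1(cohort: Cohort, landscape: SELandscape) -> float:
    """F1 of called SEs vs planted SEs for one sample (>= 1 bp overlap match)."""
    planted = _planted_intervals(cohort, landscape.sample_id)
    called = [r.interval for r in landscape.superenhancers]
    if not called or not planted:
        return 0.0
    tp_called = sum(1 for c in called if any(c.overlaps(p) for p in planted))
    tp_planted = sum(1 for p in planted if any(p.overlaps(c) for c in called))
    precision = tp_called / len(called)
    recall = tp_planted / len(planted)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def anchor_ranks_first(cohort: Cohort, landscapes: list[SELandscape]) -> bool:
    """True when the planted anchor SE tops the filtered recurrence ranking."""
    consensus = recurrence.merge_landscapes(landscapes)
    matrix = recurrence.occupancy(consensus, landscapes)
    ranked = recurrence.filter_rank(matrix)
    if not ranked:
        return False
    anchor = next(
        e for e in cohort.truth.recurrent_ses if e["name"] == cohort.truth.anchor_se
    )
    top = ranked[0]
    return top.overlaps(ScoredInterval(anchor["chrom"], anchor["start"], anchor["end"]))


def crc_recovery(cohort: Cohort, landscape: SELandscape) -> dict[str, bool]:
    """Run the CRC stage on one landscape and score it against the truth.

    Returns flags: all clique TFs self-regulated, all decoys present but not
    self-regulated, top circuit equals the full planted clique, and motif hit
    counts equal to planted counts.
    """
    graph, circuits, _ = crc_model.run_crc(
        landscape, cohort.tss, cohort.genome, cohort.pwms
    )
    clique = set(cohort.truth.clique_tfs)
    decoys = set(cohort.truth.decoy_tfs)

    planted_counts: dict[tuple[str, str], int] = {}
    for rec in cohort.truth.planted_motifs:
        key = (rec["tf"], rec["target_tf"])
        planted_counts[key] = planted_counts.get(key, 0) + 1
    counts_match = all(
        graph.counts.loc[a, b] == planted_counts.get((a, b), 0)
        for a in graph.counts.index
        for b in graph.counts.columns
    )
    return {
        "clique_self_regulated": clique <= graph.self_regulated,
        "decoys_excluded": decoys.isdisjoint(graph.self_regulated)
        and decoys <= set(graph.counts.index),
        "clique_is_top_circuit": bool(circuits)
        and set(circuits[0].members) == clique,
        "counts_match_planted": counts_match,
    }


def de_recovery(cohort: Cohort) -> dict[str, float]:
    """Differential-expression power and direction concordance vs planted truth."""
    results = diffexpr_targets.de_test(cohort.counts, reference="control")
    truth = cohort.truth.de_genes
    if not truth:
        return {"power": float("nan"), "direction_accuracy": float("nan")}
    detected = [
        r for r in results if r.gene in truth and r.direction != "ns"
    ]
    power = len(detected) / len(truth)
    correct = sum(1 for r in detected if r.direction == truth[r.gene])
    accuracy = correct / len(detected) if detected else 0.0
    return {"power": power, "direction_accuracy": accuracy}
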