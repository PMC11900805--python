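import itertools

import numpy as np
import pandas as pd
import pytest

from secircuit.errors import UsageError
from secircuit.genomic_io import Pwm, ScoredInterval
from secircuit import crc_model as crc
from secircuit import motif_scan as ms


def counts_df(tfs, entries):
    df = pd.DataFrame(0, index=tfs, columns=tfs, dtype=int)
    for (a, b), v in entries.items():
        df.loc[a, b] = v
    return df


# ---------------------------------------------------------------------------
# region extension
# ---------------------------------------------------------------------------

def test_extend_regions_basic_and_clamped():
    regions = [ScoredInterval("chr1", 1000, 2000), ScoredInterval("chr1", 200, 900)]
    out = crc.extend_regions(regions, flank=500, chrom_lengths={"chr1": 10_000})
    assert (out[0].start, out[0].end) == (500, 2500)
    assert (out[1].start, out[1].end) == (0, 1400)


def test_extend_regions_flank_zero_identity():
    regions = [ScoredInterval("chr1", 1000, 2000)]
    out = crc.extend_regions(regions, flank=0, chrom_lengths={"chr1": 5000})
    assert (out[0].start, out[0].end) == (1000, 2000)


def test_extend_regions_out_of_bounds_rejected():
    with pytest.raises(UsageError, match="exceeds"):
        crc.extend_regions(
            [ScoredInterval("chr1", 1000, 6000)], chrom_lengths={"chr1": 5000}
        )


# ---------------------------------------------------------------------------
# hit table
# ---------------------------------------------------------------------------

def _sharp(word, name):
    off = 0.01
    mat = np.full((len(word), 4), off)
    for i, b in enumerate(word):
        mat[i, "ACGT".index(b)] = 0.97
    return Pwm(name, mat, pseudocount=0.0)


def test_hit_table_counts_planted_words():
    rng = np.random.default_rng(0)
    word_a, word_b = "ACGTTGCA", "GGATCCAT"
    bg = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
    # B's region carries 3 copies of A's word; A's region carries 1 of B's
    seq = list(bg)
    for pos in (1100, 1400, 1700):
        seq[pos:pos + 8] = word_a
    seq[200:208] = word_b
    genome = {"chr1": "".join(seq)}
    regions = {
        "A": ScoredInterval("chr1", 100, 1000),
        "B": ScoredInterval("chr1", 1050, 2000),
    }
    counts = crc.tf_se_hit_table(
        regions, genome, [_sharp(word_a, "A"), _sharp(word_b, "B")]
    )
    assert counts.loc["A", "B"] == 3
    assert counts.loc["B", "A"] == 1


def test_hit_table_all_n_region_contributes_zero():
    genome = {"chr1": "N" * 1000}
    regions = {"A": ScoredInterval("chr1", 100, 900)}
    counts = crc.tf_se_hit_table(regions, genome, [_sharp("ACGTACGT", "A")])
    assert counts.loc["A", "A"] == 0


def test_hit_table_drops_tf_without_pwm_with_warning():
    genome = {"chr1": "ACGT" * 300}
    regions = {
        "A": ScoredInterval("chr1", 0, 500),
        "NOPWM": ScoredInterval("chr1", 600, 1100),
    }
    with pytest.warns(UserWarning, match="NOPWM"):
        counts = crc.tf_se_hit_table(regions, genome, [_sharp("ACGTACGT", "A")])
    assert list(counts.index) == ["A"]


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def test_self_regulation_needs_more_than_two_hits():
    tfs = ["A", "B"]
    counts = counts_df(tfs, {("A", "A"): 3, ("B", "B"): 2, ("A", "B"): 1})
    g = crc.build_graph(counts)
    assert g.self_regulated == {"A"}
    assert g.graph.has_edge("A", "B")
    assert not g.graph.has_edge("B", "A")


def test_build_graph_requires_square_table():
    df = pd.DataFrame(0, index=["A", "B"], columns=["A"])
    with pytest.raises(UsageError):
        crc.build_graph(df)


# ---------------------------------------------------------------------------
# circuit enumeration
# ---------------------------------------------------------------------------

def _brute_force_circuits(tf_graph, max_size=8):
    nodes = sorted(tf_graph.self_regulated)
    out = set()
    for k in range(2, min(len(nodes), max_size) + 1):
        for combo in itertools.combinations(nodes, k):
            if all(
                tf_graph.graph.has_edge(a, b) and tf_graph.graph.has_edge(b, a)
                for a, b in itertools.combinations(combo, 2)
            ):
                out.add(frozenset(combo))
    return out


def test_triangle_yields_all_subsets():
    tfs = ["A", "B", "C"]
    entries = {(t, t): 3 for t in tfs}
    for a, b in itertools.permutations(tfs, 2):
        entries[(a, b)] = 1
    g = crc.build_graph(counts_df(tfs, entries))
    circuits = crc.enumerate_circuits(g)
    got = {c.members for c in circuits}
    assert got == {
        frozenset(s)
        for s in [("A", "B"), ("A", "C"), ("B", "C"), ("A", "B", "C")]
    }


def test_one_way_edges_exclude_node():
    tfs = ["A", "B", "D"]
    entries = {(t, t): 3 for t in tfs}
    entries[("A", "B")] = entries[("B", "A")] = 1
    entries[("D", "A")] = 1  # one-way only
    g = crc.build_graph(counts_df(tfs, entries))
    circuits = crc.enumerate_circuits(g)
    assert all("D" not in c.members for c in circuits)
    assert {c.members for c in circuits} == {frozenset(("A", "B"))}


def test_empty_self_regulated_yields_no_circuits():
    tfs = ["A", "B"]
    g = crc.build_graph(counts_df(tfs, {("A", "B"): 1, ("B", "A"): 1}))
    assert crc.enumerate_circuits(g) == []


def test_enumeration_matches_brute_force_on_random_graphs():
    """Clique-based enumeration equals the 2^n subset sweep for n <= 12."""
    rng = np.random.default_rng(5)
    for trial in range(12):
        n = int(rng.integers(4, 13))
        tfs = [f"T{i:02d}" for i in range(n)]
        entries = {}
        for t in tfs:
            entries[(t, t)] = int(rng.integers(0, 6))
        for a, b in itertools.permutations(tfs, 2):
            if rng.random() < 0.45:
                entries[(a, b)] = 1
        g = crc.build_graph(counts_df(tfs, entries))
        got = {c.members for c in crc.enumerate_circuits(g, max_size=12)}
        assert got == _brute_force_circuits(g, max_size=12)


def test_enumeration_truncates_with_warning():
    tfs = [f"T{i}" for i in range(5)]
    entries = {(t, t): 3 for t in tfs}
    for a, b in itertools.permutations(tfs, 2):
        entries[(a, b)] = 1
    g = crc.build_graph(counts_df(tfs, entries))
    with pytest.warns(UserWarning, match="truncated"):
        circuits = crc.enumerate_circuits(g, max_size=3)
    assert max(c.size for c in circuits) == 3


def test_enumeration_order_deterministic():
    tfs = ["A", "B", "C"]
    entries = {(t, t): 3 for t in tfs}
    for a, b in itertools.permutations(tfs, 2):
        entries[(a, b)] = 1
    g = crc.build_graph(counts_df(tfs, entries))
    circuits = crc.enumerate_circuits(g)
    assert [c.sorted_members() for c in circuits] == [
        ("A", "B", "C"), ("A", "B"), ("A", "C"), ("B", "C"),
    ]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def test_score_reference_example():
    """{A,B} and {A,B,C}: occ(A)=occ(B)=2, occ(C)=1 -> scores 2 and 5/3."""
    circuits = [
        crc.Circuit(frozenset(("A", "B"))),
        crc.Circuit(frozenset(("A", "B", "C"))),
    ]
    scored = crc.score_circuits(circuits)
    by_members = {c.sorted_members(): c.score for c in scored}
    assert by_members[("A", "B")] == pytest.approx(2.0)
    assert by_members[("A", "B", "C")] == pytest.approx(5 / 3)
    assert scored[0].sorted_members() == ("A", "B")


def test_single_circuit_scores_one():
    (c,) = crc.score_circuits([crc.Circuit(frozenset(("A", "B")))])
    assert c.score == 1.0


def test_duplicating_circuit_list_doubles_scores():
    base = [
        crc.Circuit(frozenset(("A", "B"))),
        crc.Circuit(frozenset(("A", "C"))),
        crc.Circuit(frozenset(("A", "B", "C"))),
    ]
    once = crc.score_circuits(base)
    twice = crc.score_circuits(base + base)
    s1 = {c.sorted_members(): c.score for c in once}
    s2 = {}
    for c in twice:
        s2[c.sorted_members()] = c.score
    for members, score in s1.items():
        assert s2[members] == pytest.approx(2 * score)
    assert [c.sorted_members() for c in once] == list(
        dict.fromkeys(c.sorted_members() for c in twice)
    )


def test_score_conservation_identity():
    """sum_C score(C)*|C| == sum_t occ(t)^2."""
    rng = np.random.default_rng(8)
    tfs = [f"T{i}" for i in range(7)]
    entries = {(t, t): 3 for t in tfs}
    for a, b in itertools.permutations(tfs, 2):
        if rng.random() < 0.5:
            entries[(a, b)] = 1
    g = crc.build_graph(counts_df(tfs, entries))
    scored = crc.score_circuits(crc.enumerate_circuits(g))
    occ = {}
    for c in scored:
        for t in c.members:
            occ[t] = occ.get(t, 0) + 1
    lhs = sum(c.score * c.size for c in scored)
    rhs = sum(v * v for v in occ.values())
    assert lhs == pytest.approx(rhs)


def test_empty_circuit_list_scores_empty():
    assert crc.score_circuits([]) == []


# ---------------------------------------------------------------------------
# connectivity table
# ---------------------------------------------------------------------------

def test_connectivity_table_ranks_by_occ():
    tfs = ["A", "B", "C", "LONER"]
    entries = {(t, t): 3 for t in tfs}
    for a, b in itertools.permutations(["A", "B", "C"], 2):
        entries[(a, b)] = 1
    g = crc.build_graph(counts_df(tfs, entries))
    circuits = crc.score_circuits(crc.enumerate_circuits(g))
    table = crc.tf_connectivity(g, circuits)
    assert table.iloc[-1]["tf"] == "LONER"
    assert table.iloc[-1]["occ"] == 0
    assert set(table[table.in_top_circuit].tf) <= {"A", "B", "C"}
    assert list(table.occ) == sorted(table.occ, reverse=True)


def test_circuits_pass_independent_pairwise_edge_check(cohort):
    from secircuit import se_calling

    s = cohort.sample_ids[0]
    ls = se_calling.call_landscape(
        cohort.peaks[s], cohort.coverage[s], cohort.tss, sample_id=s
    )
    graph, circuits, _ = crc.run_crc(ls, cohort.tss, cohort.genome, cohort.pwms)
    for c in circuits:
        assert c.members <= graph.self_regulated
        for a, b in itertools.permutations(c.members, 2):
            assert graph.graph.has_edge(a, b)
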