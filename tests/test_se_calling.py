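import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from secircuit.errors import UsageError
from secircuit.genomic_io import CoverageTrack, ScoredInterval, TssRecord
from secircuit import se_calling as se


def iv(start, end, chrom="chr1", signal=None):
    return ScoredInterval(chrom, start, end, signal=signal)


# ---------------------------------------------------------------------------
# TSS exclusion
# ---------------------------------------------------------------------------

def test_fully_contained_peak_removed():
    peaks = [iv(1000, 1500)]
    tss = [TssRecord("g", "chr1", 2000)]
    assert se.exclude_tss_peaks(peaks, tss, t=2000) == []


def test_straddling_peak_kept():
    peaks = [iv(0, 5000)]
    tss = [TssRecord("g", "chr1", 2000)]
    assert se.exclude_tss_peaks(peaks, tss, t=2000) == peaks


def test_zero_window_keeps_realistic_peaks():
    peaks = [iv(100, 700), iv(1999, 2001)]
    tss = [TssRecord("g", "chr1", 2000)]
    assert se.exclude_tss_peaks(peaks, tss, t=0) == peaks


def test_exclusion_is_chromosome_aware():
    peaks = [iv(1000, 1500, chrom="chr2")]
    tss = [TssRecord("g", "chr1", 1200)]
    assert se.exclude_tss_peaks(peaks, tss, t=2000) == peaks


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------

def test_stitch_chains_within_distance():
    regions = se.stitch([iv(0, 100), iv(5000, 5100)], s=12500)
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (0, 5100)
    assert len(regions[0].constituents) == 2


def test_stitch_respects_gap():
    regions = se.stitch([iv(0, 100), iv(20000, 20100)], s=12500)
    assert len(regions) == 2


def test_stitch_zero_merges_only_touching():
    assert len(se.stitch([iv(0, 100), iv(100, 200)], s=0)) == 1
    assert len(se.stitch([iv(0, 100), iv(101, 200)], s=0)) == 2


def _stitch_oracle(peaks, s):
    """O(n^2) transitive closure of the 'gap <= s on same chrom' relation."""
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(n):
            a, b = peaks[i], peaks[j]
            if a.chrom != b.chrom:
                continue
            gap = max(b.start - a.end, a.start - b.end)
            if gap <= s:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(peaks[i])
    spans = set()
    for members in groups.values():
        spans.add(
            (
                members[0].chrom,
                min(p.start for p in members),
                max(p.end for p in members),
            )
        )
    return spans


def test_stitch_matches_transitive_closure_oracle():
    """Sweep-line stitching equals brute-force transitive closure exactly."""
    for seed in range(50):
        rng = np.random.default_rng(seed)
        peaks = []
        for _ in range(200):
            start = int(rng.integers(0, 200_000))
            peaks.append(
                iv(start, start + int(rng.integers(1, 2000)),
                   chrom=f"chr{rng.integers(1, 4)}")
            )
        s = int(rng.integers(0, 15_000))
        got = {(r.chrom, r.start, r.end) for r in se.stitch(peaks, s)}
        assert got == _stitch_oracle(peaks, s)


def test_stitch_region_count_monotone_in_s():
    rng = np.random.default_rng(7)
    peaks = [
        iv(int(p), int(p) + 300)
        for p in np.sort(rng.integers(0, 100_000, size=60))
        if True
    ]
    counts = [len(se.stitch(peaks, s)) for s in [0, 100, 1000, 5000, 20000]]
    assert counts == sorted(counts, reverse=True)


def test_stitch_preserves_constituents():
    peaks = [iv(0, 100), iv(50, 300), iv(5000, 5100)]
    regions = se.stitch(peaks, s=1000)
    got = sorted(
        (c.start, c.end) for r in regions for c in r.constituents
    )
    assert got == sorted((p.start, p.end) for p in peaks)


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def test_quantify_is_area_integral():
    track = CoverageTrack({"chr1": [(0, 100, 2.0)]})
    (region,) = se.stitch([iv(0, 100)], s=0)
    se.quantify([region], track)
    assert region.signal == 200.0


def test_quantify_floors_control_subtraction():
    treat = CoverageTrack({"chr1": [(0, 100, 2.0)]})
    ctl = CoverageTrack({"chr1": [(0, 100, 3.0)]})
    (region,) = se.stitch([iv(0, 100)], s=0)
    se.quantify([region], treat, control=ctl)
    assert region.signal == 0.0


def test_quantify_missing_chromosome_is_zero():
    track = CoverageTrack({"chr2": [(0, 100, 2.0)]})
    (region,) = se.stitch([iv(0, 100)], s=0)
    se.quantify([region], track)
    assert region.signal == 0.0


# ---------------------------------------------------------------------------
# cutoff
# ---------------------------------------------------------------------------

def _brute_force_elbow(signals):
    s = np.sort(np.asarray(signals, float))
    x = np.arange(len(s)) / (len(s) - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    diffs = x - y
    best = max(range(len(s)), key=lambda i: (diffs[i], i))
    return s[best]


def _regions_with_signals(signals):
    out = []
    for k, sig in enumerate(signals):
        r = se.StitchedRegion(interval=iv(1000 * k, 1000 * k + 500))
        r.signal = float(sig)
        out.append(r)
    return out


def test_elbow_on_reference_vector():
    """[0,1,2,30]: cutoff at signal 2, only the 30 becomes a super."""
    signals = [0, 1, 2, 30]
    assert _brute_force_elbow(signals) == 2  # oracle agrees
    landscape = se.call_superenhancers(_regions_with_signals(signals))
    assert landscape.cutoff_signal == 2
    assert [r.signal for r in landscape.superenhancers] == [30]


def test_membership_invariant_under_positive_rescaling():
    rng = np.random.default_rng(3)
    signals = rng.gamma(2.0, 50.0, size=40)
    base = se.call_superenhancers(_regions_with_signals(signals))
    ids_base = {(r.start, r.is_super) for r in base.regions}
    for c in (0.01, 3.5, 1e4):
        scaled = se.call_superenhancers(_regions_with_signals(signals * c))
        assert {(r.start, r.is_super) for r in scaled.regions} == ids_base


def test_linear_ramp_ties_break_to_fewest_supers():
    signals = [10, 20, 30, 40, 50]
    landscape = se.call_superenhancers(_regions_with_signals(signals))
    assert landscape.cutoff_signal == _brute_force_elbow(signals) == 50
    assert landscape.superenhancers == []


def test_cutoff_strictly_between_min_and_max():
    rng = np.random.default_rng(5)
    for _ in range(20):
        signals = rng.gamma(1.5, 30.0, size=25)
        landscape = se.call_superenhancers(_regions_with_signals(signals))
        assert signals.min() <= landscape.cutoff_signal < signals.max()
        for s_reg in landscape.superenhancers:
            for t_reg in landscape.typical:
                assert s_reg.signal > t_reg.signal


def test_degenerate_signals_rejected():
    with pytest.raises(UsageError, match="degenerate"):
        se.call_superenhancers(_regions_with_signals([5, 5, 5]))


def test_ranks_are_permutation():
    rng = np.random.default_rng(9)
    landscape = se.call_superenhancers(
        _regions_with_signals(rng.uniform(1, 100, size=15))
    )
    assert sorted(r.rank for r in landscape.regions) == list(range(1, 16))


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------

def _landscape_one_se(start, end):
    regions = _regions_with_signals([1, 2, 100])
    regions[2] = se.StitchedRegion(interval=iv(start, end))
    regions[2].signal = 100.0
    return se.call_superenhancers(regions)


def test_tss_inside_se_assigned():
    ls = _landscape_one_se(10_000, 20_000)
    genes = se.assign_genes(ls, [TssRecord("GENE_IN", "chr1", 15_000)])
    (se_rank,) = [r.rank for r in ls.superenhancers]
    assert genes[se_rank] == ["GENE_IN"]


def test_nearest_tss_within_window_assigned():
    ls = _landscape_one_se(10_000, 20_000)
    genes = se.assign_genes(
        ls,
        [TssRecord("NEAR", "chr1", 30_000), TssRecord("FAR", "chr1", 45_000)],
    )
    (se_rank,) = [r.rank for r in ls.superenhancers]
    assert genes[se_rank] == ["NEAR"]


def test_no_tss_within_window_empty():
    ls = _landscape_one_se(10_000, 20_000)
    genes = se.assign_genes(ls, [TssRecord("FAR", "chr1", 100_001)])
    (se_rank,) = [r.rank for r in ls.superenhancers]
    assert genes[se_rank] == []
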