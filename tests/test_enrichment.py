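"""Enrichment ratio, randomization null, Monte Carlo p-values, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromenrich import (
    BinPartition,
    GenomeLayout,
    GenomicInterval,
    NullModelConfig,
    PreconditionError,
    SegmentTrack,
    UndefinedRatioError,
    bh_fdr,
    coverage_fraction,
    enrichment_ratio,
    mc_pvalue,
    randomize_track,
    global_overlap_test,
    local_overlap_test,
)
from conftest import per_base, random_track


# ---------------------------------------------------------------------------
# Coverage fraction and enrichment ratio
# ---------------------------------------------------------------------------


def test_coverage_fraction_examples(layout_1kb):
    bin_ = [GenomicInterval("chrA", 0, 100)]
    ref = SegmentTrack(layout_1kb, [GenomicInterval("chrA", 0, 20)], "ref")
    query = SegmentTrack(layout_1kb, [GenomicInterval("chrA", 5, 25)], "q")
    assert coverage_fraction(ref, query, bin_) == pytest.approx(15 / 20)
    saturating = SegmentTrack(layout_1kb, [GenomicInterval("chrA", 0, 100)], "q")
    assert coverage_fraction(ref, saturating, bin_) == 1.0
    empty_ref = SegmentTrack(layout_1kb, [], "ref")
    with pytest.raises(UndefinedRatioError):
        coverage_fraction(empty_ref, query, bin_)


def test_enrichment_ratio_examples(layout_1kb):
    bin_ = [GenomicInterval("chrA", 0, 100)]
    state = SegmentTrack(layout_1kb, [GenomicInterval("chrA", 0, 10)], "S")
    query = SegmentTrack(layout_1kb, [GenomicInterval("chrA", 0, 20)], "q")
    # (10/10) / (10/90) = 9
    assert enrichment_ratio(state, query, bin_) == pytest.approx(9.0)
    whole = SegmentTrack(layout_1kb, [GenomicInterval("chrA", 0, 100)], "q")
    assert enrichment_ratio(state, whole, bin_) == pytest.approx(1.0)
    disjoint = SegmentTrack(layout_1kb, [GenomicInterval("chrA", 50, 60)], "q")
    assert enrichment_ratio(state, disjoint, bin_) == 0.0
    inside_only = SegmentTrack(layout_1kb, [GenomicInterval("chrA", 2, 8)], "q")
    with pytest.raises(UndefinedRatioError):
        enrichment_ratio(state, inside_only, bin_)  # complement uncovered


def test_enrichment_is_one_under_proportional_coverage(layout_1kb):
    """Query covering the same fraction of state and complement -> ratio 1."""
    bin_ = [GenomicInterval("chrA", 0, 1000)]
    state = SegmentTrack(layout_1kb, [GenomicInterval("chrA", 0, 200)], "S")
    # query covers 50% of the state (0-100) and 50% of the complement (200-600)
    query = SegmentTrack(
        layout_1kb,
        [GenomicInterval("chrA", 0, 100), GenomicInterval("chrA", 200, 600)],
        "q",
    )
    assert enrichment_ratio(state, query, bin_) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Monte Carlo p-values
# ---------------------------------------------------------------------------


def test_mc_pvalue_convention():
    assert mc_pvalue(4, [1, 2, 3]) == pytest.approx(1 / 3)  # floor at 1/N
    assert mc_pvalue(2, [1, 2, 3]) == pytest.approx(2 / 3)  # tie is extreme
    with pytest.raises(PreconditionError):
        mc_pvalue(1, [])


@settings(max_examples=100, derandomize=True)
@given(
    samples=st.lists(st.integers(0, 50), min_size=1, max_size=60),
    obs=st.lists(st.integers(0, 50), min_size=2, max_size=2),
)
def test_mc_pvalue_monotone_in_observed(samples, obs):
    lo, hi = min(obs), max(obs)
    assert mc_pvalue(hi, samples) <= mc_pvalue(lo, samples)


# ---------------------------------------------------------------------------
# Randomization null
# ---------------------------------------------------------------------------


def test_randomize_single_segment_has_no_freedom(layout_1kb):
    track = SegmentTrack(layout_1kb, [GenomicInterval("chrA", 0, 10)], "S")
    bin_ = [GenomicInterval("chrA", 0, 10)]
    for seed in range(5):
        rng = np.random.default_rng(seed)
        out = randomize_track(track, bin_, rng)
        assert [(iv.start, iv.end) for iv in out.intervals] == [(0, 10)]


def test_randomize_conserves_lengths_gaps_and_coverage(layout_1kb):
    rng = np.random.default_rng(30)
    bin_ = [GenomicInterval("chrA", 0, 1000)]
    for _ in range(200):
        track = random_track(rng, layout_1kb, label="S")
        out = randomize_track(track, bin_, rng)
        s0, e0 = track.arrays("chrA")
        s1, e1 = out.arrays("chrA")
        assert sorted(e0 - s0) == sorted(e1 - s1)
        assert out.covered_bp() == track.covered_bp()
        # gap multiset (with flanks) conserved too
        def gaps(s, e):
            if len(s) == 0:
                return [1000]
            return sorted(
                [int(s[0])] + list(map(int, s[1:] - e[:-1])) + [1000 - int(e[-1])]
            )
        assert gaps(s0, e0) == gaps(s1, e1)


def test_randomize_rejects_boundary_spanning_segments(layout_1kb):
    track = SegmentTrack(layout_1kb, [GenomicInterval("chrA", 90, 110)], "S")
    rng = np.random.default_rng(0)
    with pytest.raises(PreconditionError):
        randomize_track(track, [GenomicInterval("chrA", 0, 100)], rng)


def test_randomize_confined_within_each_bin_region(layout_1kb):
    track = SegmentTrack(
        layout_1kb,
        [GenomicInterval("chrA", 10, 30), GenomicInterval("chrA", 500, 520)],
        "S",
    )
    bins = [GenomicInterval("chrA", 0, 100), GenomicInterval("chrA", 450, 600)]
    rng = np.random.default_rng(7)
    for _ in range(50):
        out = randomize_track(track, bins, rng)
        (s, e) = out.arrays("chrA")
        assert len(s) == 2
        assert 0 <= s[0] and e[0] <= 100
        assert 450 <= s[1] and e[1] <= 600


# ---------------------------------------------------------------------------
# Global and local tests
# ---------------------------------------------------------------------------


def _dense_state(layout):
    # irregular segment/gap geometry so the permutation null is non-degenerate
    pairs = [(0, 55), (90, 120), (180, 260), (300, 310), (420, 490),
             (530, 640), (700, 705), (780, 860), (900, 930), (960, 985)]
    return SegmentTrack(layout, [GenomicInterval("chrA", s, e) for s, e in pairs], "S")


def test_identical_dense_tracks_give_floor_p(layout_1kb):
    state = _dense_state(layout_1kb)
    # query = state plus a sliver of the complement (so enrichment is defined)
    query = SegmentTrack(
        layout_1kb, state.intervals + [GenomicInterval("chrA", 60, 70)], "q"
    )
    cfg = NullModelConfig(n_samples=200, seed=5)
    r = global_overlap_test(state, query, cfg)
    assert r.observed == state.covered_bp()  # maximal achievable overlap
    assert r.p_value == pytest.approx(1 / 200)


def test_single_bin_partition_matches_global(layout_1kb):
    state = _dense_state(layout_1kb)
    rng = np.random.default_rng(8)
    query = SegmentTrack(
        layout_1kb,
        [GenomicInterval("chrA", int(p), int(p) + 40) for p in rng.integers(0, 950, 6)],
        "q",
    )
    cfg = NullModelConfig(n_samples=300, seed=11)
    bins = BinPartition.whole_genome(layout_1kb, bin_id="genome")
    (local_result,) = local_overlap_test(state, query, bins, cfg)
    global_result = global_overlap_test(state, query, cfg)
    assert local_result.observed == global_result.observed
    assert local_result.p_value == global_result.p_value
    assert local_result.enrichment == pytest.approx(global_result.enrichment)


def test_local_excludes_bins_without_query(layout_2chrom):
    state = SegmentTrack(
        layout_2chrom,
        [GenomicInterval("chrA", 100, 150), GenomicInterval("chrB", 100, 150)],
        "S",
    )
    query = SegmentTrack(layout_2chrom, [GenomicInterval("chrA", 120, 200)], "q")
    bins = BinPartition(
        bins=(
            ("chrAq", (GenomicInterval("chrA", 0, 1000),)),
            ("chrBq", (GenomicInterval("chrB", 0, 600),)),
        )
    )
    results = local_overlap_test(state, query, bins, NullModelConfig(n_samples=50, seed=1))
    assert [r.bin_id for r in results] == ["chrAq"]  # chrB excluded, not p=1


def test_local_flags_only_the_planted_bin(layout_2chrom):
    """Enrichment planted on chrA only; chrB stays null."""
    rng = np.random.default_rng(41)

    def irregular(chrom, length, n, rng):
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n, replace=False))
        return [
            GenomicInterval(chrom, int(cuts[2 * i]), int(cuts[2 * i + 1]))
            for i in range(n)
        ]

    state_ivs = irregular("chrA", 1000, 8, rng) + irregular("chrB", 600, 8, rng)
    state = SegmentTrack(layout_2chrom, state_ivs, "S")
    # chrA query sits exactly on the state segments; chrB query is random
    query_ivs = [iv for iv in state_ivs if iv.chrom == "chrA"]
    query_ivs += [
        GenomicInterval("chrB", int(p), int(p) + 15) for p in rng.integers(0, 580, 4)
    ]
    query = SegmentTrack(layout_2chrom, query_ivs, "q")
    bins = BinPartition(
        bins=(
            ("chrAq", (GenomicInterval("chrA", 0, 1000),)),
            ("chrBq", (GenomicInterval("chrB", 0, 600),)),
        )
    )
    results = local_overlap_test(
        state, query, bins, NullModelConfig(n_samples=400, seed=2), fdr_q=0.10
    )
    by_bin = {r.bin_id: r for r in results}
    assert by_bin["chrAq"].fdr_significant
    assert by_bin["chrAq"].p_value <= 0.01


def test_results_are_deterministic_for_fixed_seed(layout_1kb):
    state = _dense_state(layout_1kb)
    query = SegmentTrack(layout_1kb, [GenomicInterval("chrA", 30, 400)], "q")
    cfg = NullModelConfig(n_samples=100, seed=99)
    r1 = global_overlap_test(state, query, cfg)
    r2 = global_overlap_test(state, query, cfg)
    assert (r1.p_value, r1.null_mean, r1.null_sd) == (r2.p_value, r2.null_mean, r2.null_sd)


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------


def _bh_reference(ps, q):
    """Independent step-up implementation used as oracle."""
    ps = np.asarray(ps, dtype=float)
    m = ps.size
    order = np.argsort(ps, kind="stable")
    sorted_p = ps[order]
    thresh = q * (np.arange(1, m + 1)) / m
    below = np.flatnonzero(sorted_p <= thresh)
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject.tolist()


def test_bh_fdr_examples():
    assert bh_fdr([0.01, 0.02, 0.2], q=0.1) == [True, True, False]
    assert bh_fdr([1.0, 1.0, 1.0], q=0.1) == [False, False, False]
    assert bh_fdr([], q=0.1) == []


def test_bh_fdr_matches_reference_step_up():
    rng = np.random.default_rng(55)
    for _ in range(1000):
        m = int(rng.integers(1, 40))
        ps = rng.uniform(1e-6, 1.0, size=m)
        if rng.random() < 0.3:  # inject signal
            ps[: m // 2] *= 1e-3
        q = float(rng.choice([0.01, 0.05, 0.10, 0.25]))
        assert bh_fdr(ps.tolist(), q) == _bh_reference(ps, q)
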