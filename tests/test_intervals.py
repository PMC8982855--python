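import numpy as np
import pandas as pd
import pytest

from ovatools.intervals import (
    Workspace,
    annotate_tss,
    bin_coverage,
    density_profile,
    merge_intervals,
    randomized_overlap_enrichment,
    subtract_portion,
    subtract_whole,
)
from ovatools.io import GeneModel, GenomicInterval


def _iv(start, end, chrom="c", **kw):
    return GenomicInterval(chrom, start, end, **kw)


def _base_set(intervals):
    out = set()
    for iv in intervals:
        out |= {(iv.chrom, b) for b in range(iv.start, iv.end)}
    return out


def _random_intervals(rng, n, span=10_000, chroms=("c1", "c2")):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span - 1))
        e = int(rng.integers(s + 1, min(s + 500, span) + 1))
        out.append(GenomicInterval(str(rng.choice(chroms)), s, e))
    return out


class TestMerge:
    def test_overlapping_merge(self):
        out = merge_intervals([_iv(0, 10), _iv(5, 15)])
        assert [(p.start, p.end) for p in out] == [(0, 15)]

    def test_book_ended_merge(self):
        out = merge_intervals([_iv(0, 10), _iv(10, 20)])
        assert [(p.start, p.end) for p in out] == [(0, 20)]

    def test_scores_max_aggregated(self):
        out = merge_intervals([_iv(0, 10, score=2.0), _iv(5, 15, score=7.0)])
        assert out[0].score == 7.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ivs = _random_intervals(rng, 50)
        once = merge_intervals(ivs)
        twice = merge_intervals(once)
        assert [(p.chrom, p.start, p.end) for p in once] == [
            (p.chrom, p.start, p.end) for p in twice
        ]

    def test_base_set_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            ivs = _random_intervals(rng, int(rng.integers(1, 20)))
            merged = merge_intervals(ivs)
            assert _base_set(merged) == _base_set(ivs)
            # minimality: merged intervals are disjoint and non-adjacent
            by_chrom = {}
            for p in merged:
                by_chrom.setdefault(p.chrom, []).append(p)
            for ps in by_chrom.values():
                for a, b in zip(ps, ps[1:]):
                    assert a.end < b.start


class TestSubtract:
    def test_whole_peak_removed_on_any_overlap(self):
        out = subtract_whole([_iv(100, 200)], [_iv(150, 160)])
        assert out == []

    def test_portion_mode_splits(self):
        out = subtract_portion([_iv(100, 200)], [_iv(150, 160)])
        assert [(p.start, p.end) for p in out] == [(100, 150), (160, 200)]

    def test_empty_blacklist_is_identity(self):
        ivs = [_iv(100, 200), _iv(300, 400)]
        assert subtract_whole(ivs, []) == ivs
        assert [(p.start, p.end) for p in subtract_portion(ivs, [])] == [
            (100, 200), (300, 400)
        ]

    def test_portion_base_set_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            peaks = _random_intervals(rng, int(rng.integers(1, 10)))
            black = _random_intervals(rng, int(rng.integers(0, 10)))
            out = subtract_portion(peaks, black)
            assert _base_set(out) == _base_set(peaks) - _base_set(black)

    def test_whole_mode_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            peaks = _random_intervals(rng, int(rng.integers(1, 10)))
            black = _random_intervals(rng, int(rng.integers(0, 10)))
            out = subtract_whole(peaks, black)
            bl = _base_set(black)
            expected = [p for p in peaks if not (_base_set([p]) & bl)]
            assert out == expected


class TestAnnotateTss:
    def test_hand_computed_distance(self):
        # peak [900,1200), TSS 2000 (+): bound, distance -801
        ann = annotate_tss([_iv(900, 1200)], [GeneModel("g", "c", 2000, 3000, "+")])
        assert bool(ann.loc["g", "bound"])
        assert ann.loc["g", "distance"] == -801

    def test_no_peaks_no_bound_genes(self):
        ann = annotate_tss([], [GeneModel("g", "c", 2000, 3000, "+")])
        assert not ann["bound"].any()

    def test_minus_strand_sign_flip(self):
        # gene on -, TSS 2999; peak downstream in genome coords is 5' of TSS
        ann = annotate_tss([_iv(3200, 3300)], [GeneModel("g", "c", 2000, 3000, "-")])
        assert ann.loc["g", "distance"] == -(3200 - 2999)

    def test_window_nestedness(self):
        rng = np.random.default_rng(4)
        peaks = _random_intervals(rng, 40, span=100_000, chroms=("c",))
        genes = [
            GeneModel(f"g{i}", "c", int(s), int(s) + 1000,
                      "+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(rng.integers(0, 99_000, 60))
        ]
        prev = set()
        for w in (100, 500, 1000, 5000):
            ann = annotate_tss(peaks, genes, window=w)
            bound = set(ann.index[ann["bound"]])
            assert prev <= bound
            prev = bound

    def test_brute_force_distance_oracle(self):
        rng = np.random.default_rng(5)
        span = 50_000
        peaks = _random_intervals(rng, 25, span=span, chroms=("c",))
        genes = [
            GeneModel(f"g{i}", "c", int(s), int(s) + 500,
                      "+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(rng.integers(0, span - 500, 40))
        ]
        ann = annotate_tss(peaks, genes, window=1000)
        for g in genes:
            tss = g.tss
            # oracle: distance to nearest covered base, sign by strand side
            best = None
            for p in peaks:
                if p.start <= tss < p.end:
                    best = 0
                    break
                gap = (tss - (p.end - 1)) if p.end <= tss else (p.start - tss)
                if best is None or gap < abs(best):
                    upstream_genome = p.end <= tss
                    five_prime = upstream_genome == (g.strand == "+")
                    best = -gap if five_prime else gap
            assert ann.loc[g.gene_id, "distance"] == best
            assert bool(ann.loc[g.gene_id, "bound"]) == any(
                p.start < tss + 1001 and p.end > tss - 1000 for p in peaks
            )


class TestDensityProfile:
    def test_anchor_count_conservation(self):
        rng = np.random.default_rng(6)
        genes = [GeneModel("g", "c", 10_000, 12_000, "+")]
        peaks = [
            _iv(int(p), int(p) + 200, summit_offset=100)
            for p in rng.integers(8000, 12_000, 30)
        ]
        prof = density_profile(peaks, genes, flank=2000, bin_size=50)
        in_window = sum(
            1 for p in peaks if -2000 <= (p.summit - 10_000) < 2000
        )
        assert prof["count"].sum() == in_window
        assert prof["frequency"].sum() == pytest.approx(1.0)

    def test_minus_strand_orientation(self):
        # peak summit 150 bp 5' of a minus-strand TSS sits at tss + 150 in
        # genome coordinates and must fall in the -150 bin
        g = GeneModel("g", "c", 5000, 8000, "-")  # tss = 7999
        peak = _iv(8099, 8199, summit_offset=50)  # summit 8149 = tss + 150
        prof = density_profile([peak], [g], flank=2000, bin_size=50)
        hit = prof[prof["count"] > 0]
        assert len(hit) == 1
        assert hit["bin_start"].iloc[0] == -150

    def test_flank_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            density_profile([], [], flank=1000, bin_size=33)

    def test_summit_anchor_requires_summits(self):
        g = GeneModel("g", "c", 1000, 2000, "+")
        with pytest.raises(ValueError, match="summit"):
            density_profile([_iv(900, 1100)], [g], anchor="summit")
        prof = density_profile([_iv(900, 1100)], [g], anchor="midpoint")
        assert prof["count"].sum() == 1


class TestBinCoverage:
    def test_half_covered_bin(self):
        ws = Workspace({"c": 100_000})
        cov = bin_coverage([_iv(0, 50_000)], ws, bin_size=100_000)
        assert cov["pct_covered"].iloc[0] == pytest.approx(50.0)

    def test_partial_final_bin_normalized(self):
        ws = Workspace({"c": 150_000})
        cov = bin_coverage([_iv(100_000, 150_000)], ws, bin_size=100_000)
        assert cov["pct_covered"].iloc[1] == pytest.approx(100.0)

    def test_overlapping_peaks_count_once(self):
        ws = Workspace({"c": 10_000})
        cov = bin_coverage([_iv(0, 6000), _iv(4000, 8000)], ws, bin_size=10_000)
        assert cov["pct_covered"].iloc[0] == pytest.approx(80.0)

    def test_clipping_warns(self):
        ws = Workspace({"c": 1000})
        with pytest.warns(UserWarning, match="clipped"):
            cov = bin_coverage([_iv(500, 2000)], ws, bin_size=1000)
        assert cov["pct_covered"].iloc[0] == pytest.approx(50.0)

    def test_base_set_oracle(self):
        rng = np.random.default_rng(7)
        ws = Workspace({"c1": 10_000, "c2": 10_000})
        for _ in range(100):
            peaks = _random_intervals(rng, int(rng.integers(1, 15)))
            cov = bin_coverage(peaks, ws, bin_size=1000)
            bases = _base_set(peaks)
            for row in cov.itertuples():
                covered = sum(
                    1 for b in range(row.bin_start, row.bin_end)
                    if (row.chrom, b) in bases
                )
                expected = 100 * covered / (row.bin_end - row.bin_start)
                assert row.pct_covered == pytest.approx(expected)


class TestRandomizedOverlap:
    def test_closed_form_expectation(self):
        W, L, M = 1_000_000, 1000, 5000
        ws = Workspace({"c": W})
        res = randomized_overlap_enrichment(
            [_iv(0, L)], [_iv(400_000, 400_000 + M)], ws, n_sims=10_000, seed=5
        )
        se = res.sim_overlaps.std(ddof=1) / np.sqrt(res.n_sims)
        assert abs(res.expected_overlap - L * M / W) <= 3 * se

    def test_reference_covering_workspace_saturates(self):
        ws = Workspace({"c": 100_000})
        q = [_iv(10, 500), _iv(5000, 6000)]
        res = randomized_overlap_enrichment(q, [_iv(0, 100_000)], ws,
                                            n_sims=200, seed=1)
        assert res.fold_enrichment == pytest.approx(1.0)
        assert res.empirical_p == pytest.approx(1.0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(8)
        ws = Workspace({"c1": 50_000, "c2": 50_000})
        q = _random_intervals(rng, 10, span=50_000)
        r = _random_intervals(rng, 10, span=50_000)
        a = randomized_overlap_enrichment(q, r, ws, n_sims=300, seed=9)
        b = randomized_overlap_enrichment(q, r, ws, n_sims=300, seed=9)
        assert a.expected_overlap == b.expected_overlap
        assert a.empirical_p == b.empirical_p

    def test_clustered_self_comparison_enriched(self):
        # clustered peaks overlap themselves far more than uniform placement
        ws = Workspace({"c": 1_000_000})
        q = [_iv(1000 + 600 * i, 1500 + 600 * i) for i in range(20)]
        res = randomized_overlap_enrichment(q, q, ws, n_sims=300, seed=2)
        assert res.fold_enrichment > 1.0
        assert res.empirical_p < 0.05

    def test_oversized_interval_rejected(self):
        ws = Workspace({"c": 1000})
        with pytest.raises(ValueError, match="longer"):
            randomized_overlap_enrichment([_iv(0, 2000)], [], ws, n_sims=100)

    def test_small_n_sims_warns(self):
        ws = Workspace({"c": 10_000})
        with pytest.warns(UserWarning, match="n_sims"):
            randomized_overlap_enrichment([_iv(0, 10)], [_iv(50, 60)], ws,
                                          n_sims=10, seed=0)

    def test_excluded_regions_avoided(self):
        ws = Workspace(
            {"c": 100_000},
            excluded=(GenomicInterval("c", 0, 90_000),),
        )
        res = randomized_overlap_enrichment(
            [_iv(95_000, 95_100)], [_iv(0, 90_000)], ws, n_sims=200, seed=3
        )
        assert res.expected_overlap == 0.0
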