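"""Overlap primitives, binned chi-squared and peak-to-gene annotation."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wtct import (
    GenomicInterval,
    Peak,
    StateSegment,
    annotate_peaks_to_genes,
    intersect_sets,
    overlap_chi2,
    overlaps,
    stratify_by_states,
)

from conftest import make_gene, make_peak, random_genes, random_peaks


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestOverlaps:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (iv("chr1", 0, 10), iv("chr1", 9, 20), True),  # 1 bp shared
            (iv("chr1", 0, 10), iv("chr1", 10, 20), False),  # abutting
            (iv("chr1", 5, 6), iv("chr2", 0, 100), False),  # other chrom
            (iv("chr1", 0, 100), iv("chr1", 40, 60), True),  # containment
        ],
    )
    def test_one_bp_rule(self, a, b, expected):
        assert overlaps(a, b) is expected
        assert overlaps(b, a) is expected

    @given(
        s1=st.integers(0, 500), l1=st.integers(1, 100),
        s2=st.integers(0, 500), l2=st.integers(1, 100),
    )
    def test_symmetric_and_matches_interval_arithmetic(self, s1, l1, s2, l2):
        a, b = iv("chr1", s1, s1 + l1), iv("chr1", s2, s2 + l2)
        shared = min(a.end, b.end) - max(a.start, b.start)
        assert overlaps(a, b) == (shared >= 1) == overlaps(b, a)


class TestIntersectSets:
    def test_identical_sets_fully_shared(self, rng):
        peaks = random_peaks(rng, 30)
        res = intersect_sets(peaks, peaks)
        assert res.shared_a == len(peaks) and res.unique_a == 0
        assert res.shared_b == len(peaks) and res.unique_b == 0

    def test_disjoint_sets_share_nothing(self):
        a = [make_peak(start=0, end=10, name="a1")]
        b = [make_peak(start=100, end=110, name="b1")]
        res = intersect_sets(a, b)
        assert (res.shared_a, res.shared_b) == (0, 0)
        assert res.pairs == ()

    def test_asymmetric_counts(self):
        a = [make_peak(start=0, end=10, name="a1"),
             make_peak(start=100, end=110, name="a2")]
        b = [make_peak(start=5, end=15, name="b1")]
        res = intersect_sets(a, b)
        assert (res.shared_a, res.unique_a) == (1, 1)
        assert (res.shared_b, res.unique_b) == (1, 0)

    def test_agrees_with_bruteforce_and_is_symmetric(self, rng):
        for _ in range(10):
            a = random_peaks(rng, 40, chrom_len=20_000, prefix="a")
            b = random_peaks(rng, 40, chrom_len=20_000, prefix="b")
            res = intersect_sets(a, b)
            expected = {
                (pa.name, pb.name)
                for pa in a for pb in b
                if overlaps(pa.interval, pb.interval)
            }
            assert set(res.pairs) == expected
            flipped = intersect_sets(b, a)
            assert set(flipped.pairs) == {(y, x) for x, y in expected}
            assert (flipped.shared_a, flipped.shared_b) == (
                res.shared_b, res.shared_a
            )


class TestOverlapChi2:
    UNIVERSE = {"chr1": 1000}

    def test_hand_built_two_by_two(self):
        # A covers bins 0-19, B covers bins 10-29 of 100 ten-bp bins:
        # both=10, a_only=10, b_only=10, neither=70
        a = [make_peak(start=0, end=200, name="a")]
        b = [make_peak(start=100, end=300, name="b")]
        res = overlap_chi2(a, b, self.UNIVERSE, bin_size=10)
        assert (res.both, res.a_only, res.b_only, res.neither) == (10, 10, 10, 70)
        assert res.chi2 == pytest.approx(14.0625)
        assert res.total == 100

    def test_statistic_symmetric_in_sets(self, rng):
        a = random_peaks(rng, 30, chrom_len=100_000)
        b = random_peaks(rng, 30, chrom_len=100_000)
        universe = {"chr1": 100_000, "chr2": 100_000}
        r1 = overlap_chi2(a, b, universe, bin_size=500)
        r2 = overlap_chi2(b, a, universe, bin_size=500)
        assert r1.chi2 == pytest.approx(r2.chi2)
        assert r1.p == pytest.approx(r2.p)
        assert (r1.a_only, r1.b_only) == (r2.b_only, r2.a_only)

    def test_counts_sum_to_genome_bins(self, rng):
        a = random_peaks(rng, 20, chrom_len=99_999)
        b = random_peaks(rng, 20, chrom_len=99_999)
        universe = {"chr1": 99_999, "chr2": 99_999}
        res = overlap_chi2(a, b, universe, bin_size=1000)
        assert res.total == 2 * 100  # ceil(99999/1000) per chromosome

    def test_identical_sets_maximal_association(self):
        a = [make_peak(start=i * 50, end=i * 50 + 20, name=f"p{i}")
             for i in range(12)]
        res = overlap_chi2(a, a, self.UNIVERSE, bin_size=10)
        assert res.p < 1e-4

    def test_zero_marginal_reports_p_one(self, caplog):
        a = [make_peak(start=0, end=10, name="a")]
        with caplog.at_level("WARNING", logger="wtct.intervals"):
            res = overlap_chi2(a, [], self.UNIVERSE, bin_size=10)
        assert res.p == 1.0 and res.chi2 == 0.0

    def test_peak_outside_universe_rejected(self):
        a = [make_peak(start=0, end=2000, name="a")]
        with pytest.raises(ValueError, match="beyond"):
            overlap_chi2(a, a, self.UNIVERSE, bin_size=10)


class TestAnnotate:
    def test_distance_and_boundary(self):
        gene = make_gene("G1", start=50_000, end=52_000, strand="+")
        linked = make_peak(start=115_000, end=125_000, name="in")  # mid 120k
        too_far = make_peak(start=150_500, end=151_500, name="out")  # mid 151k
        links = annotate_peaks_to_genes([linked, too_far], [gene])
        assert [(l.peak_name, l.distance) for l in links] == [("in", 70_000.0)]

    def test_peak_links_to_multiple_genes(self):
        peak = make_peak(start=99_500, end=100_500, name="pk")  # mid 100k
        genes = [
            make_gene("G1", start=30_000, end=32_000),
            make_gene("G2", start=150_000, end=152_000),
        ]
        links = annotate_peaks_to_genes([peak], genes)
        assert sorted(l.gene_id for l in links) == ["G1", "G2"]

    def test_agrees_with_bruteforce_double_loop(self, rng):
        peaks = random_peaks(rng, 120, chrom_len=600_000)
        genes = random_genes(rng, 80, chrom_len=600_000)
        got = {
            (l.gene_id, l.peak_name, l.distance)
            for l in annotate_peaks_to_genes(peaks, genes, window=100_000)
        }
        expected = set()
        for g in genes:
            for p in peaks:
                if p.interval.chrom != g.interval.chrom:
                    continue
                d = abs(p.interval.midpoint - g.tss)
                if d <= 100_000:
                    expected.add((g.gene_id, p.name, d))
        assert got == expected

    def test_gene_on_empty_chromosome_gets_no_links(self):
        gene = make_gene("G1", chrom="chr9")
        assert annotate_peaks_to_genes([make_peak()], [gene]) == []


class TestStratify:
    SEGS = [
        StateSegment(iv("chr1", 0, 1000), "Active Enhancer"),
        StateSegment(iv("chr1", 1000, 2000), "Quiescent"),
    ]

    def test_peak_inside_single_state(self):
        peak = make_peak(start=100, end=200)
        out = stratify_by_states([peak], self.SEGS)
        assert out == {"Active Enhancer": [peak]}

    def test_peak_spanning_two_states_appears_in_both(self):
        peak = make_peak(start=900, end=1100)
        out = stratify_by_states([peak], self.SEGS)
        assert out["Active Enhancer"] == [peak]
        assert out["Quiescent"] == [peak]

    def test_empty_segmentation_all_unassigned(self):
        peak = make_peak()
        assert stratify_by_states([peak], []) == {"unassigned": [peak]}

    def test_peak_beyond_segments_unassigned(self):
        peak = make_peak(start=5000, end=5100)
        out = stratify_by_states([peak], self.SEGS)
        assert out == {"unassigned": [peak]}

    def test_overlapping_segments_rejected(self):
        bad = self.SEGS + [StateSegment(iv("chr1", 500, 1500), "Promoter")]
        with pytest.raises(ValueError, match="overlapping segments"):
            stratify_by_states([make_peak()], bad)
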