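"""wt-C-T scoring: weights, per-gene scores, rank-sum comparison, BH."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wtct import (
    DEGRecord,
    GenomicInterval,
    Peak,
    PeakGeneLink,
    StateSegment,
    bh_adjust,
    compare_wtct,
    peak_weight,
    wtct_gene_score,
    wtct_table,
)

from conftest import make_gene, make_peak, random_degs, random_genes, random_peaks


class TestPeakWeight:
    def test_decay_at_tss_and_window_edge(self):
        assert peak_weight(0, "weighted", 100_000) == pytest.approx(
            math.exp(-0.5)
        )
        assert peak_weight(100_000, "weighted", 100_000) == pytest.approx(
            math.exp(-4.5)
        )

    def test_unweighted_is_one(self):
        assert peak_weight(70_000, "unweighted", 100_000) == 1.0

    def test_binary_proximal_distal(self):
        assert peak_weight(10_000, "binary") == 1.0
        assert peak_weight(10_001, "binary") == 0.5

    def test_distance_beyond_window_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            peak_weight(100_001, "weighted", 100_000)

    @given(st.floats(0, 100_000))
    def test_weight_in_unit_interval_and_monotone(self, d):
        w = peak_weight(d, "weighted", 100_000)
        assert 0 < w <= 1
        assert w <= peak_weight(0, "weighted", 100_000)


class TestGeneScore:
    def test_hand_arithmetic_unweighted(self):
        deg = DEGRecord("G1", 0.5, 2.0, 0.01)
        peaks = [make_peak(name="p1", nlp=2.0), make_peak(name="p2", nlp=3.0)]
        links = [PeakGeneLink("G1", "p1", 1000.0),
                 PeakGeneLink("G1", "p2", 5000.0)]
        score = wtct_gene_score(links, peaks, deg, mode="unweighted")
        assert score.score == pytest.approx(2.5)  # (2+3) * 0.5

    def test_no_links_scores_zero(self):
        deg = DEGRecord("G1", 0.5, 2.0, 0.01)
        assert wtct_gene_score([], [], deg).score == 0.0

    def test_zero_fold_change_scores_zero(self):
        deg = DEGRecord("G1", 0.0, 2.0, 0.01)
        links = [PeakGeneLink("G1", "p1", 0.0)]
        assert wtct_gene_score(links, [make_peak(name="p1")], deg).score == 0.0

    def test_missing_peak_rejected(self):
        deg = DEGRecord("G1", 0.5, 2.0, 0.01)
        with pytest.raises(ValueError, match="unknown peak"):
            wtct_gene_score([PeakGeneLink("G1", "ghost", 0.0)], [], deg)

    def test_foreign_link_rejected(self):
        deg = DEGRecord("G1", 0.5, 2.0, 0.01)
        with pytest.raises(ValueError, match="passed to gene"):
            wtct_gene_score(
                [PeakGeneLink("G2", "p1", 0.0)], [make_peak(name="p1")], deg
            )


def bruteforce_table(peaks, genes, degs, window, mode):
    """Independent O(genes x peaks) double loop."""
    catalog = {g.gene_id: g for g in genes}
    out = {}
    for d in degs:
        if d.gene_id not in catalog:
            continue
        g = catalog[d.gene_id]
        total = 0.0
        for p in peaks:
            if p.interval.chrom != g.interval.chrom:
                continue
            dist = abs(p.interval.midpoint - g.tss)
            if dist <= window:
                total += peak_weight(dist, mode, window) * p.neglog_padj
        out[d.gene_id] = total * abs(d.log_fc)
    return out


class TestWtctTable:
    def test_matches_bruteforce_on_three_genes(self, three_genes, simple_degs):
        peaks = [
            make_peak("chr1", 40_000, 42_000, "p1", 2.0),
            make_peak("chr1", 140_000, 142_000, "p2", 3.0),
            make_peak("chr1", 390_000, 391_000, "p3", 1.5),
            make_peak("chr2", 10_000, 12_000, "p4", 4.0),
        ]
        for mode in ("unweighted", "weighted", "binary"):
            scores = wtct_table(peaks, three_genes, simple_degs, mode=mode)
            oracle = bruteforce_table(peaks, three_genes, simple_degs,
                                      100_000, mode)
            assert {s.gene_id: s.score for s in scores} == pytest.approx(oracle)

    def test_state_filter_without_peaks_scores_zero(self, three_genes,
                                                    simple_degs):
        peaks = [make_peak("chr1", 40_000, 42_000, "p1", 2.0)]
        segs = [StateSegment(GenomicInterval("chr1", 0, 1_000_000),
                             "Quiescent")]
        scores = wtct_table(peaks, three_genes, simple_degs,
                            state_filter=("Active Enhancer", segs))
        assert all(s.score == 0.0 for s in scores)

    def test_weighted_never_exceeds_unweighted(self, rng):
        peaks = random_peaks(rng, 80)
        genes = random_genes(rng, 40)
        degs = random_degs(rng, genes)
        w = {s.gene_id: s.score
             for s in wtct_table(peaks, genes, degs, mode="weighted")}
        u = {s.gene_id: s.score
             for s in wtct_table(peaks, genes, degs, mode="unweighted")}
        assert all(w[g] <= u[g] + 1e-12 for g in w)

    def test_empty_degs_rejected(self, three_genes):
        with pytest.raises(ValueError, match="empty"):
            wtct_table([], three_genes, [])

    def test_de_gene_missing_from_catalog_skipped(self, three_genes):
        degs = [DEGRecord("G1", 1.0, 2.0, 0.01),
                DEGRecord("GHOST", 1.0, 2.0, 0.01)]
        scores = wtct_table([], three_genes, degs)
        assert [s.gene_id for s in scores] == ["G1"]

    def test_linearity_in_peak_significance(self, rng):
        peaks = random_peaks(rng, 50)
        genes = random_genes(rng, 25)
        degs = random_degs(rng, genes)
        doubled = [
            Peak(p.interval, p.name, 2 * p.neglog_padj, p.source)
            for p in peaks
        ]
        for mode in ("unweighted", "weighted"):
            s1 = wtct_table(peaks, genes, degs, mode=mode)
            s2 = wtct_table(doubled, genes, degs, mode=mode)
            for a, b in zip(s1, s2):
                assert b.score == pytest.approx(2 * a.score)

    def test_monotone_in_added_peak_and_window_exclusion(self):
        gene = make_gene("G1", start=500_000, end=502_000, strand="+")
        deg = DEGRecord("G1", 1.0, 2.0, 0.01)
        base = [make_peak("chr1", 450_000, 452_000, "p1", 2.0)]
        inside = base + [make_peak("chr1", 550_000, 552_000, "p2", 1.0)]
        outside = base + [make_peak("chr1", 900_000, 902_000, "p3", 9.0)]
        s_base = wtct_table(base, [gene], [deg], mode="weighted")[0].score
        s_in = wtct_table(inside, [gene], [deg], mode="weighted")[0].score
        s_out = wtct_table(outside, [gene], [deg], mode="weighted")[0].score
        assert s_in > s_base
        assert s_out == pytest.approx(s_base)


class TestCompareWtct:
    def test_exact_small_sample(self):
        res = compare_wtct([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.1)
        assert res.direction == -1

    def test_identical_multisets_p_one(self):
        res = compare_wtct([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0

    def test_label_swap_negates_direction(self, rng):
        a = rng.normal(1, 1, size=20)
        b = rng.normal(0, 1, size=25)
        r1 = compare_wtct(a, b)
        r2 = compare_wtct(b, a)
        assert r1.p == pytest.approx(r2.p)
        assert r1.direction == -r2.direction

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_wtct([], [1.0])

    def test_all_tied_values_p_one(self, caplog):
        with caplog.at_level("WARNING", logger="wtct.scoring"):
            res = compare_wtct([0.0, 0.0], [0.0, 0.0, 0.0])
        assert res.p == 1.0

    def test_background_labels_propagated(self):
        from wtct import WtCTScore

        a = [WtCTScore("G1", 1.0, "mock"), WtCTScore("G2", 2.0, "mock")]
        b = [WtCTScore("G1", 3.0, "variant"), WtCTScore("G2", 4.0, "variant")]
        res = compare_wtct(a, b)
        assert (res.background_a, res.background_b) == ("mock", "variant")


class TestBHAdjust:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_dominate_raw_and_capped(self, ps):
        q = bh_adjust(ps)
        assert all(0 <= qi <= 1 for qi in q)
        assert all(qi >= pi - 1e-12 for qi, pi in zip(q, ps))

    def test_matches_stepup_definition(self, rng):
        ps = rng.uniform(size=20)
        q = bh_adjust(ps)
        m = len(ps)
        order = np.argsort(ps)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, ps[i] * m / rank)
            expected[i] = running
        assert q == pytest.approx(expected.tolist())
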