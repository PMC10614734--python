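"""Genome windowing, per-window stats, and the enrichment matrix."""

import numpy as np
import pytest
from scipy import stats

from rlea import (
    ChromSizes,
    FixtureSpec,
    IntervalSet,
    Locus,
    LocusSet,
    RegulatoryEnrichment,
    adjust_pvalues,
    count_genomewide_overlap,
    enrichment_matrix,
    enrichment_pvalue,
    make_locus_set,
    make_ocr_sets,
    make_toy_genome,
    make_windows,
    window_stats,
)
from rlea.enrichment import EnrichmentMatrix, EnrichmentResult, Window


def iset(name, *spans):
    return IntervalSet(name, list(spans))


class TestMakeWindows:
    def test_rounded_window_count_and_lengths(self):
        ws = make_windows(ChromSizes({"chr1": 10}), 3)
        assert [len(w) for w in ws] == [4, 3, 3]
        assert ws[0].start == 0 and ws[-1].end == 10

    def test_single_window_when_target_exceeds_chrom(self):
        ws = make_windows(ChromSizes({"chr1": 10}), 100)
        assert ws == [Window("chr1", 0, 10)]

    def test_exact_division(self):
        ws = make_windows(ChromSizes({"chr1": 9}), 3)
        assert [len(w) for w in ws] == [3, 3, 3]

    def test_tiling_invariants_on_toy_genome(self, toy_genome):
        ws = make_windows(toy_genome, 1_000_000)
        by_chrom = {}
        for w in ws:
            by_chrom.setdefault(w.chrom, []).append(w)
        assert set(by_chrom) == set(toy_genome.sizes)
        for chrom, wins in by_chrom.items():
            assert wins[0].start == 0
            assert wins[-1].end == toy_genome[chrom]
            for a, b in zip(wins, wins[1:]):
                assert a.end == b.start
            lengths = {len(w) for w in wins}
            assert max(lengths) - min(lengths) <= 1


class TestWindowStats:
    def test_saturated_window(self):
        w = Window("chr1", 0, 1000)
        ocr = iset("ct", ("chr1", 0, 1000))
        loci = LocusSet("t", [Locus("chr1", i * 100) for i in range(5)])
        s = window_stats(w, ocr, loci)
        assert s.coverage == 1.0
        assert s.n_loci == 5
        assert s.k_overlap == 5

    def test_empty_window(self):
        w = Window("chr1", 0, 1000)
        ocr = iset("ct", ("chr2", 0, 1000))
        loci = LocusSet("t", [Locus("chr1", i * 100) for i in range(5)])
        s = window_stats(w, ocr, loci)
        assert s.coverage == 0.0
        assert s.k_overlap == 0

    def test_partial_coverage_and_counting(self):
        w = Window("chr1", 0, 1000)
        ocr = iset("ct", ("chr1", 100, 200))
        loci = LocusSet("t", [Locus("chr1", 150), Locus("chr1", 500)])
        s = window_stats(w, ocr, loci)
        assert s.n_loci == 2
        assert s.coverage == pytest.approx(0.1)
        assert s.k_overlap == 1

    def test_assignment_by_start_position(self):
        # locus starts in window 1 but spans into window 2
        w1, w2 = Window("chr1", 0, 100), Window("chr1", 100, 200)
        ocr = iset("ct", ("chr1", 150, 160))
        loci = LocusSet("t", [Locus("chr1", 98, 10)])
        assert window_stats(w1, ocr, loci).n_loci == 1
        assert window_stats(w2, ocr, loci).n_loci == 0

    def test_indel_extension_of_coverage(self):
        # A 10 bp locus overlapping the peak grows each peak segment by
        # 9 bp per side: covered fraction (200-100+18)/1000 = 0.118.
        w = Window("chr1", 0, 1000)
        ocr = iset("ct", ("chr1", 100, 200))
        loci = LocusSet("t", [Locus("chr1", 95, 10)])
        s = window_stats(w, ocr, loci)
        assert s.k_overlap == 1
        assert s.coverage == pytest.approx(0.118)

    def test_non_overlapping_indel_does_not_extend(self):
        w = Window("chr1", 0, 1000)
        ocr = iset("ct", ("chr1", 100, 200))
        loci = LocusSet("t", [Locus("chr1", 500, 10)])
        s = window_stats(w, ocr, loci)
        assert s.k_overlap == 0
        assert s.coverage == pytest.approx(0.1)

    def test_extension_clipped_to_window(self):
        # peak touching the window edge cannot grow past it
        w = Window("chr1", 0, 100)
        ocr = iset("ct", ("chr1", 0, 100))
        loci = LocusSet("t", [Locus("chr1", 50, 20)])
        s = window_stats(w, ocr, loci)
        assert s.coverage == 1.0


class TestGenomewideOverlap:
    def test_all_inside(self):
        ocr = iset("ct", ("chr1", 0, 1000))
        loci = LocusSet("t", [Locus("chr1", i) for i in range(10)])
        assert count_genomewide_overlap(ocr, loci) == 10

    def test_span_reaching_into_peak_counts(self):
        ocr = iset("ct", ("chr1", 100, 200))
        loci = LocusSet("t", [Locus("chr1", 98, 5), Locus("chr1", 94, 5)])
        # [98,103) intersects; [94,99) does not reach 100
        assert count_genomewide_overlap(ocr, loci) == 1

    def test_empty_ocr(self):
        loci = LocusSet("t", [Locus("chr1", 5)])
        assert count_genomewide_overlap(IntervalSet("ct", []), loci) == 0


class TestEnrichmentPvalue:
    def test_binomial_toy_case(self):
        sizes = ChromSizes({"chr1": 1000})
        windows = make_windows(sizes, 1000)
        ocr = iset("ct", ("chr1", 100, 200))
        inside = [Locus("chr1", 100 + 10 * i) for i in range(5)]
        outside = [Locus("chr1", 300 + 50 * i) for i in range(5)]
        res = enrichment_pvalue(ocr, LocusSet("t", inside + outside), windows)
        assert res.k_observed == 5
        assert res.n_total == 10
        # P(Binomial(10, 0.1) >= 5)
        assert res.p_raw == pytest.approx(stats.binom.sf(4, 10, 0.1), rel=1e-9)
        assert res.p_raw == pytest.approx(1.63e-3, rel=5e-3)
        assert res.neg_log10_p == pytest.approx(-np.log10(res.p_raw))

    def test_full_coverage_gives_p_one(self):
        sizes = ChromSizes({"chr1": 1000})
        windows = make_windows(sizes, 1000)
        ocr = iset("ct", ("chr1", 0, 1000))
        loci = LocusSet("t", [Locus("chr1", i * 90) for i in range(10)])
        res = enrichment_pvalue(ocr, loci, windows)
        assert res.p_raw == 1.0

    def test_zero_coverage_zero_overlap_gives_p_one(self):
        sizes = ChromSizes({"chr1": 1000, "chr2": 1000})
        windows = make_windows(sizes, 500)
        ocr = iset("ct", ("chr2", 0, 10))
        loci = LocusSet("t", [Locus("chr1", i * 90) for i in range(10)])
        res = enrichment_pvalue(ocr, loci, windows)
        assert res.p_raw == 1.0

    def test_no_usable_loci_rejected(self):
        sizes = ChromSizes({"chr1": 1000})
        windows = make_windows(sizes, 1000)
        ocr = iset("ct", ("chr1", 0, 100))
        loci = LocusSet("t", [Locus("chr2", 5)])
        with pytest.raises(ValueError, match="no usable loci"):
            enrichment_pvalue(ocr, loci, windows)

    def test_conservation_of_locus_counts(self, toy_spec, toy_genome):
        ocr = make_ocr_sets(toy_spec)[0]
        loci = make_locus_set(toy_spec)
        windows = make_windows(toy_genome, 1_000_000)
        stats_list = [window_stats(w, ocr, loci) for w in windows]
        assert sum(s.n_loci for s in stats_list) == len(loci)
        # SNV-only fixture: no locus spans a window boundary
        assert sum(s.k_overlap for s in stats_list) == count_genomewide_overlap(
            ocr, loci
        )

    def test_invariance_under_chromosome_renaming(self, toy_spec):
        ocr = make_ocr_sets(toy_spec)[0]
        loci = make_locus_set(toy_spec)
        sizes = make_toy_genome(toy_spec)
        windows = make_windows(sizes, 1_000_000)
        ref = enrichment_pvalue(ocr, loci, windows)

        mapping = {"chr1": "chrz9", "chr2": "chrz3"}
        ocr2 = IntervalSet(
            ocr.name, [(mapping[i.chrom], i.start, i.end) for i in ocr.intervals]
        )
        loci2 = LocusSet(
            loci.name, [Locus(mapping[l.chrom], l.pos, l.length) for l in loci.loci]
        )
        sizes2 = ChromSizes({mapping[c]: n for c, n in sizes.items()})
        res2 = enrichment_pvalue(ocr2, loci2, make_windows(sizes2, 1_000_000))
        assert res2.p_raw == pytest.approx(ref.p_raw, rel=1e-12)
        assert res2.k_observed == ref.k_observed

    def test_invariance_under_ocr_file_split(self, toy_spec, toy_genome):
        ocr = make_ocr_sets(toy_spec)[0]
        loci = make_locus_set(toy_spec)
        windows = make_windows(toy_genome, 1_000_000)
        ref = enrichment_pvalue(ocr, loci, windows)
        spans = [(i.chrom, i.start, i.end) for i in ocr.intervals]
        rejoined = IntervalSet(ocr.name, spans[::2] + spans[1::2])
        res = enrichment_pvalue(rejoined, loci, windows)
        assert res.p_raw == ref.p_raw


class TestEnrichmentMatrix:
    def make_inputs(self, toy_spec):
        sizes = make_toy_genome(toy_spec)
        ocr_sets = make_ocr_sets(toy_spec)[:2]
        locus_sets = [
            make_locus_set(toy_spec.replace(seed=s, n_loci=300), name=f"t{s}")
            for s in (1, 2, 3)
        ]
        return ocr_sets, locus_sets, sizes

    def test_shape_and_bonferroni(self, toy_spec):
        ocr_sets, locus_sets, sizes = self.make_inputs(toy_spec)
        mat = enrichment_matrix(ocr_sets, locus_sets, sizes, 1_000_000)
        assert mat.shape == (2, 3)
        for row in mat.cells:
            for c in row:
                assert c.p_adjusted == pytest.approx(min(1.0, 6 * c.p_raw))
                assert c.p_adjusted >= c.p_raw

    def test_single_pair_adjustment_is_identity(self, toy_spec):
        ocr_sets, locus_sets, sizes = self.make_inputs(toy_spec)
        mat = enrichment_matrix(ocr_sets[:1], locus_sets[:1], sizes, 1_000_000)
        cell = mat.cells[0][0]
        assert mat.shape == (1, 1)
        assert cell.p_adjusted == pytest.approx(cell.p_raw)

    def test_column_order_follows_input_order(self, toy_spec):
        ocr_sets, locus_sets, sizes = self.make_inputs(toy_spec)
        a = enrichment_matrix(ocr_sets, locus_sets, sizes, 1_000_000)
        b = enrichment_matrix(ocr_sets, locus_sets[::-1], sizes, 1_000_000)
        assert b.cols == a.cols[::-1]
        assert np.allclose(
            b.p_raw[a.cols].to_numpy(), a.p_raw.to_numpy()
        )

    def test_model_results_roundtrip(self, toy_spec, tmp_path):
        ocr_sets, locus_sets, sizes = self.make_inputs(toy_spec)
        model = RegulatoryEnrichment(ocr_sets, locus_sets, sizes)
        res = model.fit()
        assert res.shape == (2, 3)
        paths = res.to_csv(str(tmp_path))
        assert all(p.endswith(".csv") for p in paths)
        text = res.summary()
        assert "cell types: 2" in text and "locus sets: 3" in text


class TestAdjustPvalues:
    def grid(self, p_values):
        cells = [
            [
                EnrichmentResult("ct", f"s{j}", 0, 10, p, -np.log10(max(p, 1e-300)))
                for j, p in enumerate(row)
            ]
            for row in p_values
        ]
        for i, row in enumerate(cells):
            for c in row:
                c.cell_type = f"ct{i}"
        return EnrichmentMatrix(cells)

    def test_all_ones_nothing_survives(self):
        mat = adjust_pvalues(self.grid([[1.0, 1.0], [1.0, 1.0]]), "bonferroni")
        assert (mat.p_adjusted.to_numpy() == 1.0).all()
        assert not mat.survives.to_numpy().any()

    def test_bh_matches_step_up_oracle(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.09, 0.7]
        mat = adjust_pvalues(self.grid([p[:3], p[3:]]), "bh")
        # brute-force Benjamini-Hochberg step-up
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            adj[i] = running
        got = mat.p_adjusted.to_numpy().ravel()
        assert np.allclose(got, adj)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues(self.grid([[0.5]]), "holmes")


class TestWindowSizeStability:
    def test_median_log10_shift_between_10kb_and_100kb_is_small(self, toy_spec, toy_genome):
        ocr = make_ocr_sets(toy_spec)[0]
        w10 = make_windows(toy_genome, 10_000)
        w100 = make_windows(toy_genome, 100_000)
        diffs = []
        for seed in range(20):
            loci = make_locus_set(toy_spec.replace(seed=seed), name=f"r{seed}")
            p_a = enrichment_pvalue(ocr, loci, w10).neg_log10_p
            p_b = enrichment_pvalue(ocr, loci, w100).neg_log10_p
            diffs.append(abs(p_a - p_b))
        assert np.median(diffs) < 0.5
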