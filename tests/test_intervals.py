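"""Peak intersection, gene assignment and site filtering."""

import numpy as np
import pytest

from circout.intervals import (
    GeneModel,
    GenomicInterval,
    Location,
    assign_peak,
    assign_peaks,
    intersect_peaks,
    overlap_with_sites,
    read_bed,
    read_genes,
    top_sites_by_signal,
    write_bed,
)


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestGenomicInterval:
    def test_rejects_malformed(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 100)

    def test_center_is_floor_midpoint(self):
        assert iv("chr1", 100, 201).center == 150
        assert iv("chr1", 100, 200).center == 150


class TestGeneModel:
    def test_tss_tts_strand_aware(self):
        plus = GeneModel("chr1", 100, 200, "+", "g1")
        minus = GeneModel("chr1", 100, 200, "-", "g2")
        assert (plus.tss, plus.tts) == (100, 199)
        assert (minus.tss, minus.tts) == (199, 100)

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            GeneModel("chr1", 100, 200, ".", "g1")


class TestIntersectPeaks:
    def test_single_overlap_keeps_b_coordinates(self):
        out = intersect_peaks([iv("chr1", 100, 200)], [iv("chr1", 150, 250)])
        assert out == [iv("chr1", 150, 250)]

    def test_different_chromosome_no_overlap(self):
        assert intersect_peaks([iv("chr1", 100, 200)], [iv("chr2", 100, 200)]) == []

    def test_adjacent_intervals_do_not_overlap(self):
        # half-open: [100,200) and [200,300) share no base
        assert intersect_peaks([iv("chr1", 100, 200)], [iv("chr1", 200, 300)]) == []

    def test_deduplicated_and_sorted(self):
        a = [iv("chr1", 0, 1000)]
        b = [iv("chr1", 500, 600), iv("chr1", 100, 300), iv("chr1", 500, 600)]
        out = intersect_peaks(a, b)
        assert out == [iv("chr1", 100, 300), iv("chr1", 500, 600)]

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(42)
        a = [
            iv("chr%d" % rng.integers(1, 4), s, s + int(rng.integers(1, 300)))
            for s in rng.integers(0, 50_000, 400)
        ]
        b = [
            iv("chr%d" % rng.integers(1, 4), s, s + int(rng.integers(1, 300)))
            for s in rng.integers(0, 50_000, 400)
        ]
        expected = sorted(
            {
                (x.chrom, x.start, x.end)
                for x in b
                if any(x.overlaps(y) for y in a)
            }
        )
        got = [(x.chrom, x.start, x.end) for x in intersect_peaks(a, b)]
        assert got == expected
        assert len(got) <= len(b)


class TestAssignPeak:
    GENE = GeneModel("chr1", 100_000, 120_001, "+", "G")  # TSS=100000, TTS=120000

    def _assign(self, center):
        peak = iv("chr1", center - 50, center + 50)
        return assign_peak(peak, [self.GENE])

    def test_extended_promoter(self):
        a = self._assign(95_000)
        assert a.gene_id == "G" and a.location is Location.EXTENDED_PROMOTER

    def test_tss_window(self):
        a = self._assign(100_500)
        assert a.gene_id == "G" and a.location is Location.TSS

    def test_beyond_tts_window_is_intergenic(self):
        a = self._assign(121_500)
        assert a.gene_id is None and a.location is Location.INTERGENIC

    def test_gene_body(self):
        a = self._assign(110_000)
        assert a.location is Location.GENE_BODY

    def test_nearest_tss_wins_and_ties_break_lexicographically(self):
        g1 = GeneModel("chr1", 100_000, 120_000, "+", "B")
        g2 = GeneModel("chr1", 104_000, 125_000, "+", "A")
        near_g2 = assign_peak(iv("chr1", 103_450, 103_550), [g1, g2])
        assert near_g2.gene_id == "A"  # 500 bp from A's TSS vs 3.5 kb from B's
        tie = GeneModel("chr1", 100_000, 120_000, "+", "C")
        tied = assign_peak(iv("chr1", 100_450, 100_550), [g1, tie])
        assert tied.gene_id == "B"

    def test_strand_reflection_symmetry(self):
        """Mirroring coordinates and flipping strand preserves categories."""
        rng = np.random.default_rng(5)
        L = 1_000_000
        gene = GeneModel("chr1", 400_000, 450_000, "+", "G")
        mirror = GeneModel("chr1", L - 450_000, L - 400_000, "-", "G")
        for center in rng.integers(380_000, 460_000, 50):
            center = int(center)
            fwd = assign_peak(iv("chr1", center - 10, center + 10), [gene])
            # mirrored peak: same span reflected; center maps to L-1-center,
            # use a width-1 peak anchored exactly there
            mc = L - 1 - center
            rev = assign_peak(iv("chr1", mc, mc + 1), [mirror])
            assert fwd.location is rev.location

    def test_location_partition(self, small_cohort):
        assignments = assign_peaks(
            small_cohort["peaks_b"][:150], small_cohort["genes"]
        )
        n_intergenic = sum(a.location is Location.INTERGENIC for a in assignments)
        n_assigned = sum(a.gene_id is not None for a in assignments)
        assert n_intergenic + n_assigned == len(assignments)
        for a in assignments:
            assert (a.gene_id is None) == (a.location is Location.INTERGENIC)

    def test_empty_gene_table_rejected(self):
        with pytest.raises(ValueError):
            assign_peak(iv("chr1", 0, 10), [])


class TestOverlapWithSites:
    def test_trivial_partitions(self):
        inside, outside = overlap_with_sites([iv("chr1", 10, 20)], [iv("chr1", 15, 30)])
        assert (len(inside), len(outside)) == (1, 0)
        inside, outside = overlap_with_sites([iv("chr1", 10, 20)], [])
        assert (len(inside), len(outside)) == (0, 1)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(17)
        peaks = [
            iv("chr%d" % rng.integers(1, 3), s, s + int(rng.integers(1, 200)))
            for s in rng.integers(0, 100_000, 1000)
        ]
        sites = [
            iv("chr%d" % rng.integers(1, 3), s, s + int(rng.integers(1, 200)))
            for s in rng.integers(0, 100_000, 500)
        ]
        inside, outside = overlap_with_sites(peaks, sites)
        assert len(inside) + len(outside) == len(peaks)
        oracle_inside = [p for p in peaks if any(p.overlaps(s) for s in sites)]
        assert sorted(inside) == sorted(oracle_inside)


class TestTopSitesBySignal:
    def test_highest_scores_kept(self):
        sites = [iv("chr1", i * 10, i * 10 + 5, score=s) for i, s in enumerate([1, 5, 3, 2, 4])]
        out = top_sites_by_signal(sites, n=3)
        assert sorted(s.score for s in out) == [3, 4, 5]

    def test_identity_when_n_exceeds_length(self):
        sites = [iv("chr1", 0, 5, score=1.0)]
        assert top_sites_by_signal(sites, n=10) == sites

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError, match="score"):
            top_sites_by_signal([iv("chr1", 0, 5)], n=1)

    def test_matches_full_sort_oracle_with_ties(self):
        rng = np.random.default_rng(23)
        sites = [
            iv("chr%d" % rng.integers(1, 3), int(s), int(s) + 10,
               score=float(rng.integers(0, 50)))  # heavy ties
            for s in rng.integers(0, 10_000_000, 5000)
        ]
        n = 2000
        oracle = sorted(sites, key=lambda s: (-s.score, s.chrom, s.start, s.end))[:n]
        got = top_sites_by_signal(sites, n=n)
        assert sorted(got, key=lambda s: (-s.score, s.chrom, s.start)) == oracle


class TestIO:
    def test_bed_roundtrip(self, tmp_path):
        peaks = [
            iv("chr1", 0, 100, name="p1", score=3.5, strand="+"),
            iv("chr2", 50, 80),
        ]
        path = tmp_path / "peaks.bed"
        write_bed(peaks, path)
        back = read_bed(path)
        assert back == peaks
        assert back[0].score == 3.5 and back[0].strand == "+"

    def test_malformed_record_reports_index(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t100\nchr1\t500\t400\n")
        with pytest.raises(ValueError, match="record 1"):
            read_bed(path)

    def test_read_genes_both_formats(self, tmp_path):
        p5 = tmp_path / "genes5.tsv"
        p5.write_text("chr1\t100\t200\t+\tgeneA\n")
        p6 = tmp_path / "genes6.bed"
        p6.write_text("chr1\t100\t200\tgeneA\t0\t+\n")
        assert read_genes(p5) == read_genes(p6)
        assert read_genes(p5)[0].gene_id == "geneA"
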