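import numpy as np
import pytest

import tfdirect as td
from tfdirect.genome_io import GenomicInterval, PeakRecord
from tfdirect.peaks import (annotate_peak_features, assign_peaks_to_genes,
                            nonredundant_fraction, peak_distance_between_tfs,
                            peak_position_profile, reproducible_peaks,
                            strand_cross_correlation)


def _peak(chrom, start, end, summit, name="p"):
    return PeakRecord(GenomicInterval(chrom, start, end), summit, 1.0, name)


class TestNRF:
    def test_all_distinct(self):
        tags = [("chr1", i, "+") for i in range(10)]
        assert nonredundant_fraction(tags) == 1.0

    def test_half_duplicated(self):
        tags = [("chr1", i, "+") for i in range(5)] * 2
        assert nonredundant_fraction(tags) == 0.5

    def test_matches_hash_set_oracle(self):
        rng = np.random.default_rng(4)
        tags = [("chr1", int(rng.integers(100)), "+-"[int(rng.integers(2))])
                for _ in range(500)]
        assert nonredundant_fraction(tags) == len(set(tags)) / len(tags)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            nonredundant_fraction([])


class TestCrossCorrelation:
    def test_exact_shift_recovered(self):
        rng = np.random.default_rng(0)
        plus = rng.poisson(0.05, 10_000).astype(float)
        minus = np.roll(plus, 120)
        rep = strand_cross_correlation(plus, minus, range(0, 300, 5))
        assert rep.fragment_length_estimate == 120

    def test_independent_vectors_low_correlation(self):
        rng = np.random.default_rng(1)
        plus = rng.poisson(0.05, 10_000).astype(float)
        minus = rng.poisson(0.05, 10_000).astype(float)
        rep = strand_cross_correlation(plus, minus, range(0, 300, 10))
        assert max(abs(c) for c in rep.cc_profile.values()) < 0.2

    def test_constant_vector_flagged_zero(self):
        rep = strand_cross_correlation(np.ones(100), np.ones(100), [0, 10])
        assert rep.cc_profile[0] == 0.0
        assert rep.zero_variance_warning

    def test_phantom_exclusion_skips_read_length(self):
        rng = np.random.default_rng(2)
        plus = rng.poisson(0.05, 10_000).astype(float)
        minus = np.roll(plus, 50)   # artificial peak exactly at read length
        rep = strand_cross_correlation(plus, minus, range(0, 300, 5),
                                       read_length=50)
        assert rep.fragment_length_estimate != 50

    def test_planted_fragment_length_recovered(self, dataset, peak_replicates):
        from tfdirect.synthetic import simulate_tags
        from tfdirect.peaks import tag_start_vectors
        cfg = dataset["config"]
        rep_a = [p for p in peak_replicates[0] if p.interval.chrom == "chr1"]
        chrom_len = cfg.chrom_length
        tags = simulate_tags(rep_a, {"chr1": bytearray(chrom_len)}, cfg,
                             fragment_length=150)
        plus, minus = tag_start_vectors(tags, "chr1", chrom_len)
        rep = strand_cross_correlation(plus, minus, range(50, 301, 2),
                                       read_length=36)
        assert abs(rep.fragment_length_estimate - 150) <= 5


class TestReproduciblePeaks:
    def test_identity(self, peak_replicates):
        rep_a = peak_replicates[0]
        assert reproducible_peaks(rep_a, rep_a) == rep_a

    def test_disjoint_empty(self):
        a = [_peak("chr1", 0, 100, 50)]
        b = [_peak("chr1", 200, 300, 250)]
        assert reproducible_peaks(a, b) == []

    def test_bounded_by_rep_a(self, peak_replicates):
        rep_a, rep_b = peak_replicates
        assert len(reproducible_peaks(rep_a, rep_b)) <= len(rep_a)

    def test_recovers_planted_peaks_under_noise(self, dataset, peak_replicates):
        """With 10% replicate-unique noise, exactly the planted peaks
        survive reconciliation."""
        rep_a, rep_b = peak_replicates
        repro = reproducible_peaks(rep_a, rep_b)
        names = {p.name for p in repro}
        planted = {p.name for p in rep_a if p.name.startswith("peakA")}
        assert names == planted


@pytest.fixture(scope="module")
def toy_genes():
    return [td.GeneModel("plus", GenomicInterval("chr1", 5000, 8001, "+")),
            td.GeneModel("minus", GenomicInterval("chr2", 5000, 8001, "-"))]


class TestAssignPeaksToGenes:
    @pytest.mark.parametrize("summit,expect_bound,expect_zone,expect_d", [
        (4001, True, "upstream_window", -999),
        (3999, False, None, None),
        (7500, True, "gene_body", 2500),
    ])
    def test_plus_strand_window(self, toy_genes, summit, expect_bound,
                                expect_zone, expect_d):
        peaks = [_peak("chr1", summit - 50, summit + 50, summit)]
        bound, links = assign_peaks_to_genes(peaks, toy_genes)
        assert ("plus" in bound) == expect_bound
        if expect_bound:
            assert links[0].zone == expect_zone
            assert links[0].signed_distance_to_tss == expect_d

    def test_minus_strand_upstream(self, toy_genes):
        # minus-strand TSS at 8000; summit 8500 is 500 bp upstream
        peaks = [_peak("chr2", 8450, 8550, 8500)]
        bound, links = assign_peaks_to_genes(peaks, toy_genes)
        assert "minus" in bound
        assert links[0].signed_distance_to_tss == -500
        assert links[0].zone == "upstream_window"

    def test_negative_window_raises(self, toy_genes):
        with pytest.raises(ValueError):
            assign_peaks_to_genes([], toy_genes, upstream_window=-1)

    def test_recovers_planted_bound_set(self, dataset, genes, peak_replicates):
        rep_a, rep_b = peak_replicates
        repro = reproducible_peaks(rep_a, rep_b)
        bound, _ = assign_peaks_to_genes(repro, genes)
        assert bound == dataset["truth"].bound_genes

    def test_translation_invariance(self, toy_genes):
        """Shifting every coordinate by a constant leaves assignments
        unchanged."""
        peaks = [_peak("chr1", 4400, 4600, 4500), _peak("chr1", 6000, 6200, 6100)]
        shift = 12345
        shifted_genes = [
            td.GeneModel(g.gene_id, GenomicInterval(
                g.interval.chrom, g.interval.start + shift,
                g.interval.end + shift, g.strand))
            for g in toy_genes]
        shifted_peaks = [
            _peak(p.interval.chrom, p.interval.start + shift,
                  p.interval.end + shift, p.summit + shift) for p in peaks]
        b1, l1 = assign_peaks_to_genes(peaks, toy_genes)
        b2, l2 = assign_peaks_to_genes(shifted_peaks, shifted_genes)
        assert b1 == b2
        assert [x.signed_distance_to_tss for x in l1] == \
               [x.signed_distance_to_tss for x in l2]


class TestFeatureAnnotation:
    def test_utr5_beats_other_genes_upstream_window(self):
        a = td.GeneModel("a", GenomicInterval("chr1", 1000, 2000, "+"),
                         exons=[GenomicInterval("chr1", 1000, 2000, "+")],
                         utr5=[GenomicInterval("chr1", 1000, 1100, "+")])
        b = td.GeneModel("b", GenomicInterval("chr1", 2500, 3500, "+"))
        peaks = [_peak("chr1", 1000, 1100, 1050)]
        feat = annotate_peak_features(peaks, [a, b])
        assert feat.counts["utr5"] == 1

    def test_no_genes_all_intergenic(self):
        peaks = [_peak("chr1", 0, 100, 50), _peak("chr2", 0, 100, 50)]
        feat = annotate_peak_features(peaks, [])
        assert feat.counts["intergenic"] == 2

    def test_fractions_partition_fuzzed(self, genes):
        rng = np.random.default_rng(8)
        peaks = [_peak("chr1", int(s), int(s) + 100, int(s) + 50)
                 for s in rng.integers(0, 400_000, 300)]
        feat = annotate_peak_features(peaks, genes)
        assert sum(feat.counts.values()) == 300
        assert abs(sum(feat.fractions.values()) - 1) < 1e-9

    def test_intron_and_downstream_categories(self):
        g = td.GeneModel(
            "g", GenomicInterval("chr1", 1000, 3000, "+"),
            exons=[GenomicInterval("chr1", 1000, 1500, "+"),
                   GenomicInterval("chr1", 2500, 3000, "+")])
        feat = annotate_peak_features(
            [_peak("chr1", 1900, 2100, 2000),        # intron
             _peak("chr1", 3400, 3600, 3500)], [g])  # 500 bp past the TTS
        assert feat.counts["intron"] == 1
        assert feat.counts["downstream_1kb"] == 1


class TestPositionProfile:
    def test_all_at_tss_single_bin(self, genes):
        g = genes[0]
        peaks = [_peak(g.interval.chrom, g.tss - 50, g.tss + 50, g.tss)
                 for _ in range(5)]
        _, links = assign_peaks_to_genes(peaks, [g])
        edges, counts = peak_position_profile(links, bin_width=100)
        assert counts.sum() == 5
        assert (counts > 0).sum() == 1

    def test_total_conserved_and_mode_downstream(self, dataset, genes,
                                                 peak_replicates):
        rep_a, rep_b = peak_replicates
        repro = reproducible_peaks(rep_a, rep_b)
        _, links = assign_peaks_to_genes(repro, genes)
        edges, counts = peak_position_profile(links, bin_width=100)
        assert counts.sum() == len(links)
        mode_bin = edges[:-1][np.argmax(counts)]
        assert mode_bin >= 0   # offsets drawn downstream-heavy


class TestTFDistance:
    def test_arithmetic(self):
        a = [_peak("chr1", 50, 150, 100)]
        b = [_peak("chr1", 200, 300, 242)]
        dists, med, dmin, dmax, excl = peak_distance_between_tfs(a, b)
        assert dists == [142] and med == 142 and excl == 0

    def test_identity_all_zero(self, peak_replicates):
        rep_a = peak_replicates[0]
        dists, med, dmin, dmax, _ = peak_distance_between_tfs(rep_a, rep_a)
        assert med == 0 and dmin == 0 and dmax == 0

    def test_no_shared_chromosome_warns(self):
        a = [_peak("chr1", 0, 100, 50)]
        b = [_peak("chr9", 0, 100, 50)]
        with pytest.warns(UserWarning):
            dists, med, *_ , excl = peak_distance_between_tfs(a, b)
        assert dists == [] and excl == 1

    def test_planted_offset_median_recovered(self, dataset, peak_replicates):
        d = dataset["dir"]
        tf_b = td.read_narrowpeak(d / "tfb.narrowPeak")
        true_peaks = [p for p in peak_replicates[0]
                      if p.name.startswith("peakA")]
        dists, med, *_ = peak_distance_between_tfs(true_peaks, tf_b)
        planted = np.median(np.abs(dataset["truth"].tf_b_offsets))
        assert med <= planted  # nearest-neighbour can only shrink distances
        assert abs(med - planted) <= 0.3 * planted + 5
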