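import numpy as np
import pytest
from scipy import stats

import tfdirect as td
from tfdirect.genome_io import reverse_complement, write_fasta
from tfdirect.motifs import (IUPACMotif, IUPAC_CODES, BindingSite,
                             geneset_motif_background, make_binding_sites,
                             motif_enrichment, motif_positional_distribution,
                             sample_matched_background, scan_region)

AW = IUPACMotif("AW-Box", "CNTNGNNNNNNNCG")


def naive_scan(seq, motif, both_strands=True):
    """Per-position brute-force oracle for IUPAC matching."""
    def match_at(s, pat, i):
        for j, code in enumerate(pat):
            base = s[i + j]
            if base == "N":
                if code != "N":
                    return False
            elif base not in IUPAC_CODES[code]:
                return False
        return True

    hits = []
    pats = [(motif.pattern, "+")]
    if both_strands:
        pats.append((motif.reverse_complement().pattern, "-"))
    for pat, strand in pats:
        for i in range(len(seq) - len(pat) + 1):
            if match_at(seq, pat, i):
                hits.append((i, strand))
    return sorted(hits)


class TestIUPACMotif:
    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            IUPACMotif("bad", "ACGX")
        with pytest.raises(ValueError):
            IUPACMotif("empty", "")

    def test_reverse_complement_is_involution(self):
        assert AW.reverse_complement().reverse_complement().pattern == AW.pattern


class TestScanRegion:
    def test_constructed_aw_box_match(self):
        assert scan_region("CATAGAAAAAAACG", AW) == [(0, "+")]

    def test_homopolymer_no_match(self):
        assert scan_region("A" * 14, AW) == []

    def test_sequence_n_matches_only_code_n(self):
        m = IUPACMotif("m", "CNT")
        assert scan_region("CNT", m, both_strands=False) == [(0, "+")]
        assert scan_region("NAT", m, both_strands=False) == []

    def test_invalid_base_raises(self):
        with pytest.raises(ValueError):
            scan_region("ACGU", AW)

    @pytest.mark.parametrize("motif", [AW, IUPACMotif("CNC-Box", "CNCCNCC"),
                                       IUPACMotif("G-Box", "CACGTG")])
    def test_matches_naive_oracle_on_random_sequences(self, motif):
        rng = np.random.default_rng(17)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 2000))
            assert scan_region(seq, motif) == naive_scan(seq, motif)

    def test_reverse_complement_invariance(self):
        """A region and its reverse complement contain equally many
        double-strand matches."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 1000))
            assert len(scan_region(seq, AW)) == \
                len(scan_region(reverse_complement(seq), AW))


class TestMatchedBackground:
    def test_single_gene_forced_offset(self, genes, genome):
        g = genes[0]
        site_iv = td.GenomicInterval(g.interval.chrom, g.tss + 150,
                                     g.tss + 250, "+")
        site = BindingSite(site_iv, "A" * 100, tss_offset=200)
        (bg,) = sample_matched_background([site], [g], genome, seed=0)
        center = bg.interval.start + 50
        assert g.tss_offset(center) == 200

    def test_width_multiset_preserved(self, genes, genome, peak_replicates):
        peaks = peak_replicates[0][:20]
        _, links = td.assign_peaks_to_genes(peaks, genes)
        sites = make_binding_sites([l.peak for l in links], genome, 100,
                                   [l.signed_distance_to_tss for l in links])
        bg = sample_matched_background(sites, genes, genome, seed=1)
        assert sorted(len(s.interval) for s in bg) == \
               sorted(len(s.interval) for s in sites)

    def test_offset_distribution_matched(self, genes, genome):
        """Background TSS offsets reproduce the site offset distribution
        (KS < 0.05 at n = 2000)."""
        rng = np.random.default_rng(3)
        offsets = rng.integers(-500, 1000, 2000)
        g0 = genes[0]
        sites = [BindingSite(td.GenomicInterval("chr1", 1000, 1100, "+"),
                             "A" * 100, int(o)) for o in offsets]
        bg = sample_matched_background(sites, genes, genome, seed=4)
        bg_offsets = [s.tss_offset for s in bg]
        ks = stats.ks_2samp(offsets, bg_offsets).statistic
        assert ks < 0.05


class TestEnrichment:
    def _sites(self, seqs):
        return [BindingSite(td.GenomicInterval("chr1", i * 200, i * 200 + len(s)), s)
                for i, s in enumerate(seqs)]

    def test_equal_fractions_not_significant(self):
        pos = "CATAGAAAAAAACG" + "T" * 86
        neg = "T" * 100
        sites = self._sites([pos] * 5 + [neg] * 5)
        bg = self._sites([pos] * 5 + [neg] * 5)
        (r,) = motif_enrichment(sites, bg, [AW])
        assert r.pvalue >= 0.5 and not r.significant

    def test_fisher_matches_hypergeometric_enumeration(self):
        """The 9/1 vs 1/9 table: one-sided p equals the fixed-margin
        hypergeometric enumeration, 101/184756."""
        pos = "CATAGAAAAAAACG" + "T" * 86
        neg = "T" * 100
        sites = self._sites([pos] * 9 + [neg])
        bg = self._sites([pos] + [neg] * 9)
        (r,) = motif_enrichment(sites, bg, [AW])
        from math import comb
        expected = (comb(10, 9) * comb(10, 1) + comb(10, 10)) / comb(20, 10)
        assert r.pvalue == pytest.approx(expected, abs=1e-12)
        assert r.pvalue == pytest.approx(0.000546667, abs=1e-9)

    def test_planted_rate_significant_after_bonferroni(self, genes, genome,
                                                       dataset,
                                                       peak_replicates):
        """AW Box planted in 56% of sites is detected against the matched
        background with the full 5-motif panel correction."""
        rep_a = [p for p in peak_replicates[0] if p.name.startswith("peakA")]
        _, links = td.assign_peaks_to_genes(rep_a, genes)
        sites = make_binding_sites([l.peak for l in links], genome, 100,
                                   [l.signed_distance_to_tss for l in links])
        bg = sample_matched_background(sites, genes, genome, seed=5)
        results = motif_enrichment(sites, bg, td.DEFAULT_MOTIF_PANEL)
        aw = next(r for r in results if r.motif == "AW-Box")
        assert aw.significant
        assert aw.adjusted_pvalue == pytest.approx(min(1, aw.pvalue * 5))


class TestGenesetNull:
    def test_target_equals_universe_p_one(self, genes, genome):
        ids = [g.gene_id for g in genes]
        obs, bg, p = geneset_motif_background(ids, genes, genome, AW,
                                              n_sets=50, seed=0)
        assert np.allclose(bg, obs) and p == 1.0

    def test_p_bounds(self, genes, genome):
        ids = [g.gene_id for g in genes][:10]
        _, _, p = geneset_motif_background(ids, genes, genome, AW,
                                           n_sets=99, seed=1)
        assert 1 / 100 <= p <= 1.0

    def test_invalid_inputs(self, genes, genome):
        with pytest.raises(ValueError):
            geneset_motif_background(["nope"], genes, genome, AW)
        with pytest.raises(ValueError):
            geneset_motif_background([genes[0].gene_id], genes, genome, AW,
                                     n_sets=0)


class TestPositionalDistribution:
    def test_planted_position_single_bin(self, tmp_path):
        from tfdirect.synthetic import (SimulationConfig,
                                        simulate_genome_annotation)
        cfg = SimulationConfig(seed=31, n_genes=30)
        chroms, genes = simulate_genome_annotation(cfg)
        motif = IUPACMotif("fixed", "ACGTACGTACGT")
        # plant at exactly +200 for every gene
        for g in genes:
            inst = "ACGTACGTACGT"
            if g.strand == "-":
                inst = reverse_complement(inst)
            start = g.tss + 200 if g.strand != "-" else g.tss - 200 - 11
            chroms[g.interval.chrom][start:start + 12] = inst.encode()
        write_fasta({c: s.decode() for c, s in chroms.items()},
                    tmp_path / "g.fa")
        fa = td.read_fasta(tmp_path / "g.fa")
        edges, counts = motif_positional_distribution(genes, fa, motif,
                                                      window=500, bin_width=50)
        planted_bin = np.flatnonzero(edges[:-1] == 200)[0]
        assert counts[planted_bin] >= len(genes) * 0.9
        assert counts.sum() >= counts[planted_bin]

    def test_histogram_conserves_matches(self, genes, genome):
        edges, counts = motif_positional_distribution(genes, genome, AW,
                                                      window=800, bin_width=100)
        total = 0
        for g in genes:
            if g.strand != "-":
                iv = td.GenomicInterval(g.interval.chrom, g.tss - 800,
                                        g.tss + 800, "+")
            else:
                iv = td.GenomicInterval(g.interval.chrom, g.tss + 1 - 800,
                                        g.tss + 1 + 800, "-")
            total += len(scan_region(td.fetch_sequence(genome, iv), AW))
        assert counts.sum() == total
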