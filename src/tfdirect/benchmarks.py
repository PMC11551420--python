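"""Seeded validation experiments: oracle checks and planted-truth recovery.

These routines re-derive every statistic the pipeline computes from
independent ground truth — exhaustive enumeration for the exact tests,
planted synthetic datasets for the pipeline stages — and return plain
numbers.  They back both the validation test-suite and the
``scripts/acceptance.py`` report.
"""
from __future__ import annotations

import tempfile
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expression import (CountMatrix, benjamini_hochberg, call_coexpressed,
                         call_direct_targets, de_results_to_frame,
                         nb_exact_test, tmm_factors)
from .genome_io import read_fasta, reverse_complement, write_fasta
from .motifs import (IUPACMotif, geneset_motif_background, make_binding_sites,
                     motif_enrichment, sample_matched_background, scan_region)
from .peaks import (annotate_peak_features, assign_peaks_to_genes,
                    peak_distance_between_tfs, reproducible_peaks,
                    strand_cross_correlation, tag_start_vectors)
from .setstats import hypergeometric_overlap, wilcoxon_rank_sum
from .synthetic import (EMBRYO_GROUPS, SEEDCOAT_GROUPS, SimulationConfig,
                        plant_motif_in_gene_regions, simulate_counts,
                        simulate_genome_annotation, simulate_peaks_and_motifs,
                        simulate_tags)

AW_BOX = IUPACMotif("AW-Box", "CNTNGNNNNNNNCG")


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1000 + k) % (2 ** 31)


# ---------------------------------------------------------------------------
# oracle equivalence

def hypergeometric_vs_enumeration(seed: int = 0, n_cases: int = 25) -> float:
    """Max |error| of the upper-tail overlap p against exhaustive subset
    enumeration, over random instances with universe size <= 20."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    worst = 0.0
    for _ in range(n_cases):
        N = int(rng.integers(6, 15))
        u = set(range(N))
        a = set(rng.choice(N, int(rng.integers(1, N - 1)), replace=False).tolist())
        n_b = int(rng.integers(1, N - 1))
        b = set(rng.choice(N, n_b, replace=False).tolist())
        r = hypergeometric_overlap(a, b, u)
        hits = total = 0
        for bb in combinations(range(N), n_b):
            total += 1
            hits += len(set(bb) & a) >= r.n_overlap
        worst = max(worst, abs(r.pvalue_upper - hits / total))
    return worst


def scan_vs_naive_oracle(seed: int = 0, n_seqs: int = 100,
                         length: int = 10_000) -> int:
    """Number of sequences where vectorized IUPAC scanning disagrees with
    a per-position brute-force matcher."""
    from .motifs import IUPAC_CODES
    rng = np.random.default_rng(_sub_seed(seed, 2))
    pat_f = AW_BOX.pattern
    pat_r = AW_BOX.reverse_complement().pattern
    mism = 0
    for _ in range(n_seqs):
        seq = "".join(rng.choice(list("ACGT"), length))
        naive = []
        for pat, strand in ((pat_f, "+"), (pat_r, "-")):
            for i in range(length - len(pat) + 1):
                if all(seq[i + j] in IUPAC_CODES[c]
                       for j, c in enumerate(pat)):
                    naive.append((i, strand))
        if sorted(naive) != scan_region(seq, AW_BOX):
            mism += 1
    return mism


def wilcoxon_vs_enumeration(seed: int = 0, n_cases: int = 20) -> float:
    """Max |error| of the exact rank-sum p against full enumeration of
    rank assignments (tie-free samples, min n <= 8)."""
    rng = np.random.default_rng(_sub_seed(seed, 3))
    worst = 0.0
    for _ in range(n_cases):
        nx, ny = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        pooled = rng.permutation(np.arange(1.0, nx + ny + 1))
        x, y = pooled[:nx], pooled[nx:]
        _, p = wilcoxon_rank_sum(x, y)

        def ustat(xs, ys):
            return sum(float(xi > yj) for xi in xs for yj in ys)

        u_obs, mean_u = ustat(x, y), nx * ny / 2
        hits = total = 0
        for idx in combinations(range(nx + ny), nx):
            xs = pooled[np.array(idx)]
            ys = np.delete(pooled, np.array(idx))
            total += 1
            hits += abs(ustat(xs, ys) - mean_u) >= abs(u_obs - mean_u) - 1e-12
        worst = max(worst, abs(p - hits / total))
    return worst


def bh_worked_example_error() -> float:
    """Max |error| of BH against the hand step-up on (0.01,...,0.04)."""
    q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
    return float(np.abs(q - np.array([0.04, 0.04, 0.04, 0.04])).max())


# ---------------------------------------------------------------------------
# planted-truth recovery

def _strong_signal_config(seed: int, noise: float = 0.0) -> SimulationConfig:
    """>= 2,000 genes / >= 500 peaks in the deterministic-call regime."""
    return SimulationConfig(
        seed=seed, n_genes=2000, n_peaks=500, n_chroms=12,
        chrom_length=1_200_000, noise_fraction=noise,
        planted_fold_change=8.0, nb_dispersion=0.05,
        nb_mean_range=(200.0, 1000.0), n_samples_per_group=4)


def planted_truth_recovery(seed: int = 0) -> dict[str, float]:
    """Bound / coexpressed / DT recovery on a zero-noise dataset, plus
    reproducible-peak recall and precision under 10% replicate noise."""
    cfg = _strong_signal_config(_sub_seed(seed, 4))
    chroms, genes = simulate_genome_annotation(cfg)
    rep_a, rep_b, _, truth = simulate_peaks_and_motifs(chroms, genes, cfg)
    cm, coexpressed_truth = simulate_counts(genes, cfg)
    truth.coexpressed_genes = coexpressed_truth

    repro = reproducible_peaks(rep_a, rep_b)
    bound, _ = assign_peaks_to_genes(repro, genes, cfg.upstream_window)
    tables = [de_results_to_frame(nb_exact_test(cm, sc, em))
              for em in EMBRYO_GROUPS for sc in SEEDCOAT_GROUPS]
    coexpressed = call_coexpressed(tables, fdr_max=0.01)
    dt = call_direct_targets(bound, coexpressed)

    def jaccard(a, b):
        return len(a & b) / len(a | b) if a | b else 1.0

    out = {
        "bound_jaccard": jaccard(bound, truth.bound_genes),
        "coexpressed_jaccard": jaccard(coexpressed, truth.coexpressed_genes),
        "dt_jaccard": jaccard(dt, truth.dt_genes),
        "n_genes": cfg.n_genes,
    }

    noisy = _strong_signal_config(_sub_seed(seed, 5), noise=0.10)
    chroms, genes = simulate_genome_annotation(noisy)
    rep_a, rep_b, _, truth_n = simulate_peaks_and_motifs(chroms, genes, noisy)
    repro = reproducible_peaks(rep_a, rep_b)
    called = {p.name for p in repro}
    planted = {p.name for p in rep_a if p.name.startswith("peakA")}
    out["repro_recall"] = len(called & planted) / len(planted)
    out["repro_precision"] = len(called & planted) / len(called) if called else 0.0
    return out


# ---------------------------------------------------------------------------
# enrichment behaviour

def _enrichment_run(seed: int, plant_rate: float, n_sites: int = 200,
                    workdir: Path | None = None) -> bool:
    cfg = SimulationConfig(seed=seed, n_genes=250, n_peaks=n_sites,
                           n_chroms=2, chrom_length=700_000,
                           motif_plant_rate=plant_rate)
    chroms, genes = simulate_genome_annotation(cfg)
    rep_a, _, _, _ = simulate_peaks_and_motifs(chroms, genes, cfg)
    with tempfile.TemporaryDirectory(dir=workdir) as d:
        write_fasta({c: s.decode() for c, s in chroms.items()},
                    Path(d) / "g.fa")
        fa = read_fasta(Path(d) / "g.fa")
        _, links = assign_peaks_to_genes(rep_a[:n_sites], genes)
        sites = make_binding_sites([l.peak for l in links], fa, 100,
                                   [l.signed_distance_to_tss for l in links])
        bg = sample_matched_background(sites, genes, fa, seed=seed)
        (res,) = motif_enrichment(sites, bg, [cfg.motif])
    return res.significant


def enrichment_significant_runs(seed: int = 0, n_runs: int = 100,
                                plant_rate: float = 0.56) -> int:
    """How many of ``n_runs`` seeded datasets yield Bonferroni-significant
    AW-Box enrichment at the given planting rate."""
    base = _sub_seed(seed, 6 if plant_rate > 0 else 7)
    return sum(_enrichment_run(_sub_seed(base, k), plant_rate)
               for k in range(n_runs))


def geneset_null_experiment(seed: int = 0, n_sets: int = 1000,
                            target_rate: float = 0.70,
                            background_rate: float = 0.40) -> float:
    """Empirical p for a 70%-vs-40% planted gene-set contrast."""
    cfg = SimulationConfig(seed=_sub_seed(seed, 8), n_genes=1000, n_peaks=10,
                           n_chroms=4, chrom_length=1_500_000)
    chroms, genes = simulate_genome_annotation(cfg)
    rng = np.random.default_rng(_sub_seed(seed, 9))
    ids = np.array([g.gene_id for g in genes])
    target = rng.choice(ids, 300, replace=False)
    rest = np.setdiff1d(ids, target)
    plant_motif_in_gene_regions(
        chroms, genes, rng.choice(target, int(target_rate * len(target)),
                                  replace=False), AW_BOX, rng)
    plant_motif_in_gene_regions(
        chroms, genes, rng.choice(rest, int(background_rate * len(rest)),
                                  replace=False), AW_BOX, rng)
    with tempfile.TemporaryDirectory() as d:
        write_fasta({c: s.decode() for c, s in chroms.items()},
                    Path(d) / "g.fa")
        fa = read_fasta(Path(d) / "g.fa")
        _, _, p = geneset_motif_background(
            sorted(target), genes, fa, AW_BOX, "downstream", 500,
            n_sets, seed=_sub_seed(seed, 10))
    return p


# ---------------------------------------------------------------------------
# statistical calibration

def nb_calibration(seed: int = 0) -> dict[str, float]:
    """Type-I error (2,000 null genes) and 4-fold power at the reference
    NB conditions (mean 100, dispersion 0.1, 3 vs 3)."""
    rng = np.random.default_rng(_sub_seed(seed, 11))
    groups = {f"s{j}": ("A" if j < 3 else "B") for j in range(6)}
    r = 10.0
    null = rng.negative_binomial(r, r / (r + 100.0), size=(2000, 6))
    cm = CountMatrix(pd.DataFrame(null, index=[f"g{i}" for i in range(2000)],
                                  columns=list(groups)), groups)
    p = np.array([x.pvalue for x in nb_exact_test(cm, "A", "B")])
    type1 = float((p < 0.05).mean())

    n = 1000
    true = rng.choice(n, 100, replace=False)
    mu_b = np.full(n, 100.0)
    mu_b[true] *= 4
    a = rng.negative_binomial(r, r / (r + 100.0), size=(n, 3))
    b = rng.negative_binomial(r, (r / (r + mu_b))[:, None], size=(n, 3))
    cm = CountMatrix(pd.DataFrame(np.hstack([a, b]),
                                  index=[f"g{i}" for i in range(n)],
                                  columns=list(groups)), groups)
    fdr = np.array([x.fdr for x in nb_exact_test(cm, "A", "B")])
    power = float((fdr[true] < 0.05).mean())
    return {"type1_error": type1, "power": power, "n_null": 2000}


def tmm_scaling_recovery(seed: int = 0, n_genes: int = 3000) -> float:
    """log2 factor difference recovered for a planted 2x library scaling
    (Poisson depth noise on a common expression profile)."""
    rng = np.random.default_rng(_sub_seed(seed, 12))
    base = rng.uniform(20, 300, n_genes)
    a = rng.poisson(base)
    b = rng.poisson(2 * base)
    df = pd.DataFrame({"A": a, "B": b}, index=[f"g{i}" for i in range(n_genes)])
    f = tmm_factors(df)
    return float(np.log2(f["B"] / f["A"]))


# ---------------------------------------------------------------------------
# structural invariants

def structural_invariants(seed: int = 0) -> dict[str, float]:
    """Feature-fraction partition, reverse-complement scan invariance,
    fragment-length recovery, and planted two-TF median distance."""
    cfg = SimulationConfig(seed=_sub_seed(seed, 13), n_genes=600, n_peaks=500,
                           n_chroms=6, chrom_length=700_000)
    chroms, genes = simulate_genome_annotation(cfg)
    rep_a, rep_b, tf_b, truth = simulate_peaks_and_motifs(chroms, genes, cfg)

    rng = np.random.default_rng(_sub_seed(seed, 14))
    from .genome_io import GenomicInterval, PeakRecord
    fuzz = [PeakRecord(GenomicInterval("chr1", int(s), int(s) + 100),
                       int(s) + 50) for s in rng.integers(0, 600_000, 500)]
    feat = annotate_peak_features(fuzz, genes)
    frac_sum = float(sum(feat.fractions.values()))

    seq = "".join(rng.choice(list("ACGT"), 5000))
    rc_diff = abs(len(scan_region(seq, AW_BOX))
                  - len(scan_region(reverse_complement(seq), AW_BOX)))

    chr1 = {"chr1": chroms["chr1"]}
    tags = simulate_tags([p for p in rep_a if p.interval.chrom == "chr1"],
                         chr1, cfg, fragment_length=150)
    plus, minus = tag_start_vectors(tags, "chr1", cfg.chrom_length)
    qc = strand_cross_correlation(plus, minus, range(50, 301, 2),
                                  read_length=36)

    dists, med, _, _, _ = peak_distance_between_tfs(rep_a, tf_b)
    planted_median = float(np.median(np.abs(truth.tf_b_offsets)))
    return {
        "feature_fraction_sum": frac_sum,
        "revcomp_match_count_diff": float(rc_diff),
        "fragment_length_error_bp": abs(qc.fragment_length_estimate - 150),
        "tf_median_distance": float(med),
        "planted_median_distance": planted_median,
        "n_tf_peaks": len(dists),
    }
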