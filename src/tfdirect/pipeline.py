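"""End-to-end orchestration: peaks + counts -> direct-target report.

``run_full_pipeline`` wires the stages together — QC (when tag data are
supplied), replicate reconciliation, peak-to-gene assignment, differential
expression over the four tissue contrasts (or injected DE tables),
coexpression and direct-target calls, gene-set overlap, motif enrichment
against matched random regions, positional profiles, and the optional
second-TF comparison — and writes a deterministic JSON report plus TSV
tables.  Identical config + seed give byte-identical reports.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expression import (CountMatrix, call_coexpressed, call_direct_targets,
                         de_results_to_frame, nb_exact_test)
from .genome_io import read_fasta, read_gff3, read_narrowpeak
from .motifs import (DEFAULT_MOTIF_PANEL, make_binding_sites, motif_enrichment,
                     read_motif_panel, sample_matched_background)
from .peaks import (annotate_peak_features, assign_peaks_to_genes,
                    nonredundant_fraction, peak_distance_between_tfs,
                    peak_position_profile, reproducible_peaks)
from .setstats import hypergeometric_overlap

__all__ = ["PipelineConfig", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run (defaults = study thresholds)."""

    genome: str
    annotation: str
    peaks_rep1: str
    peaks_rep2: str
    counts: str | None = None
    sample_groups: str | None = None
    de_tables: list[str] | None = None        # inject externally computed DE
    contrasts: list[list[str]] | None = None  # [denominator, numerator] pairs
    peaks_tf_b: str | None = None
    gene_set: str | None = None               # e.g. the FAT gene list
    motif_panel: str | None = None
    tags: str | None = None                   # chrom<TAB>pos<TAB>strand

    upstream_window: int = 1000
    site_width: int = 100
    two_tf_site_width: int = 50
    min_fold: float = 2.0
    coexpress_fdr: float = 0.01
    de_fdr: float = 0.05
    min_contrasts: int = 2
    bonferroni_alpha: float = 0.01
    geneset_n: int = 1000
    tss_window: int = 500
    profile_bin: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _read_gene_set(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def _default_contrasts(groups: dict[str, str]) -> list[list[str]]:
    """Every (seed-coat-like, embryo-like) pairing, by label convention."""
    labels = sorted(set(groups.values()))
    embryo = [g for g in labels if g.startswith("embryo")]
    seedcoat = [g for g in labels if g.startswith("seedcoat")]
    if not embryo or not seedcoat:
        raise ValueError(
            "cannot infer contrasts from group labels; set 'contrasts'")
    return [[sc, em] for em in embryo for sc in seedcoat]


def run_full_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; write report.json + TSVs; return the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {"config_sha256": config.digest(), "seed": config.seed,
                       "version": __version__},
        "counts": {},
    }

    genome = read_fasta(config.genome)
    genes = read_gff3(config.annotation)
    rep_a = read_narrowpeak(config.peaks_rep1)
    rep_b = read_narrowpeak(config.peaks_rep2)
    universe = {g.gene_id for g in genes}

    # optional QC
    if config.tags:
        tags = [(c, int(p), s) for c, p, s in
                (line.split("\t") for line in
                 Path(config.tags).read_text().splitlines() if line)]
        report["qc"] = {"nrf": nonredundant_fraction(tags)}

    # replicate reconciliation and binding
    repro = reproducible_peaks(rep_a, rep_b)
    bound, links = assign_peaks_to_genes(repro, genes, config.upstream_window)
    feat = annotate_peak_features(repro, genes)
    edges, hist = peak_position_profile(links, config.profile_bin)
    pd.DataFrame({
        "peak": [l.peak.name for l in links],
        "gene": [l.gene_id for l in links],
        "distance_to_tss": [l.signed_distance_to_tss for l in links],
        "zone": [l.zone for l in links],
    }).to_csv(outdir / "peak_gene_links.tsv", sep="\t", index=False)
    pd.DataFrame({"bin_start": edges[:-1], "count": hist}).to_csv(
        outdir / "peak_position_profile.tsv", sep="\t", index=False)
    report["feature_fractions"] = {k: round(v, 6)
                                   for k, v in feat.fractions.items()}

    # differential expression / coexpression
    coexpressed: set[str] = set()
    if config.de_tables:
        tables = [pd.read_csv(p, sep="\t", index_col=0) for p in config.de_tables]
    elif config.counts:
        groups = pd.read_csv(config.sample_groups, sep="\t",
                             index_col=0)["group"].to_dict()
        cm = CountMatrix.from_tsv(config.counts, groups)
        contrasts = config.contrasts or _default_contrasts(groups)
        tables = []
        for denom, num in contrasts:
            res = nb_exact_test(cm, denom, num)
            tab = de_results_to_frame(res)
            tab.to_csv(outdir / f"de_{num}_vs_{denom}.tsv", sep="\t")
            tables.append(tab)
    else:
        tables = []
    if tables:
        coexpressed = call_coexpressed(
            tables, config.min_fold, config.coexpress_fdr, config.min_contrasts)
    dt = call_direct_targets(bound, coexpressed)

    for name, s in (("bound_genes", bound), ("coexpressed_genes", coexpressed),
                    ("dt_genes", dt)):
        (outdir / f"{name}.txt").write_text(
            "".join(f"{g}\n" for g in sorted(s)))

    # gene-set (e.g. FAT) overlap with the direct targets
    if config.gene_set:
        gs = _read_gene_set(config.gene_set) & universe
        ov = hypergeometric_overlap(gs, dt, universe)
        report["gene_set_overlap"] = {
            "n_universe": ov.n_universe, "n_gene_set": ov.n_a,
            "n_dt": ov.n_b, "n_overlap": ov.n_overlap,
            "expected_overlap": round(ov.expected_overlap, 4),
            "pvalue_upper": ov.pvalue_upper,
        }

    # motif enrichment in binding sites vs matched random regions
    motifs = (read_motif_panel(config.motif_panel) if config.motif_panel
              else list(DEFAULT_MOTIF_PANEL))
    dt_links = [l for l in links if l.gene_id in dt] or links
    site_peaks = [l.peak for l in dt_links]
    site_offsets = [l.signed_distance_to_tss for l in dt_links]
    enr_rows = []
    if site_peaks:
        sites = make_binding_sites(site_peaks, genome, config.site_width,
                                   site_offsets)
        background = sample_matched_background(sites, genes, genome,
                                               seed=config.seed)
        for r in motif_enrichment(sites, background, motifs,
                                  alpha=config.bonferroni_alpha):
            enr_rows.append({
                "motif": r.motif, "observed_fraction": round(r.observed_fraction, 4),
                "background_fraction": round(r.background_fraction, 4),
                "pvalue": r.pvalue, "adjusted_pvalue": r.adjusted_pvalue,
                "significant": bool(r.significant)})
        pd.DataFrame(enr_rows).to_csv(outdir / "motif_enrichment.tsv",
                                      sep="\t", index=False)
    report["motif_enrichment"] = enr_rows

    # optional second-TF comparison
    if config.peaks_tf_b:
        tf_b = read_narrowpeak(config.peaks_tf_b)
        dists, med, dmin, dmax, excl = peak_distance_between_tfs(
            [l.peak for l in dt_links], tf_b)
        pd.Series(dists, name="distance").to_csv(
            outdir / "tf_tf_distances.tsv", sep="\t", index=False)
        bound_b, _ = assign_peaks_to_genes(tf_b, genes, config.upstream_window)
        two_tf = {"median_distance": med, "min_distance": dmin,
                  "max_distance": dmax, "n_excluded": excl,
                  "n_dt_bound_by_tf_b": len(dt & bound_b)}
        for label, subset in (("tf_b_bound", dt & bound_b),
                              ("tf_b_unbound", dt - bound_b)):
            sub = [l for l in dt_links if l.gene_id in subset]
            if not sub:
                continue
            sites = make_binding_sites(
                [l.peak for l in sub], genome, config.two_tf_site_width,
                [l.signed_distance_to_tss for l in sub])
            bg = sample_matched_background(sites, genes, genome,
                                           seed=config.seed + 1)
            two_tf[f"enrichment_{label}"] = [
                {"motif": r.motif,
                 "observed_fraction": round(r.observed_fraction, 4),
                 "adjusted_pvalue": r.adjusted_pvalue,
                 "significant": bool(r.significant)}
                for r in motif_enrichment(sites, bg, motifs,
                                          alpha=config.bonferroni_alpha)]
        report["two_tf"] = two_tf

    report["counts"] = {
        "peaks_rep1": len(rep_a), "peaks_rep2": len(rep_b),
        "reproducible_peaks": len(repro), "bound_genes": len(bound),
        "coexpressed_genes": len(coexpressed), "dt_genes": len(dt),
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
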