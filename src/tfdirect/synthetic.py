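"""Synthetic genomes, peaks, motifs and counts with planted ground truth.

The generator emulates the statistical structure of a TF ChIP-Seq /
tissue-contrast coexpression study: peaks concentrated downstream of gene
TSSs, degenerate-motif instances planted into a controlled fraction of
binding-site sequences, negative-binomial counts with fold-change effects
planted in embryo-like vs seed-coat-like tissue groups, and a second TF
whose summits sit at controlled signed offsets from the first TF's.

One global seed drives every stage through numpy SeedSequence spawning:
stage ``k`` uses ``default_rng([seed, k])``, so stages are independent and
the whole dataset is bit-reproducible.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .genome_io import (GeneModel, GenomicInterval, PeakRecord,
                        write_fasta, write_gff3, write_narrowpeak)
from .motifs import IUPACMotif, IUPAC_CODES

__all__ = [
    "MixtureComponent",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genome_annotation",
    "simulate_peaks_and_motifs",
    "simulate_counts",
    "simulate_tags",
    "simulate_dataset",
]

# rng stream indices per stage (stream-splitting scheme)
_STREAM_GENOME, _STREAM_PEAKS, _STREAM_COUNTS, _STREAM_TAGS = 0, 1, 2, 3


@dataclass(frozen=True)
class MixtureComponent:
    """One component of an offset mixture: normal, uniform or signed_exponential."""

    weight: float
    kind: str            # normal | uniform | signed_exponential
    params: tuple        # normal: (mu, sd); uniform: (lo, hi);
                         # signed_exponential: (median_abs,)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "normal":
            return rng.normal(self.params[0], self.params[1], n)
        if self.kind == "uniform":
            return rng.uniform(self.params[0], self.params[1], n)
        if self.kind == "signed_exponential":
            scale = self.params[0] / np.log(2.0)
            mag = rng.exponential(scale, n)
            sign = rng.choice([-1.0, 1.0], n)
            return sign * mag
        raise ValueError(f"unknown mixture kind {self.kind!r}")


def sample_mixture(components: list[MixtureComponent],
                   rng: np.random.Generator, n: int) -> np.ndarray:
    w = np.array([c.weight for c in components], dtype=float)
    w /= w.sum()
    which = rng.choice(len(components), size=n, p=w)
    out = np.empty(n)
    for i, c in enumerate(components):
        m = which == i
        out[m] = c.sample(rng, int(m.sum()))
    return np.rint(out).astype(int)


# study-condition defaults: binding predominantly downstream of the TSS,
# a second TF at a median absolute offset of 142 bp from the first
DEFAULT_PEAK_OFFSETS = [
    MixtureComponent(0.8, "normal", (300.0, 150.0)),
    MixtureComponent(0.2, "uniform", (-1000.0, -1.0)),
]
DEFAULT_TFB_OFFSETS = [MixtureComponent(1.0, "signed_exponential", (142.0,))]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (1500, 4000)
    gene_spacing: int = 2500
    gc_content: float = 0.38
    n_peaks: int = 60
    peak_width: int = 200
    peak_offset_distribution: list[MixtureComponent] = field(
        default_factory=lambda: list(DEFAULT_PEAK_OFFSETS))
    upstream_window: int = 1000
    motif: IUPACMotif = field(
        default_factory=lambda: IUPACMotif("AW-Box", "CNTNGNNNNNNNCG"))
    motif_plant_rate: float = 0.56
    replicate_jitter: int = 10
    noise_fraction: float = 0.0
    n_samples_per_group: int = 3
    nb_mean_range: tuple[float, float] = (50.0, 500.0)
    nb_dispersion: float = 0.1
    planted_fold_change: float = 4.0
    fraction_coexpressed: float = 0.3
    second_tf_offset_distribution: list[MixtureComponent] = field(
        default_factory=lambda: list(DEFAULT_TFB_OFFSETS))

    def __post_init__(self) -> None:
        for name in ("gc_content", "motif_plant_rate", "noise_fraction",
                     "fraction_coexpressed"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if self.planted_fold_change < 1:
            raise ValueError("planted_fold_change must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SyntheticTruth:
    """Planted ground truth for every downstream stage."""

    bound_genes: set[str]
    coexpressed_genes: set[str]
    motif_bearing_sites: set[str]
    tf_b_offsets: list[int]

    @property
    def dt_genes(self) -> set[str]:
        return self.bound_genes & self.coexpressed_genes

    def to_json(self, path) -> None:
        obj = {
            "bound_genes": sorted(self.bound_genes),
            "coexpressed_genes": sorted(self.coexpressed_genes),
            "dt_genes": sorted(self.dt_genes),
            "motif_bearing_sites": sorted(self.motif_bearing_sites),
            "tf_b_offsets": list(map(int, self.tf_b_offsets)),
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        obj = json.loads(Path(path).read_text())
        return cls(set(obj["bound_genes"]), set(obj["coexpressed_genes"]),
                   set(obj["motif_bearing_sites"]), obj["tf_b_offsets"])


def simulate_genome_annotation(config: SimulationConfig
                               ) -> tuple[dict[str, bytearray], list[GeneModel]]:
    """Random genome plus non-overlapping genes with alternating strands.

    Bases are i.i.d. at the configured GC fraction; genes are laid out
    left to right with a fixed spacing margin so that no gene's upstream
    window reaches a neighbour.  Returns mutable chromosome sequences
    (motif planting edits them in place) and the gene models.
    """
    rng = config.rng(_STREAM_GENOME)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms = {
        f"chr{i + 1}": bytearray(
            rng.choice(bases, size=config.chrom_length, p=p).tobytes())
        for i in range(config.n_chroms)
    }

    genes: list[GeneModel] = []
    gi = 0
    chrom_names = list(chroms)
    for ci, chrom in enumerate(chrom_names):
        # per-chromosome quota, re-balanced so shortfalls roll forward
        quota = -(-(config.n_genes - gi) // (config.n_chroms - ci))
        cursor = config.gene_spacing
        for _ in range(quota):
            if gi >= config.n_genes:
                break
            length = int(rng.integers(config.gene_length_range[0],
                                      config.gene_length_range[1] + 1))
            if cursor + length + config.gene_spacing > config.chrom_length:
                break
            strand = "+" if gi % 2 == 0 else "-"
            iv = GenomicInterval(chrom, cursor, cursor + length, strand)
            genes.append(_build_gene_model(f"gene{gi:05d}", iv, rng))
            cursor += length + config.gene_spacing
            gi += 1
    if gi < config.n_genes:
        raise ValueError(
            f"could not place {config.n_genes} genes without overlap "
            f"(placed {gi}); increase chrom_length or n_chroms")
    return chroms, genes


def _build_gene_model(gene_id: str, iv: GenomicInterval,
                      rng: np.random.Generator) -> GeneModel:
    """Random 1-3 exon structure with terminal UTRs inside the first/last exon."""
    n_exons = int(rng.integers(1, 4))
    length = len(iv)
    if n_exons == 1:
        exons = [iv]
    else:
        # exon/intron boundaries: interior cut points, alternating
        cuts = np.sort(rng.choice(
            np.arange(100, length - 100), size=2 * (n_exons - 1), replace=False))
        edges = [0, *cuts.tolist(), length]
        exons = [GenomicInterval(iv.chrom, iv.start + edges[2 * k],
                                 iv.start + edges[2 * k + 1], iv.strand)
                 for k in range(n_exons)]
    first, last = exons[0], exons[-1]
    u_len5 = max(1, int(0.15 * len(first if iv.strand != "-" else last)))
    u_len3 = max(1, int(0.15 * len(last if iv.strand != "-" else first)))
    if iv.strand != "-":
        utr5 = [GenomicInterval(iv.chrom, first.start, first.start + u_len5, iv.strand)]
        utr3 = [GenomicInterval(iv.chrom, last.end - u_len3, last.end, iv.strand)]
    else:
        utr5 = [GenomicInterval(iv.chrom, last.end - u_len5, last.end, iv.strand)]
        utr3 = [GenomicInterval(iv.chrom, first.start, first.start + u_len3, iv.strand)]
    return GeneModel(gene_id, iv, exons=exons, utr5=utr5, utr3=utr3)


def _resolve_motif(motif: IUPACMotif, rng: np.random.Generator) -> str:
    """A concrete instance: degenerate positions resolved uniformly."""
    return "".join(
        rng.choice(sorted(IUPAC_CODES[c])) if len(IUPAC_CODES[c]) > 1 else c
        for c in motif.pattern)


def simulate_peaks_and_motifs(chroms: dict[str, bytearray],
                              genes: list[GeneModel],
                              config: SimulationConfig):
    """Plant TF-A peaks at TSS-relative offsets, motifs, replicates, TF-B.

    Returns ``(rep_a, rep_b, tf_b_peaks, truth)``.  Each planted peak is
    attached to a distinct gene with its summit at a draw from the offset
    mixture, clipped into the gene's bound window (1 kb upstream through
    the gene body) so planted binding is recoverable exactly.  A fraction
    ``motif_plant_rate`` of peaks has a concrete motif instance written
    into the genome under the summit.  Replicate B jitters boundaries by
    <= ``replicate_jitter`` bp; both replicates additionally receive
    ``noise_fraction`` replicate-unique intergenic peaks.  TF-B summits
    are TF-A summits plus draws from the second-TF offset mixture.
    """
    if config.n_peaks > len(genes):
        raise ValueError("n_peaks exceeds n_genes: peaks are one per gene")
    if len(config.motif) > config.peak_width:
        raise ValueError("motif longer than the peak window")
    rng = config.rng(_STREAM_PEAKS)
    half = config.peak_width // 2

    chosen = rng.choice(len(genes), size=config.n_peaks, replace=False)
    offsets = sample_mixture(config.peak_offset_distribution, rng,
                             config.n_peaks)
    rep_a: list[PeakRecord] = []
    motif_sites: set[str] = set()
    for k, (gidx, off) in enumerate(zip(chosen, offsets)):
        g = genes[int(gidx)]
        off = int(np.clip(off, -config.upstream_window, len(g.interval) - 1))
        summit = g.tss + off if g.strand != "-" else g.tss - off
        chrom_len = len(chroms[g.interval.chrom])
        summit = int(np.clip(summit, half, chrom_len - half - 1))
        name = f"peakA_{k:05d}"
        iv = GenomicInterval(g.interval.chrom, summit - half, summit + half, ".")
        rep_a.append(PeakRecord(iv, summit, 100.0, name))
        if rng.random() < config.motif_plant_rate:
            inst = _resolve_motif(config.motif, rng)
            pos = summit - len(inst) // 2
            chroms[g.interval.chrom][pos:pos + len(inst)] = inst.encode()
            motif_sites.add(name)

    # replicate B: jittered boundaries, same summits
    rep_b: list[PeakRecord] = []
    for k, p in enumerate(rep_a):
        j1 = int(rng.integers(-config.replicate_jitter, config.replicate_jitter + 1))
        j2 = int(rng.integers(-config.replicate_jitter, config.replicate_jitter + 1))
        start = max(0, min(p.interval.start + j1, p.summit))
        end = max(p.summit + 1, p.interval.end + j2)
        rep_b.append(PeakRecord(
            GenomicInterval(p.interval.chrom, start, end, "."),
            p.summit, p.score, f"peakB_{k:05d}"))

    # replicate-unique noise peaks in intergenic space, far from true peaks
    n_noise = int(round(config.noise_fraction * config.n_peaks))
    if n_noise:
        spots = _intergenic_spots(chroms, genes, config, rng, 2 * n_noise)
        for i, s in enumerate(spots[:n_noise]):
            iv = GenomicInterval(s[0], s[1] - half, s[1] + half, ".")
            rep_a.append(PeakRecord(iv, s[1], 10.0, f"noiseA_{i:05d}"))
        for i, s in enumerate(spots[n_noise:]):
            iv = GenomicInterval(s[0], s[1] - half, s[1] + half, ".")
            rep_b.append(PeakRecord(iv, s[1], 10.0, f"noiseB_{i:05d}"))

    # second TF at controlled offsets from TF-A summits
    tfb_offsets = sample_mixture(config.second_tf_offset_distribution, rng,
                                 config.n_peaks)
    tf_b: list[PeakRecord] = []
    kept_offsets: list[int] = []
    for k in range(config.n_peaks):
        p = rep_a[k]
        chrom_len = len(chroms[p.interval.chrom])
        summit = int(np.clip(p.summit + int(tfb_offsets[k]),
                             half, chrom_len - half - 1))
        kept_offsets.append(summit - p.summit)
        iv = GenomicInterval(p.interval.chrom, summit - half, summit + half, ".")
        tf_b.append(PeakRecord(iv, summit, 100.0, f"peakTFB_{k:05d}"))

    key = lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
    rep_a.sort(key=key)
    rep_b.sort(key=key)
    tf_b.sort(key=key)
    truth = SyntheticTruth(
        bound_genes={genes[int(i)].gene_id for i in chosen},
        coexpressed_genes=set(),      # filled by simulate_counts
        motif_bearing_sites=motif_sites,
        tf_b_offsets=kept_offsets)
    return rep_a, rep_b, tf_b, truth


def _intergenic_spots(chroms, genes, config, rng, n):
    """Positions whose peak window stays clear of every gene's bound window."""
    margin = config.upstream_window + config.peak_width
    spots = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        occupied.setdefault(g.interval.chrom, []).append(
            (g.interval.start - margin, g.interval.end + margin))
    names = list(chroms)
    attempts = 0
    while len(spots) < n and attempts < 100 * n:
        attempts += 1
        chrom = names[int(rng.integers(len(names)))]
        pos = int(rng.integers(config.peak_width, len(chroms[chrom]) - config.peak_width))
        if any(a <= pos < b for a, b in occupied.get(chrom, ())):
            continue
        occupied.setdefault(chrom, []).append(
            (pos - config.peak_width, pos + config.peak_width))
        spots.append((chrom, pos))
    if len(spots) < n:
        raise RuntimeError("could not place noise peaks in intergenic space")
    return spots


def plant_motif_in_gene_regions(chroms: dict[str, bytearray],
                                genes: list[GeneModel], gene_ids,
                                motif: IUPACMotif,
                                rng: np.random.Generator,
                                side: str = "downstream",
                                width: int = 500) -> None:
    """Write one resolved motif instance into each listed gene's TSS window.

    The instance lands at a uniform start within the ``width`` bp window
    on the given strand-aware side of the TSS (on the gene's strand, so a
    double-strand scan always finds it).
    """
    wanted = set(gene_ids)
    m = len(motif)
    for g in genes:
        if g.gene_id not in wanted:
            continue
        inst = _resolve_motif(motif, rng)
        if g.strand == "-":
            from .genome_io import reverse_complement
            inst = reverse_complement(inst)
        off = int(rng.integers(0, width - m))
        if g.strand != "-":
            start = g.tss + off if side == "downstream" else g.tss - width + off
        else:
            start = (g.tss - off - m + 1 if side == "downstream"
                     else g.tss + 1 + off)
        seq = chroms[g.interval.chrom]
        if 0 <= start and start + m <= len(seq):
            seq[start:start + m] = inst.encode()


GROUPS = ("embryo_abaxial", "embryo_adaxial", "seedcoat_hilum",
          "seedcoat_parenchyma")
EMBRYO_GROUPS = GROUPS[:2]
SEEDCOAT_GROUPS = GROUPS[2:]


def simulate_counts(genes: list[GeneModel], config: SimulationConfig
                    ) -> tuple[CountMatrix, set[str]]:
    """NB counts for four tissue groups with planted embryo up-regulation.

    A ``fraction_coexpressed`` subset of genes has its mean multiplied by
    ``planted_fold_change`` in the two embryo-like groups.  Returns the
    count matrix and the planted coexpressed gene set.
    """
    if config.n_samples_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    if config.nb_dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = config.rng(_STREAM_COUNTS)
    gene_ids = [g.gene_id for g in genes]
    lo, hi = config.nb_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), len(gene_ids)))

    n_co = int(round(config.fraction_coexpressed * len(gene_ids)))
    co_idx = rng.choice(len(gene_ids), size=n_co, replace=False) \
        if config.planted_fold_change > 1 else np.empty(0, dtype=int)
    coexpressed = {gene_ids[int(i)] for i in co_idx}

    r = 1.0 / config.nb_dispersion
    cols, data, groups = [], [], {}
    for group in GROUPS:
        mu = base_mean.copy()
        if group in EMBRYO_GROUPS and len(co_idx):
            mu[co_idx] *= config.planted_fold_change
        for rep in range(config.n_samples_per_group):
            sample = f"{group}_r{rep + 1}"
            cols.append(sample)
            groups[sample] = group
            data.append(rng.negative_binomial(r, r / (r + mu)))
    counts = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    return CountMatrix(counts, groups), coexpressed


def simulate_tags(peaks, chroms, config: SimulationConfig,
                  fragment_length: int = 150, tags_per_peak: int = 50,
                  pos_sd: float = 20.0):
    """Strand-aware tag 5' positions for QC metrics.

    Plus-strand tags start near ``summit - fragment_length/2``; minus
    tags near ``summit + fragment_length/2``, so the strand
    cross-correlation peaks at the fragment length.
    """
    rng = config.rng(_STREAM_TAGS)
    tags = []
    for p in peaks:
        chrom_len = len(chroms[p.interval.chrom])
        jit = rng.normal(0, pos_sd, tags_per_peak)
        plus = np.clip(np.rint(p.summit - fragment_length / 2 + jit), 0,
                       chrom_len - 1).astype(int)
        minus = np.clip(plus + fragment_length, 0, chrom_len - 1)
        for pp, mm in zip(plus, minus):
            tags.append((p.interval.chrom, int(pp), "+"))
            tags.append((p.interval.chrom, int(mm), "-"))
    return tags


def simulate_dataset(config: SimulationConfig, outdir) -> SyntheticTruth:
    """Run all stages and write FASTA/GFF3/narrowPeak/TSV/JSON to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chroms, genes = simulate_genome_annotation(config)
    rep_a, rep_b, tf_b, truth = simulate_peaks_and_motifs(chroms, genes, config)
    cm, coexpressed = simulate_counts(genes, config)
    truth.coexpressed_genes = coexpressed

    write_fasta({c: s.decode() for c, s in chroms.items()}, outdir / "genome.fa")
    write_gff3(genes, outdir / "annotation.gff3")
    write_narrowpeak(rep_a, outdir / "tfa_rep1.narrowPeak")
    write_narrowpeak(rep_b, outdir / "tfa_rep2.narrowPeak")
    write_narrowpeak(tf_b, outdir / "tfb.narrowPeak")
    cm.to_tsv(outdir / "counts.tsv")
    pd.Series(cm.groups).rename("group").to_csv(
        outdir / "sample_groups.tsv", sep="\t", index_label="sample")
    truth.to_json(outdir / "truth.json")
    return truth
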