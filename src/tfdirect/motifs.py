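"""Degenerate IUPAC motif scanning and the two constructed enrichment nulls.

Scanning is double-stranded by default: a region contains a motif if the
consensus matches the forward sequence or its reverse complement.  Two
background constructions are provided for enrichment testing:

* matched random regions — for each binding site, a region of identical
  width at the same strand-aware TSS offset of a random gene, controlling
  for both size and the positional bias of binding sites; and
* the empirical gene-set null — the motif-positive fraction of N random
  gene sets of matched size, yielding an empirical tail probability.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genome_io import (GeneModel, GenomicInterval, fetch_sequence,
                        reverse_complement)

__all__ = [
    "IUPAC_CODES",
    "IUPACMotif",
    "BindingSite",
    "EnrichmentResult",
    "scan_region",
    "make_binding_sites",
    "sample_matched_background",
    "motif_enrichment",
    "geneset_motif_background",
    "motif_positional_distribution",
    "read_motif_panel",
    "DEFAULT_MOTIF_PANEL",
]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# base -> row index in the match table; N is a distinct symbol that only
# the motif code N accepts.
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate nucleotide consensus, e.g. the AW Box CNTNGNNNNNNNCG."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC codes in {self.name}: {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)

    def reverse_complement(self) -> "IUPACMotif":
        rc = self.pattern.translate(_IUPAC_COMPLEMENT)[::-1]
        return IUPACMotif(self.name, rc)

    def _table(self) -> np.ndarray:
        """Boolean (motif length x 5) table over A,C,G,T,N sequence symbols."""
        tab = np.zeros((len(self.pattern), 5), dtype=bool)
        for j, code in enumerate(self.pattern):
            for b in IUPAC_CODES[code]:
                tab[j, _BASE_INDEX[b]] = True
            if code == "N":       # sequence N matches only motif code N
                tab[j, 4] = True
        return tab


DEFAULT_MOTIF_PANEL: list[IUPACMotif] = [
    IUPACMotif("AW-Box", "CNTNGNNNNNNNCG"),
    IUPACMotif("CNC-Box", "CNCCNCC"),
    IUPACMotif("G-Box", "CACGTG"),
    IUPACMotif("RY", "CATGCA"),
    IUPACMotif("CCAAT-Box", "CCAAT"),
]

SHORT_AW_BOX = IUPACMotif("short-AW-Box", "CNTNGNNNNNNCG")


def chance_match_probability(motif: IUPACMotif,
                             base_probs: dict[str, float],
                             seq_len: int, both_strands: bool = True) -> float:
    """Approximate probability that an i.i.d. sequence contains the motif.

    The per-position start probability is the product over motif positions
    of the probability that a random base falls in the position's IUPAC
    set; the region-level probability treats the 2*(L - m + 1) start
    positions (both strands) as independent, which is accurate for rare
    motifs.
    """
    p1 = 1.0
    for code in motif.pattern:
        p1 *= sum(base_probs[b] for b in IUPAC_CODES[code])
    n_starts = max(0, seq_len - len(motif) + 1)
    if both_strands:
        rc = motif.reverse_complement()
        p1rc = 1.0
        for code in rc.pattern:
            p1rc *= sum(base_probs[b] for b in IUPAC_CODES[code])
        return 1.0 - (1.0 - p1) ** n_starts * (1.0 - p1rc) ** n_starts
    return 1.0 - (1.0 - p1) ** n_starts


def read_motif_panel(path) -> list[IUPACMotif]:
    """Read a ``name<TAB>IUPAC`` panel file."""
    panel = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, pattern = line.split("\t")
            panel.append(IUPACMotif(name, pattern))
    return panel


def _encode(sequence: str) -> np.ndarray:
    arr = _BASE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({sequence[i] for i in np.flatnonzero(arr < 0)[:5]})
        raise ValueError(f"invalid bases in sequence: {bad}")
    return arr


def _match_starts(encoded: np.ndarray, motif: IUPACMotif) -> np.ndarray:
    m = len(motif)
    n = encoded.size
    if n < m:
        return np.empty(0, dtype=np.intp)
    tab = motif._table()
    ok = tab[0, encoded[: n - m + 1]]
    for j in range(1, m):
        ok &= tab[j, encoded[j: n - m + 1 + j]]
    return np.flatnonzero(ok)


def scan_region(sequence: str, motif: IUPACMotif,
                both_strands: bool = True) -> list[tuple[int, str]]:
    """All (offset, strand) matches of a degenerate consensus in a sequence.

    Offsets are 0-based starts on the forward sequence; minus-strand
    matches are matches of the reverse-complement pattern.  An N in the
    sequence is matched only by the motif code N.
    """
    enc = _encode(sequence)
    hits = [(int(i), "+") for i in _match_starts(enc, motif)]
    if both_strands:
        hits += [(int(i), "-") for i in _match_starts(enc, motif.reverse_complement())]
    return sorted(hits)


def region_has_motif(sequence: str, motif: IUPACMotif,
                     both_strands: bool = True) -> bool:
    return bool(scan_region(sequence, motif, both_strands))


# ---------------------------------------------------------------------------
# Binding sites and matched backgrounds

@dataclass
class BindingSite:
    """Fixed-width window centered on a peak summit, with its sequence.

    ``tss_offset`` is the strand-aware signed distance of the summit from
    the TSS of the gene the peak was assigned to (used to place matched
    background regions).
    """

    interval: GenomicInterval
    sequence: str
    tss_offset: int | None = None


def make_binding_sites(peaks, genome, width: int = 100,
                       offsets: Sequence[int] | None = None) -> list[BindingSite]:
    """Cut ``width`` bp windows around peak summits (clipped at chrom ends)."""
    half = width // 2
    sites = []
    for i, p in enumerate(peaks):
        chrom = p.interval.chrom
        chrom_len = len(genome[chrom])
        start = max(0, min(p.summit - half, chrom_len - width))
        iv = GenomicInterval(chrom, start, start + width, "+")
        off = None if offsets is None else int(offsets[i])
        sites.append(BindingSite(iv, fetch_sequence(genome, iv), off))
    return sites


def sample_matched_background(sites: Sequence[BindingSite],
                              genes: Sequence[GeneModel], genome,
                              n_per_site: int = 1, seed: int = 0,
                              max_attempts: int = 1000) -> list[BindingSite]:
    """Random regions of identical width at matched TSS offsets.

    For each site, a random gene is drawn uniformly and a region of the
    site's width is centered at the site's signed offset from that gene's
    TSS (strand-aware); out-of-bounds placements are rejection-resampled.
    """
    rng = np.random.default_rng(seed)
    out = []
    for k, site in enumerate(sites):
        width = len(site.interval)
        offset = site.tss_offset if site.tss_offset is not None else 0
        for _ in range(n_per_site):
            for attempt in range(max_attempts):
                g = genes[rng.integers(len(genes))]
                center = (g.tss + offset if g.strand != "-" else g.tss - offset)
                start = center - width // 2
                chrom_len = len(genome[g.interval.chrom])
                if 0 <= start and start + width <= chrom_len:
                    iv = GenomicInterval(g.interval.chrom, start, start + width, "+")
                    out.append(BindingSite(iv, fetch_sequence(genome, iv), offset))
                    break
            else:
                raise RuntimeError(
                    f"could not place background for site {k} "
                    f"after {max_attempts} attempts")
    return out


# ---------------------------------------------------------------------------
# Enrichment

@dataclass
class EnrichmentResult:
    """Observed vs background motif-positive region counts for one motif."""

    motif: str
    n_sites: int
    n_sites_with_motif: int
    n_background: int
    n_background_with_motif: int
    pvalue: float
    adjusted_pvalue: float
    significant: bool

    @property
    def observed_fraction(self) -> float:
        return self.n_sites_with_motif / self.n_sites

    @property
    def background_fraction(self) -> float:
        return self.n_background_with_motif / self.n_background


def motif_enrichment(sites: Sequence[BindingSite],
                     background: Sequence[BindingSite],
                     motifs: Iterable[IUPACMotif],
                     both_strands: bool = True,
                     alpha: float = 0.01) -> list[EnrichmentResult]:
    """One-sided Fisher exact enrichment of each motif in sites vs background.

    Bonferroni correction is over the motifs tested in this call; a motif
    is significant when its adjusted p-value is below ``alpha``.
    """
    motifs = list(motifs)
    if not sites or not background:
        raise ValueError("sites and background must be non-empty")
    results = []
    for motif in motifs:
        a = sum(region_has_motif(s.sequence, motif, both_strands) for s in sites)
        b = sum(region_has_motif(s.sequence, motif, both_strands)
                for s in background)
        table = [[a, len(sites) - a], [b, len(background) - b]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        adj = min(1.0, p * len(motifs))
        results.append(EnrichmentResult(
            motif.name, len(sites), a, len(background), b,
            p, adj, adj < alpha))
    return results


def _gene_region(gene: GeneModel, side: str, width: int,
                 chrom_len: int) -> GenomicInterval | None:
    """Strand-aware window of ``width`` bp downstream or upstream of the TSS."""
    if gene.strand != "-":
        start, end = (gene.tss, gene.tss + width) if side == "downstream" \
            else (gene.tss - width, gene.tss)
    else:
        start, end = (gene.tss + 1 - width, gene.tss + 1) if side == "downstream" \
            else (gene.tss + 1, gene.tss + 1 + width)
    start, end = max(0, start), min(chrom_len, end)
    if end - start <= 0:
        return None
    return GenomicInterval(gene.interval.chrom, start, end, gene.strand)


def geneset_motif_background(target_genes: Sequence[str],
                             all_genes: Sequence[GeneModel], genome,
                             motif: IUPACMotif, side: str = "downstream",
                             width: int = 500, n_sets: int = 1000,
                             seed: int = 0, both_strands: bool = True):
    """Empirical gene-set null for motif presence near the TSS.

    The observed statistic is the fraction of target genes whose ``width``
    bp window on the given ``side`` of the TSS contains >= 1 motif match.
    Each of ``n_sets`` background sets is a uniform sample (without
    replacement) of equally many genes from ``all_genes``.  Returns
    (observed_fraction, background fractions array, empirical p), with
    p = (1 + #{background >= observed}) / (n_sets + 1).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if side not in ("downstream", "upstream"):
        raise ValueError(f"side must be downstream|upstream, got {side!r}")
    target = set(target_genes)
    if not target <= {g.gene_id for g in all_genes}:
        raise ValueError("target_genes not a subset of all_genes")

    # motif presence is computed once per gene; set sampling then reduces
    # to boolean means
    has = np.zeros(len(all_genes), dtype=bool)
    for i, g in enumerate(all_genes):
        iv = _gene_region(g, side, width, len(genome[g.interval.chrom]))
        if iv is not None:
            has[i] = region_has_motif(fetch_sequence(genome, iv), motif,
                                      both_strands)
    idx_target = np.array([i for i, g in enumerate(all_genes)
                           if g.gene_id in target])
    observed = float(has[idx_target].mean())

    rng = np.random.default_rng(seed)
    k = len(idx_target)
    bg = np.empty(n_sets)
    for s in range(n_sets):
        bg[s] = has[rng.choice(len(all_genes), size=k, replace=False)].mean()
    pval = (1 + int((bg >= observed - 1e-12).sum())) / (n_sets + 1)
    return observed, bg, float(pval)


def motif_positional_distribution(genes: Sequence[GeneModel], genome,
                                  motif: IUPACMotif, window: int = 1000,
                                  bin_width: int = 50,
                                  both_strands: bool = True):
    """Histogram of strand-aware motif-start offsets around gene TSSs.

    Scans [TSS - window, TSS + window) for each gene (reverse-complemented
    for minus-strand genes so downstream is positive) and bins match start
    offsets.  Returns (bin_edges, counts); counts sum to the number of
    matches.
    """
    if window <= 0 or bin_width <= 0:
        raise ValueError("window and bin_width must be positive")
    offsets = []
    for g in genes:
        chrom_len = len(genome[g.interval.chrom])
        if g.strand != "-":
            start, end = g.tss - window, g.tss + window
            if start < 0 or end > chrom_len:
                continue
            iv = GenomicInterval(g.interval.chrom, start, end, "+")
            seq = fetch_sequence(genome, iv)
        else:
            start, end = g.tss + 1 - window, g.tss + 1 + window
            if start < 0 or end > chrom_len:
                continue
            iv = GenomicInterval(g.interval.chrom, start, end, "-")
            seq = fetch_sequence(genome, iv)   # reverse complement
        for off, _strand in scan_region(seq, motif, both_strands):
            offsets.append(off - window)
    edges = np.arange(-window, window + bin_width, bin_width)
    counts, _ = np.histogram(offsets, bins=edges)
    return edges, counts
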