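"""Peak QC, replicate reconciliation, peak-to-gene assignment and profiles.

A gene is "bound" when a reproducible peak summit falls within a 1 kb
window upstream of its TSS or anywhere in the annotated gene body; all
distances are strand-aware signed offsets from the TSS (negative =
upstream).  Reproducibility between replicates is >= 1 bp interval
overlap, with replicate-A coordinates retained.
"""
from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .genome_io import GeneModel, PeakRecord

__all__ = [
    "QCReport",
    "PeakGeneLink",
    "FeatureAnnotation",
    "FEATURE_CATEGORIES",
    "nonredundant_fraction",
    "strand_cross_correlation",
    "tag_start_vectors",
    "reproducible_peaks",
    "assign_peaks_to_genes",
    "annotate_peak_features",
    "peak_position_profile",
    "peak_distance_between_tfs",
]


@dataclass
class QCReport:
    """ChIP library quality metrics (ENCODE-style)."""

    nrf: float
    cc_profile: dict[int, float]
    fragment_length_estimate: int
    zero_variance_warning: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.nrf <= 1:
            raise ValueError(f"NRF must be in (0, 1], got {self.nrf}")


@dataclass
class PeakGeneLink:
    """One (peak, gene) binding assignment with its signed TSS distance."""

    peak: PeakRecord
    gene_id: str
    signed_distance_to_tss: int
    zone: str                        # upstream_window | gene_body


FEATURE_CATEGORIES = ("utr5", "exon", "intron", "utr3", "upstream_2kb",
                      "downstream_1kb", "intergenic")


@dataclass
class FeatureAnnotation:
    """Partition of peaks over genomic feature categories (by summit)."""

    counts: dict[str, int]
    fractions: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        self.fractions = {c: (self.counts.get(c, 0) / total if total else 0.0)
                          for c in FEATURE_CATEGORIES}


def nonredundant_fraction(tag_positions) -> float:
    """Distinct (chrom, pos, strand) triples over the total tag count."""
    tags = list(tag_positions)
    if not tags:
        raise ValueError("empty tag list")
    return len(set(tags)) / len(tags)


def tag_start_vectors(tags, chrom: str, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-base tag-5'-start count vectors (plus, minus) for one chromosome."""
    plus = np.zeros(length)
    minus = np.zeros(length)
    for c, pos, strand in tags:
        if c == chrom and 0 <= pos < length:
            (plus if strand == "+" else minus)[pos] += 1
    return plus, minus


def strand_cross_correlation(plus_cov: np.ndarray, minus_cov: np.ndarray,
                             shifts, read_length: int | None = None,
                             phantom_exclusion: int = 5,
                             nrf: float = 1.0) -> QCReport:
    """Pearson correlation of strand coverage vs shift; argmax = fragment size.

    The fragment-length estimate excludes shifts within
    ``phantom_exclusion`` bp of the read length (the phantom peak).
    Constant vectors yield correlation 0 with a warning flag.
    """
    plus_cov = np.asarray(plus_cov, dtype=float)
    minus_cov = np.asarray(minus_cov, dtype=float)
    if plus_cov.shape != minus_cov.shape:
        raise ValueError("coverage vectors must have equal length")
    L = plus_cov.size
    profile: dict[int, float] = {}
    warned = False
    for s in shifts:
        s = int(s)
        if s < 0 or s >= L:
            raise ValueError(f"shift {s} out of range")
        a = plus_cov[: L - s] if s else plus_cov
        b = minus_cov[s:]
        if a.std() == 0 or b.std() == 0:
            profile[s] = 0.0
            warned = True
        else:
            profile[s] = float(np.corrcoef(a, b)[0, 1])

    candidates = {
        s: c for s, c in profile.items()
        if read_length is None or abs(s - read_length) > phantom_exclusion
    }
    if not candidates:
        raise ValueError("no shifts outside the phantom exclusion zone")
    frag = max(candidates, key=lambda s: (candidates[s], -s))
    return QCReport(nrf, profile, frag, warned)


def reproducible_peaks(rep_a: list[PeakRecord],
                       rep_b: list[PeakRecord]) -> list[PeakRecord]:
    """Replicate-A peaks overlapping some replicate-B peak by >= 1 bp.

    Output keeps replicate-A coordinates and summits; each A peak is
    emitted at most once.  Inputs must be coordinate-sorted.
    """
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for p in rep_b:
        starts_ends = by_chrom.setdefault(p.interval.chrom, ([], []))
        starts_ends[0].append(p.interval.start)
        starts_ends[1].append(p.interval.end)
    # sort + prefix max of ends for overlap query
    arrs = {}
    for chrom, (starts, ends) in by_chrom.items():
        order = np.argsort(starts, kind="stable")
        s = np.asarray(starts)[order]
        e = np.maximum.accumulate(np.asarray(ends)[order])
        arrs[chrom] = (s, e)
    out = []
    for p in rep_a:
        if p.interval.chrom not in arrs:
            continue
        s, e = arrs[p.interval.chrom]
        i = int(np.searchsorted(s, p.interval.end, side="left"))  # b.start < a.end
        if i > 0 and e[i - 1] > p.interval.start:                 # b.end > a.start
            out.append(p)
    return out


def assign_peaks_to_genes(peaks: list[PeakRecord], genes: list[GeneModel],
                          upstream_window: int = 1000
                          ) -> tuple[set[str], list[PeakGeneLink]]:
    """Bound genes and (peak, gene) links by summit position.

    A gene is bound iff some peak summit lies in the strand-aware window
    [TSS - upstream_window, TTS]; one peak may bind several genes.
    """
    if upstream_window < 0:
        raise ValueError("upstream_window must be >= 0")
    gene_windows: dict[str, list[tuple[int, int, GeneModel]]] = {}
    for g in genes:
        if g.strand != "-":
            lo = g.interval.start - upstream_window
            hi = g.interval.end - 1
        else:
            lo = g.interval.start
            hi = g.interval.end - 1 + upstream_window
        gene_windows.setdefault(g.interval.chrom, []).append((lo, hi, g))
    for v in gene_windows.values():
        v.sort(key=lambda t: t[0])

    bound: set[str] = set()
    links: list[PeakGeneLink] = []
    for p in peaks:
        for lo, hi, g in gene_windows.get(p.interval.chrom, ()):
            if lo > p.summit:
                break
            if p.summit > hi:
                continue
            d = g.tss_offset(p.summit)
            in_body = g.interval.contains(p.summit)
            if not in_body and not (-upstream_window <= d < 0):
                continue
            bound.add(g.gene_id)
            links.append(PeakGeneLink(
                p, g.gene_id, d, "gene_body" if in_body else "upstream_window"))
    return bound, links


def _classify_summit(pos: int, chrom: str,
                     genes_by_chrom: dict[str, list[GeneModel]]) -> str:
    """Feature category with precedence utr5 > exon > intron > utr3 >
    upstream_2kb > downstream_1kb > intergenic; among candidate genes the
    nearest TSS wins."""
    rank = {c: i for i, c in enumerate(FEATURE_CATEGORIES)}
    best: tuple[int, int] | None = None     # (rank, |distance to tss|)
    best_cat = "intergenic"
    for g in genes_by_chrom.get(chrom, ()):
        cat = None
        if any(u.contains(pos) for u in g.utr5):
            cat = "utr5"
        elif any(u.contains(pos) for u in g.utr3):
            cat = "utr3"
        elif any(e.contains(pos) for e in g.exons):
            cat = "exon"
        elif g.interval.contains(pos):
            cat = "intron"
        else:
            d = g.tss_offset(pos)
            if -2000 <= d < 0:
                cat = "upstream_2kb"
            else:
                dt = (pos - g.tts) if g.strand != "-" else (g.tts - pos)
                if 0 < dt <= 1000:
                    cat = "downstream_1kb"
        if cat is None:
            continue
        key = (rank[cat], abs(g.tss_offset(pos)))
        if best is None or key < best:
            best, best_cat = key, cat
    return best_cat


def annotate_peak_features(peaks: list[PeakRecord],
                           genes: list[GeneModel]) -> FeatureAnnotation:
    """Classify each peak summit into one genomic feature category."""
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)
    counts = {c: 0 for c in FEATURE_CATEGORIES}
    for p in peaks:
        counts[_classify_summit(p.summit, p.interval.chrom, genes_by_chrom)] += 1
    return FeatureAnnotation(counts)


def peak_position_profile(links: list[PeakGeneLink], bin_width: int = 100
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of signed summit-to-TSS distances; counts sum to len(links)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = np.array([l.signed_distance_to_tss for l in links], dtype=int)
    if d.size == 0:
        return np.array([0, bin_width]), np.zeros(1, dtype=int)
    lo = (d.min() // bin_width) * bin_width
    hi = (d.max() // bin_width + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return edges, counts


def peak_distance_between_tfs(peaks_a: list[PeakRecord],
                              peaks_b: list[PeakRecord]):
    """Per-A-peak distance to the nearest B summit on the same chromosome.

    Returns ``(distances, median, min, max, n_excluded)`` with unsigned
    distances; A peaks with no same-chromosome B peak are excluded and
    counted.  An empty result (no shared chromosome) carries a warning.
    """
    if not peaks_a or not peaks_b:
        raise ValueError("both peak lists must be non-empty")
    b_summits: dict[str, list[int]] = {}
    for p in peaks_b:
        b_summits.setdefault(p.interval.chrom, []).append(p.summit)
    for v in b_summits.values():
        v.sort()
    distances = []
    excluded = 0
    for p in peaks_a:
        ss = b_summits.get(p.interval.chrom)
        if not ss:
            excluded += 1
            continue
        i = bisect_left(ss, p.summit)
        cand = []
        if i < len(ss):
            cand.append(ss[i] - p.summit)
        if i > 0:
            cand.append(p.summit - ss[i - 1])
        distances.append(min(cand))
    if not distances:
        warnings.warn("no shared chromosome between the two peak sets")
        return [], float("nan"), float("nan"), float("nan"), excluded
    arr = np.array(distances)
    return distances, float(np.median(arr)), int(arr.min()), int(arr.max()), excluded
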