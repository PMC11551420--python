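"""Genomic interval types and readers/writers for FASTA, GFF3 and narrowPeak.

All in-memory coordinates are 0-based half-open on the forward strand.
GFF3 (1-based, inclusive) is converted on read and write; BED-family
formats are stored natively.  TSS/TTS are strand-aware: for a minus-strand
gene the TSS is the last base of its interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from pyfaidx import Fasta

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "PeakRecord",
    "reverse_complement",
    "read_gff3",
    "write_gff3",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_fasta",
    "write_fasta",
    "fetch_sequence",
]

_COMPLEMENT = str.maketrans("ACGTNacgtnRYSWKMBDHVryswkmbdhv",
                            "TGCANtgcanYRSWMKVHDByrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class GeneModel:
    """A gene with strand-aware TSS/TTS and exon/UTR substructure.

    ``tss`` is the 5' end (interval.start on +, interval.end - 1 on -);
    introns are the gaps between consecutive exons.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for e in self.exons:
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"exon {e} outside gene {self.gene_id}")
            if prev_end is not None and e.start < prev_end:
                raise ValueError(f"overlapping exons in {self.gene_id}")
            prev_end = e.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return (self.interval.start if self.strand != "-"
                else self.interval.end - 1)

    @property
    def tts(self) -> int:
        return (self.interval.end - 1 if self.strand != "-"
                else self.interval.start)

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.interval.chrom, a.end,
                                           b.start, self.strand))
        return out

    def tss_offset(self, pos: int) -> int:
        """Strand-aware signed distance of ``pos`` from the TSS.

        Negative values are upstream of the gene, positive downstream.
        """
        return pos - self.tss if self.strand != "-" else self.tss - pos


@dataclass
class PeakRecord:
    """A called peak with its summit (absolute genomic position)."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside {self.interval}")
        if self.score < 0:
            raise ValueError("score must be non-negative")


# ---------------------------------------------------------------------------
# GFF3

_GFF_TYPES = {"gene", "mRNA", "exon", "five_prime_UTR", "three_prime_UTR"}


def read_gff3(path) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModels (primary = longest mRNA).

    gene/mRNA/exon/five_prime_UTR/three_prime_UTR features are linked via
    ID/Parent attributes; 1-based inclusive coordinates become 0-based
    half-open.  A child referencing an unknown Parent is an error.
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line {lineno}: "
                                 f"expected 9 fields, got {len(fields)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _fr, attrs_s = fields
            if ftype not in _GFF_TYPES:
                continue
            try:
                start = int(start_s) - 1
                end = int(end_s)
            except ValueError as exc:
                raise ValueError(f"malformed GFF3 line {lineno}: {exc}") from exc
            attrs = dict(kv.split("=", 1) for kv in attrs_s.split(";") if "=" in kv)
            iv = GenomicInterval(chrom, start, end, strand)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"gene without ID at line {lineno}")
                genes[gid] = {"interval": iv, "mrnas": {}}
                order.append(gid)
            elif ftype == "mRNA":
                parent = attrs.get("Parent")
                if parent not in genes:
                    raise ValueError(
                        f"mRNA with unknown Parent {parent!r} at line {lineno}")
                mid = attrs.get("ID", f"{parent}.m{len(genes[parent]['mrnas'])}")
                genes[parent]["mrnas"][mid] = {
                    "interval": iv, "exons": [], "utr5": [], "utr3": []}
                mrna_to_gene[mid] = parent
            else:
                parent = attrs.get("Parent")
                if parent not in mrna_to_gene:
                    raise ValueError(
                        f"{ftype} with unknown Parent {parent!r} at line {lineno}")
                rec = genes[mrna_to_gene[parent]]["mrnas"][parent]
                key = {"exon": "exons", "five_prime_UTR": "utr5",
                       "three_prime_UTR": "utr3"}[ftype]
                rec[key].append(iv)

    out = []
    for gid in order:
        g = genes[gid]
        if g["mrnas"]:
            # primary transcript = longest mRNA; ties broken by ID
            mid = max(sorted(g["mrnas"]), key=lambda m: len(g["mrnas"][m]["interval"]))
            m = g["mrnas"][mid]
            out.append(GeneModel(gid, g["interval"], exons=m["exons"],
                                 utr5=m["utr5"], utr3=m["utr3"]))
        else:
            out.append(GeneModel(gid, g["interval"]))
    return out


def write_gff3(genes: Iterable[GeneModel], path, source: str = "tfdirect") -> None:
    """Serialize GeneModels deterministically (one mRNA per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            def row(ftype, r, attrs):
                return (f"{r.chrom}\t{source}\t{ftype}\t{r.start + 1}\t{r.end}"
                        f"\t.\t{r.strand}\t.\t{attrs}\n")
            fh.write(row("gene", iv, f"ID={g.gene_id}"))
            mid = f"{g.gene_id}.1"
            fh.write(row("mRNA", iv, f"ID={mid};Parent={g.gene_id}"))
            for e in g.exons:
                fh.write(row("exon", e, f"Parent={mid}"))
            for u in sorted(g.utr5, key=lambda r: r.start):
                fh.write(row("five_prime_UTR", u, f"Parent={mid}"))
            for u in sorted(g.utr3, key=lambda r: r.start):
                fh.write(row("three_prime_UTR", u, f"Parent={mid}"))


# ---------------------------------------------------------------------------
# narrowPeak (BED6+4)

def read_narrowpeak(path) -> list[PeakRecord]:
    """Read a BED6+4 narrowPeak file, sorted by (chrom, start).

    Column 10 is the summit offset from start; -1 means unknown and falls
    back to the interval midpoint (floor).
    """
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(
                    f"narrowPeak line {lineno}: expected 10 columns, got {len(f)}")
            chrom, start, end, name, score = f[0], int(f[1]), int(f[2]), f[3], f[4]
            strand = f[5] if f[5] in ("+", "-", ".") else "."
            offset = int(f[9])
            if start < 0:
                raise ValueError(f"narrowPeak line {lineno}: negative start")
            if offset >= end - start:
                raise ValueError(
                    f"narrowPeak line {lineno}: summit offset {offset} "
                    f">= interval length {end - start}")
            iv = GenomicInterval(chrom, start, end, strand)
            summit = start + offset if offset >= 0 else start + (end - start) // 2
            peaks.append(PeakRecord(iv, summit, float(score), name))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def write_narrowpeak(peaks: Iterable[PeakRecord], path) -> None:
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start,
                                        p.interval.end))
    with open(path, "w") as fh:
        for p in rows:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t"
                     f"{p.score:g}\t{iv.strand}\t0\t-1\t-1\t"
                     f"{p.summit - iv.start}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> Fasta:
    """Open an indexed FASTA (builds the .fai on first use)."""
    return Fasta(str(path), sequence_always_upper=True)


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def fetch_sequence(genome: Fasta, interval: GenomicInterval) -> str:
    """Uppercase sequence of an interval; minus strand reverse-complements.

    Out-of-bounds requests raise instead of clipping.
    """
    if interval.chrom not in genome:
        raise KeyError(f"chromosome {interval.chrom!r} not in genome")
    chrom_len = len(genome[interval.chrom])
    if interval.start < 0 or interval.end > chrom_len:
        raise ValueError(
            f"{interval} out of bounds for {interval.chrom} (len {chrom_len})")
    seq = str(genome[interval.chrom][interval.start:interval.end]).upper()
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq
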