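"""Sequence, gene-model and variant I/O plus the coordinate conventions used package-wide.

Internal coordinates are always 0-based half-open. Exported coordinates follow
each format's standard (GFF3/VCF 1-based, BED 0-based half-open). CDS positions
in reports are 1-based on the spliced CDS.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed input file."""


class ModelError(ValueError):
    """Structurally invalid gene model."""


class ExportError(ValueError):
    """A record cannot be represented in the requested output format."""


@dataclass
class SequenceRecord:
    """A named uppercase DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"sequence record {self.id!r} is empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _as_text_stream(source) -> TextIO:
    if isinstance(source, str):
        if "\n" in source or source.startswith(">"):
            return _io.StringIO(source)
        return open(source, "rt")
    return source


def parse_fasta(source) -> list[SequenceRecord]:
    """Parse FASTA text into records, uppercasing and joining wrapped lines.

    ``source`` may be a path, FASTA text, or an open text stream. Characters
    outside {A,C,G,T,N} (either case) raise :class:`FormatError` naming the
    offending line.
    """
    stream = _as_text_stream(source)
    records: list[SequenceRecord] = []
    name: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is not None:
            records.append(SequenceRecord(name, "".join(chunks)))

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            name = line[1:].split()[0] if line[1:].split() else ""
            chunks = []
        else:
            if name is None:
                raise FormatError(f"line {lineno}: sequence data before any '>' header")
            up = line.upper()
            bad = set(up) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"line {lineno}: illegal sequence characters {sorted(bad)}"
                )
            chunks.append(up)
    _flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], stream: TextIO, width: int = 70) -> None:
    for rec in records:
        stream.write(f">{rec.id}\n")
        for i in range(0, len(rec.sequence), width):
            stream.write(rec.sequence[i : i + width] + "\n")


def fasta_to_dict(source) -> dict[str, str]:
    return {r.id: r.sequence for r in parse_fasta(source)}


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene's strand, exon/intron structure, CDS and promoter window.

    ``exons`` are 0-based half-open genomic intervals, non-overlapping and
    sorted in genomic order. ``cds_start``/``cds_end`` bound the CDS on the
    genome (0-based half-open); the spliced CDS is the exon union intersected
    with that interval, reverse-complemented for minus-strand genes.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    promoter_length: int = 1000

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ModelError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.promoter_length <= 0:
            raise ModelError(f"{self.gene_id}: promoter_length must be positive")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if a >= b:
                raise ModelError(f"{self.gene_id}: empty exon [{a},{b})")
        for (a0, b0), (a1, b1) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ModelError(f"{self.gene_id}: overlapping exons")
        if self.cds_start >= self.cds_end:
            raise ModelError(f"{self.gene_id}: empty CDS")
        if not self._cds_within_exons():
            raise ModelError(f"{self.gene_id}: CDS not covered by exons")

    # -- structure ---------------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def _cds_segments(self) -> list[tuple[int, int]]:
        segs = []
        for a, b in self.exons:
            s, e = max(a, self.cds_start), min(b, self.cds_end)
            if s < e:
                segs.append((s, e))
        return segs

    def _cds_within_exons(self) -> bool:
        # the CDS interval spans introns; it must begin and end inside exons
        starts_in = any(a <= self.cds_start < b for a, b in self.exons)
        ends_in = any(a < self.cds_end <= b for a, b in self.exons)
        return starts_in and ends_in

    def exons_tx_order(self) -> list[tuple[int, int]]:
        """Exons numbered in transcription order (5'→3' of the mRNA)."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns(self) -> list[tuple[int, int]]:
        gaps = [(b0, a1) for (_, b0), (a1, _) in zip(self.exons, self.exons[1:])]
        return gaps if self.strand == "+" else list(reversed(gaps))

    @property
    def tss(self) -> int:
        """Transcription start: 0-based genomic coordinate of the first transcribed base."""
        return self.span[0] if self.strand == "+" else self.span[1] - 1

    def promoter_interval(self) -> tuple[int, int]:
        """Genomic interval of the upstream promoter window (may extend past the sequence)."""
        if self.strand == "+":
            return self.span[0] - self.promoter_length, self.span[0]
        return self.span[1], self.span[1] + self.promoter_length

    # -- coordinate maps ---------------------------------------------------

    def cds_genomic_positions(self) -> list[int]:
        """Genomic coordinate (0-based) of each spliced-CDS base, in CDS order."""
        coords: list[int] = []
        for a, b in self._cds_segments():
            coords.extend(range(a, b))
        if self.strand == "-":
            coords.reverse()
        return coords

    def spliced_cds(self, genome_seq: str) -> str:
        parts = [genome_seq[a:b] for a, b in self._cds_segments()]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)

    def cds_to_genomic(self, cds_pos_1based: int) -> int:
        """Map a 1-based spliced-CDS position to its 0-based genomic coordinate."""
        coords = self.cds_genomic_positions()
        if not 1 <= cds_pos_1based <= len(coords):
            raise ModelError(
                f"{self.gene_id}: CDS position {cds_pos_1based} outside [1,{len(coords)}]"
            )
        return coords[cds_pos_1based - 1]


def parse_gff3(source) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    Coordinates are converted from GFF3's 1-based inclusive convention to the
    package's 0-based half-open one.
    """
    stream = _as_text_stream(source)
    genes: dict[str, dict] = {}
    parent_of: dict[str, str] = {}
    order: list[str] = []
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"GFF3 line does not have 9 columns: {line[:60]!r}")
        seqid, _, ftype, start, end, _, strand, _, attrs = fields
        a = {k: v for k, _, v in (kv.partition("=") for kv in attrs.split(";") if kv)}
        start0, end0 = int(start) - 1, int(end)
        if ftype == "gene":
            gid = a.get("ID")
            if not gid:
                raise FormatError("gene feature without ID attribute")
            genes[gid] = {
                "seq_id": seqid,
                "strand": strand,
                "exons": [],
                "cds": [],
                "promoter_length": int(a.get("promoter_length", 1000)),
            }
            order.append(gid)
        elif ftype == "mRNA":
            parent_of[a.get("ID", "")] = a.get("Parent", "")
        elif ftype in ("exon", "CDS"):
            parent = a.get("Parent", "")
            gid = parent_of.get(parent, parent)
            if gid not in genes:
                raise FormatError(f"{ftype} with unknown parent {parent!r}")
            genes[gid]["exons" if ftype == "exon" else "cds"].append((start0, end0))
    models = []
    for gid in order:
        g = genes[gid]
        exons = g["exons"] or g["cds"]
        cds = g["cds"] or exons
        cds_start = min(a for a, _ in cds)
        cds_end = max(b for _, b in cds)
        models.append(
            GeneModel(
                gene_id=gid,
                seq_id=g["seq_id"],
                strand=g["strand"],
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
                promoter_length=g["promoter_length"],
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], stream: TextIO) -> None:
    stream.write("##gff-version 3\n")
    for m in models:
        s, e = m.span
        stream.write(
            f"{m.seq_id}\tregelscan\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
            f"ID={m.gene_id};promoter_length={m.promoter_length}\n"
        )
        mrna = f"{m.gene_id}.t1"
        stream.write(
            f"{m.seq_id}\tregelscan\tmRNA\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
            f"ID={mrna};Parent={m.gene_id}\n"
        )
        for i, (a, b) in enumerate(m.exons, start=1):
            stream.write(
                f"{m.seq_id}\tregelscan\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                f"ID={mrna}.exon{i};Parent={mrna}\n"
            )
        for a, b in m.exons:
            ca, cb = max(a, m.cds_start), min(b, m.cds_end)
            if ca < cb:
                stream.write(
                    f"{m.seq_id}\tregelscan\tCDS\t{ca + 1}\t{cb}\t.\t{m.strand}\t0\t"
                    f"ID={mrna}.cds;Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# Variant records and VCF
# ---------------------------------------------------------------------------


@dataclass
class VariantRecordOut:
    """A reference-anchored substitution or insertion ready for export.

    ``cds_position`` is 1-based on the spliced CDS; for insertions it is the
    CDS base the insertion follows. ``genomic_position`` is 1-based.
    """

    gene_id: str
    cds_position: int
    genomic_position: int
    kind: str  # substitution | insertion
    ref_allele: str
    alt_allele: str
    consensus_ratio: float
    depth: int
    seq_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "substitution":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("substitution alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("substitution with identical alleles")
        else:
            if not (len(self.alt_allele) > len(self.ref_allele) == 1):
                raise ValueError("insertion ALT must extend a single anchor base")
            if not self.alt_allele.startswith(self.ref_allele):
                raise ValueError("insertion ALT must start with the anchor base")
        if not 0.0 <= self.consensus_ratio <= 1.0:
            raise ValueError("consensus_ratio outside [0,1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CBR,Number=1,Type=Float,Description="Consensus base ratio">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Supporting non-gap depth">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">
##INFO=<ID=CDSPOS,Number=1,Type=Integer,Description="1-based position on the spliced CDS">
##INFO=<ID=KIND,Number=1,Type=String,Description="substitution or insertion">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(variants: Iterable[VariantRecordOut], stream: TextIO) -> None:
    """Write VCF v4.2. Insertions must already be left-anchored (REF = anchor base)."""
    stream.write(_VCF_HEADER)
    for v in variants:
        if v.genomic_position < 1:
            raise ExportError(
                f"{v.gene_id}: insertion before position 1 has no anchor base"
            )
        chrom = v.seq_id or v.gene_id
        info = (
            f"CBR={v.consensus_ratio:g};DP={v.depth};GENE={v.gene_id};"
            f"CDSPOS={v.cds_position};KIND={v.kind}"
        )
        stream.write(
            f"{chrom}\t{v.genomic_position}\t.\t{v.ref_allele}\t{v.alt_allele}"
            f"\t.\tPASS\t{info}\n"
        )


def parse_variants_vcf(source) -> list[VariantRecordOut]:
    stream = _as_text_stream(source)
    out = []
    for line in stream:
        if line.startswith("#") or not line.strip():
            continue
        chrom, pos, _, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
        kv = dict(item.split("=", 1) for item in info.split(";"))
        out.append(
            VariantRecordOut(
                gene_id=kv["GENE"],
                cds_position=int(kv["CDSPOS"]),
                genomic_position=int(pos),
                kind=kv["KIND"],
                ref_allele=ref,
                alt_allele=alt,
                consensus_ratio=float(kv["CBR"]),
                depth=int(kv["DP"]),
                seq_id=chrom,
            )
        )
    return out


# ---------------------------------------------------------------------------
# BED and minimal MEME motif text
# ---------------------------------------------------------------------------


def write_bed(intervals: Iterable[tuple[str, int, int, str]], stream: TextIO) -> None:
    """Write (seq_id, start, end, name) tuples as BED (0-based half-open)."""
    for seq_id, start, end, name in intervals:
        stream.write(f"{seq_id}\t{start}\t{end}\t{name}\n")


def write_meme_motifs(motifs, stream: TextIO, background=None) -> None:
    """Write position probability matrices in MEME minimal text format.

    ``motifs`` is an iterable of objects with ``name``, ``pwm`` (4 x w array,
    rows in A,C,G,T order) and optionally ``n_sites`` / ``permutation_p``.
    """
    stream.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    bg = background if background is not None else [0.25] * 4
    stream.write(
        "Background letter frequencies\n"
        + " ".join(f"{b} {f:.3f}" for b, f in zip("ACGT", bg))
        + "\n\n"
    )
    for m in motifs:
        pwm = m.pwm
        w = pwm.shape[1]
        nsites = getattr(m, "n_sites", 20)
        pval = getattr(m, "permutation_p", None)
        stream.write(f"MOTIF {m.name}\n")
        stream.write(
            f"letter-probability matrix: alength= 4 w= {w} nsites= {nsites}"
            + (f" P= {pval:g}" if pval is not None else "")
            + "\n"
        )
        for j in range(w):
            stream.write(" ".join(f"{pwm[i, j]:.6f}" for i in range(4)) + "\n")
        stream.write("\n")
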