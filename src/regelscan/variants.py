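"""Consensus-base-ratio variant calling from strain contigs and joint-codon effects.

Contigs are aligned one-by-one against their reference CDS (overlap alignment),
projected onto reference columns, and a substitution is reported only when
*every* non-gap observation at a column differs from the reference and agrees
on a single alternate base — the consensus-base-ratio-1.0 criterion. Insertions
are reported when every contig spanning the flanking reference positions
carries the identical inserted string.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .align import PairwiseAlignment, align_contig, assign_contigs
from .io import GeneModel, VariantRecordOut

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class ColumnMatrix:
    """Reference-anchored evidence: per-position base observations and
    per-slot insertion observations (slot *k* sits after 0-based position *k*)."""

    ref_id: str
    reference: str
    # position (0-based) -> list of (contig_id, base or '-')
    columns: dict[int, list[tuple[str, str]]] = field(default_factory=dict)
    # slot after position k -> list of (contig_id, inserted string, possibly '')
    insertions: dict[int, list[tuple[str, str]]] = field(default_factory=dict)


def build_column_matrix(
    alignments: list[PairwiseAlignment], reference: str, ref_id: str = "ref"
) -> ColumnMatrix:
    """Project pairwise alignments onto reference columns.

    Every contig contributes to the contiguous reference span it aligns to;
    contig bases opposite reference gaps are collected as insertion evidence on
    the slot after the last consumed reference position. A contig spanning the
    slot between positions k and k+1 without any inserted base contributes an
    empty-string observation there, so absence of an insertion is evidence too.
    Contig overhangs beyond the reference ends are ignored.
    """
    mat = ColumnMatrix(ref_id=ref_id, reference=reference)
    for aln in alignments:
        if aln.ref_id != ref_id:
            raise ValueError(
                f"alignment of {aln.contig_id} is against {aln.ref_id!r}, not {ref_id!r}"
            )
        pos = aln.ref_start
        pending_insert: list[str] = []
        seen_first_ref = False
        for rb, cb in zip(aln.aligned_ref, aln.aligned_contig):
            if rb == "-":
                pending_insert.append(cb)
                continue
            if seen_first_ref:
                mat.insertions.setdefault(pos - 1, []).append(
                    (aln.contig_id, "".join(pending_insert))
                )
            pending_insert = []
            seen_first_ref = True
            mat.columns.setdefault(pos, []).append((aln.contig_id, cb))
            pos += 1
        # pending_insert left at the end is a contig overhang, not an insertion
    return mat


def normalize_insertion(reference: str, slot: int, inserted: str) -> tuple[int, str]:
    """Left-align an insertion (the VCF convention) within repeat context.

    An insertion of ``inserted`` after 0-based position ``slot`` is equivalent
    to inserting ``reference[slot] + inserted[:-1]`` one base earlier whenever
    the string's last base equals the anchor base.
    """
    while slot > 0 and inserted and inserted[-1] == reference[slot]:
        inserted = reference[slot] + inserted[:-1]
        slot -= 1
    return slot, inserted


@dataclass
class VariantCall:
    """A called substitution or insertion on the spliced CDS (0-based position)."""

    ref_id: str
    position: int  # substitution: 0-based ref position; insertion: position it follows
    kind: str
    ref_allele: str
    alt_allele: str
    consensus_ratio: float
    depth: int
    alt_agreement: bool = True


def call_variants(
    matrix: ColumnMatrix,
    min_support: int = 2,
    call_deletions: bool = False,
) -> list[VariantCall]:
    """Call variants under the consensus-base-ratio criterion.

    Per reference position the ratio is (# non-gap observations differing from
    the reference base) / (# non-gap observations); gap observations are
    excluded from both numerator and denominator. A substitution is emitted iff
    the ratio is exactly 1.0, depth >= ``min_support`` and all differing
    observations share one alternate base. An insertion is emitted iff every
    contig spanning the slot carries the identical non-empty inserted string.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    calls: list[VariantCall] = []
    for pos in sorted(matrix.columns):
        obs = [b for _, b in matrix.columns[pos] if b != "-"]
        ref_base = matrix.reference[pos]
        if not obs:
            if call_deletions and len(matrix.columns[pos]) >= min_support:
                calls.append(
                    VariantCall(
                        ref_id=matrix.ref_id,
                        position=pos,
                        kind="deletion",
                        ref_allele=ref_base,
                        alt_allele="",
                        consensus_ratio=1.0,
                        depth=len(matrix.columns[pos]),
                    )
                )
            continue
        diff = [b for b in obs if b != ref_base]
        ratio = len(diff) / len(obs)
        assert 0.0 <= ratio <= 1.0
        if ratio == 1.0 and len(obs) >= min_support:
            alleles = set(diff)
            if len(alleles) == 1 and "N" not in alleles:
                calls.append(
                    VariantCall(
                        ref_id=matrix.ref_id,
                        position=pos,
                        kind="substitution",
                        ref_allele=ref_base,
                        alt_allele=diff[0],
                        consensus_ratio=ratio,
                        depth=len(obs),
                    )
                )
    seen_insertions: set[tuple[int, str]] = set()
    for slot in sorted(matrix.insertions):
        observations = matrix.insertions[slot]
        strings = [s for _, s in observations]
        if len(observations) < min_support:
            continue
        if all(s and s == strings[0] for s in strings) and "N" not in strings[0]:
            pos, ins = normalize_insertion(matrix.reference, slot, strings[0])
            if (pos, ins) in seen_insertions:
                continue
            seen_insertions.add((pos, ins))
            calls.append(
                VariantCall(
                    ref_id=matrix.ref_id,
                    position=pos,
                    kind="insertion",
                    ref_allele=matrix.reference[pos],
                    alt_allele=matrix.reference[pos] + ins,
                    consensus_ratio=1.0,
                    depth=len(observations),
                )
            )
    for c in calls:
        assert c.consensus_ratio == 1.0
    return calls


def call_gene_variants(
    contigs: dict[str, str],
    references: dict[str, str],
    min_support: int = 2,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> dict[str, list[VariantCall]]:
    """Assign contigs to references by k-mer vote, align, and call per gene."""
    assignment = assign_contigs(contigs, references)
    by_ref: dict[str, list[str]] = defaultdict(list)
    for cid, rid in assignment.items():
        if rid is not None:
            by_ref[rid].append(cid)
    out: dict[str, list[VariantCall]] = {}
    for rid, cids in sorted(by_ref.items()):
        ref = references[rid]
        alns = [
            align_contig(contigs[cid], ref, contig_id=cid, ref_id=rid,
                         match=match, mismatch=mismatch, gap=gap)
            for cid in sorted(cids)
        ]
        matrix = build_column_matrix(alns, ref, ref_id=rid)
        out[rid] = call_variants(matrix, min_support=min_support)
    return out


# ---------------------------------------------------------------------------
# Codon effects
# ---------------------------------------------------------------------------


@dataclass
class CodonEffect:
    """Joint per-codon translation consequence of the variants hitting it."""

    gene_id: str
    codon_index: int  # 1-based
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect_class: str  # synonymous | missense | nonsense | frameshift
    contributing: list[VariantCall]


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def annotate_effects(
    variants: list[VariantCall],
    cds: str,
    gene_id: str = "",
    joint: bool = True,
) -> list[CodonEffect]:
    """Classify coding consequences, applying same-codon substitutions jointly.

    With ``joint=True`` (default) all substitutions falling in one codon are
    applied together and every contributing variant inherits that codon's
    effect; ``joint=False`` annotates each substitution in isolation. An
    insertion whose length is not a multiple of 3 is a frameshift, evaluated
    only at the affected codon (downstream codons are not re-annotated).
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"{gene_id}: CDS length {len(cds)} not divisible by 3")
    effects: list[CodonEffect] = []
    subs = [v for v in variants if v.kind == "substitution"]
    for v in subs:
        if not 0 <= v.position < len(cds):
            raise ValueError(f"{gene_id}: variant position {v.position} outside CDS")
        if v.alt_allele not in "ACGT":
            raise ValueError(f"{gene_id}: non-ACGT alternate allele {v.alt_allele!r}")

    by_codon: dict[int, list[VariantCall]] = defaultdict(list)
    for v in subs:
        by_codon[v.position // 3].append(v)
    for codon0 in sorted(by_codon):
        groups = [by_codon[codon0]] if joint else [[v] for v in by_codon[codon0]]
        for group in groups:
            ref_codon = cds[codon0 * 3 : codon0 * 3 + 3]
            alt = list(ref_codon)
            for v in group:
                offset = v.position - codon0 * 3
                if ref_codon[offset] != v.ref_allele:
                    raise ValueError(
                        f"{gene_id}: reference allele mismatch at CDS position "
                        f"{v.position + 1} ({ref_codon[offset]} != {v.ref_allele})"
                    )
                alt[offset] = v.alt_allele
            alt_codon = "".join(alt)
            ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
            if ref_aa == alt_aa:
                klass = "synonymous"
            elif alt_codon in STOP_CODONS:
                klass = "nonsense"
            else:
                klass = "missense"
            effects.append(
                CodonEffect(
                    gene_id=gene_id,
                    codon_index=codon0 + 1,
                    ref_codon=ref_codon,
                    alt_codon=alt_codon,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    effect_class=klass,
                    contributing=list(group),
                )
            )
    for v in variants:
        if v.kind != "insertion":
            continue
        inserted = v.alt_allele[len(v.ref_allele):]
        codon0 = v.position // 3
        ref_codon = cds[codon0 * 3 : codon0 * 3 + 3]
        klass = "frameshift" if len(inserted) % 3 != 0 else "missense"
        effects.append(
            CodonEffect(
                gene_id=gene_id,
                codon_index=codon0 + 1,
                ref_codon=ref_codon,
                alt_codon="",
                ref_aa=_translate(ref_codon) if len(ref_codon) == 3 else "",
                alt_aa="",
                effect_class=klass,
                contributing=[v],
            )
        )
    effects.sort(key=lambda e: (e.codon_index, e.effect_class))
    return effects


def variant_to_record(
    call: VariantCall, gene: GeneModel, genome: dict[str, str] | None = None
) -> VariantRecordOut:
    """Map a CDS-space call to an exportable, genome-anchored record.

    For minus-strand genes the insertion slot "after spliced-CDS position k"
    lies genomically *before* the mapped base, and the inserted string is
    reverse-complemented onto the plus strand.
    """
    from .io import ExportError, reverse_complement

    cds_pos = call.position + 1  # 1-based; insertions: anchor base
    g0 = gene.cds_to_genomic(cds_pos)
    if call.kind == "substitution":
        if gene.strand == "+":
            ref, alt = call.ref_allele, call.alt_allele
        else:
            ref, alt = (
                reverse_complement(call.ref_allele),
                reverse_complement(call.alt_allele),
            )
        return VariantRecordOut(
            gene_id=gene.gene_id,
            cds_position=cds_pos,
            genomic_position=g0 + 1,
            kind="substitution",
            ref_allele=ref,
            alt_allele=alt,
            consensus_ratio=call.consensus_ratio,
            depth=call.depth,
            seq_id=gene.seq_id,
        )
    inserted = call.alt_allele[len(call.ref_allele):]
    if gene.strand == "+":
        anchor0 = g0
        ins_plus = inserted
    else:
        anchor0 = g0 - 1
        ins_plus = reverse_complement(inserted)
    if anchor0 < 0:
        raise ExportError(f"{gene.gene_id}: insertion anchor before sequence start")
    if genome is not None:
        anchor_base = genome[gene.seq_id][anchor0]
    else:
        anchor_base = call.ref_allele if gene.strand == "+" else "N"
    return VariantRecordOut(
        gene_id=gene.gene_id,
        cds_position=cds_pos,
        genomic_position=anchor0 + 1,
        kind="insertion",
        ref_allele=anchor_base,
        alt_allele=anchor_base + ins_plus,
        consensus_ratio=call.consensus_ratio,
        depth=call.depth,
        seq_id=gene.seq_id,
    )
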