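"""Curated coding-variant catalogue for P450 genes of a resistant housefly strain.

These are the published variant records for cytochrome P450 genes of the
spinosad-selected housefly strain 791spin relative to the susceptible WHO-SRS
reference: reference codons, 1-based spliced-CDS locations, substitutions and
insertions, with the reported amino-acid changes. Depth values are the number
of strain sequences aligned per gene.

The per-gene CDS "backbones" returned by :func:`reconstructed_cds` are
synthetic scaffolds — neutral GCT (Ala) codons everywhere except the variant
codons, which carry the published reference codons — sufficient for codon-level
effect annotation since effects are evaluated per affected codon only.

Two quirks of the published records are encoded explicitly rather than
silently resolved:

* the cyp12a2 record printed at location 1114 with an A-C-G codon and a G→A
  change only makes sense at codon offset 2 (ACG→ACA, synonymous); the forced
  offset is stored and the record flagged (``location_caveat``);
* the cyp6d1 substitutions come in same-codon pairs; the reported amino-acid
  changes (M→L, E→S, L→P) are reproduced only when each pair is applied
  jointly — reading the position-10 G→T alone would create a stop codon
  (``joint_caveat``). Joint-codon annotation is therefore the default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .variants import CodonEffect, VariantCall, annotate_effects


@dataclass(frozen=True)
class CatalogRecord:
    gene: str
    printed_location: int  # 1-based CDS location as published
    kind: str  # substitution | insertion
    ref_codon: str
    codon_offset: int  # 0-based offset within the codon (forced where needed)
    ref_base: str  # substitution only
    alt: str  # substitution: alternate base; insertion: inserted string
    printed_aa_change: str  # e.g. "L→L"; '' for insertions
    location_caveat: bool = False
    joint_caveat: bool = False

    @property
    def codon_index(self) -> int:
        """1-based codon number the record affects.

        The printed location is the codon's location even for the one record
        whose changed base sits at a different codon offset (location_caveat).
        """
        return (self.printed_location - 1) // 3 + 1

    @property
    def cds_position(self) -> int:
        """Resolved 1-based CDS position of the changed/anchor base."""
        if self.kind == "insertion":
            return self.printed_location
        return (self.codon_index - 1) * 3 + self.codon_offset + 1


RECORDS: list[CatalogRecord] = [
    CatalogRecord("cyp4g2", 67, "substitution", "CTG", 0, "C", "T", "L→L"),
    CatalogRecord("cyp4g2", 281, "substitution", "GGT", 1, "G", "T", "G→V"),
    CatalogRecord("cyp4g2", 139, "insertion", "", 0, "", "AT", ""),
    CatalogRecord("cyp6a37", 1102, "substitution", "CAT", 0, "C", "T", "H→Y"),
    CatalogRecord("cyp6d1", 1, "substitution", "ATG", 0, "A", "C", "M→L", joint_caveat=True),
    CatalogRecord("cyp6d1", 3, "substitution", "ATG", 2, "G", "T", "M→L", joint_caveat=True),
    CatalogRecord("cyp6d1", 9, "substitution", "GTA", 2, "A", "G", "V→V"),
    CatalogRecord("cyp6d1", 10, "substitution", "GAA", 0, "G", "T", "E→S", joint_caveat=True),
    CatalogRecord("cyp6d1", 11, "substitution", "GAA", 1, "A", "C", "E→S", joint_caveat=True),
    CatalogRecord("cyp6d1", 13, "substitution", "TTA", 0, "T", "C", "L→P", joint_caveat=True),
    CatalogRecord("cyp6d1", 14, "substitution", "TTA", 1, "T", "C", "L→P", joint_caveat=True),
    CatalogRecord("cyp6d1", 11, "insertion", "", 0, "", "C", ""),
    CatalogRecord("cyp12a2", 230, "substitution", "AAG", 1, "A", "T", "K→M"),
    CatalogRecord("cyp12a2", 1114, "substitution", "ACG", 2, "G", "A", "T→T", location_caveat=True),
]

#: strain sequences aligned per gene (contigs plus any resistant-strain sequence)
DEPTH = {"cyp4g2": 14, "cyp6a37": 6, "cyp6d1": 6, "cyp12a2": 8}

GENES = ["cyp4g2", "cyp6a37", "cyp6d1", "cyp12a2"]


def gene_records(gene: str) -> list[CatalogRecord]:
    return [r for r in RECORDS if r.gene == gene]


def reconstructed_cds(gene: str) -> str:
    """Synthetic CDS scaffold carrying the published reference codons.

    Neutral GCT codons fill every codon the catalogue does not constrain.
    """
    recs = gene_records(gene)
    n_codons = max(
        max((r.codon_index for r in recs if r.kind == "substitution"), default=1),
        max(((r.printed_location - 1) // 3 + 1 for r in recs if r.kind == "insertion"),
            default=1),
    )
    codons = ["GCT"] * n_codons
    for r in recs:
        if r.kind == "substitution":
            codons[r.codon_index - 1] = r.ref_codon
    return "".join(codons)


def variant_calls(gene: str) -> list[VariantCall]:
    """The catalogue's records as ratio-1.0 variant calls on the scaffold CDS."""
    cds = reconstructed_cds(gene)
    calls = []
    for r in gene_records(gene):
        if r.kind == "substitution":
            pos0 = r.cds_position - 1
            calls.append(
                VariantCall(
                    ref_id=gene,
                    position=pos0,
                    kind="substitution",
                    ref_allele=cds[pos0],
                    alt_allele=r.alt,
                    consensus_ratio=1.0,
                    depth=DEPTH[gene],
                )
            )
        else:
            pos0 = r.printed_location - 1
            calls.append(
                VariantCall(
                    ref_id=gene,
                    position=pos0,
                    kind="insertion",
                    ref_allele=cds[pos0],
                    alt_allele=cds[pos0] + r.alt,
                    consensus_ratio=1.0,
                    depth=DEPTH[gene],
                )
            )
    return calls


def annotate(gene: str, joint: bool = True) -> list[CodonEffect]:
    """Run the codon-effect annotator on the catalogue's records for one gene."""
    return annotate_effects(variant_calls(gene), reconstructed_cds(gene),
                            gene_id=gene, joint=joint)


def per_variant_effects(gene: str, joint: bool = True) -> list[tuple[VariantCall, CodonEffect]]:
    """Each record paired with the effect its codon carries (joint inheritance)."""
    effects = annotate(gene, joint=joint)
    pairs = []
    for e in effects:
        for v in e.contributing:
            pairs.append((v, e))
    pairs.sort(key=lambda p: (p[0].position, p[0].kind))
    return pairs


def variant_counts(convention: str = "all_rows") -> dict[str, int]:
    """Per-gene variant counts under an explicit counting convention.

    ``all_rows`` counts every catalogue record (substitutions and insertions);
    ``substitutions`` counts substitution records only. The two conventions
    exist because published per-gene tallies mix them.
    """
    if convention not in ("all_rows", "substitutions"):
        raise ValueError(f"unknown counting convention {convention!r}")
    out: dict[str, int] = {}
    for r in RECORDS:
        if convention == "substitutions" and r.kind != "substitution":
            continue
        out[r.gene] = out.get(r.gene, 0) + 1
    return out


def classification_summary(joint: bool = True) -> dict[str, dict[str, int]]:
    """Per-gene counts of synonymous vs non-synonymous records.

    Frameshift insertions count as non-synonymous; with joint annotation every
    substitution inherits its codon's class.
    """
    out: dict[str, dict[str, int]] = {}
    for gene in GENES:
        syn = nonsyn = 0
        for _, eff in per_variant_effects(gene, joint=joint):
            if eff.effect_class == "synonymous":
                syn += 1
            else:
                nonsyn += 1
        out[gene] = {"synonymous": syn, "non_synonymous": nonsyn}
    return out


def aa_changes(gene: str) -> list[tuple[str, str]]:
    """(printed, computed) amino-acid change per substitution record, in CDS order."""
    computed = {}
    for v, eff in per_variant_effects(gene, joint=True):
        if v.kind == "substitution":
            computed[v.position] = f"{eff.ref_aa}→{eff.alt_aa}"
    out = []
    for r in sorted(gene_records(gene), key=lambda r: r.cds_position):
        if r.kind == "substitution":
            out.append((r.printed_aa_change, computed[r.cds_position - 1]))
    return out
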