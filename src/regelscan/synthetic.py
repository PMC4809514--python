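"""Seeded synthetic data: genome, gene models, strain contigs, islands, motifs, GO.

Emulates the structure of a strain-versus-reference transcript comparison: a
multi-gene reference with exon/intron architecture, per-gene contig sets of
varying depth (2-14 by default, matching the per-gene contig counts such
comparisons typically have), planted fixed substitutions/insertions carried by
every overlapping contig (the ratio-1.0 ground truth), independent per-base
sequencing error elsewhere, CpG-rich planted segments, promoter motifs shared
by gene subsets (at most one site per promoter), and gene-GO annotations with
designated enriched terms. Identical (seed, config) pairs produce byte-identical
artifact sets; each artifact kind draws from its own RNG stream so adding genes
does not perturb contig noise.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import io as rio
from .io import GeneModel, SequenceRecord

BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass
class PlantedVariant:
    gene: str
    cds_position: int  # 1-based; insertions follow this base
    kind: str  # substitution | insertion
    # substitution: alternate base (None -> the reference base's transversion
    # partner, resolved at simulation time); insertion: inserted string
    alt: str | None = None
    mode: str = "fixed"  # fixed (all contigs) | polymorphic (a fraction)
    fraction: float = 0.5


@dataclass
class PlantedIsland:
    location: object  # genomic start (int) or (gene_id, label) with label in
    # {promoter, 5p, 3p, downstream}
    length: int
    gc: float
    oe: float


@dataclass
class PlantedMotif:
    consensus: str
    genes: tuple[str, ...]
    mutation_rate: float = 0.0


@dataclass
class GOSpec:
    n_terms: int = 20
    p_background: float = 0.05
    enriched: dict = field(default_factory=dict)  # term -> (tuple of genes, p_hi)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 8
    gene_length_range: tuple[int, int] = (1500, 2500)
    exons_per_gene: tuple[int, int] = (1, 3)
    intergenic_length: int = 1500
    contig_depth_range: tuple[int, int] = (2, 14)
    contig_length_range: tuple[int, int] = (200, 800)
    error_rate: float = 0.001
    gc_background: float = 0.40
    promoter_length: int = 1000
    planted_variants: list = field(default_factory=list)
    planted_islands: list = field(default_factory=list)
    planted_motifs: list = field(default_factory=list)
    go_spec: GOSpec = field(default_factory=GOSpec)
    n_promoters: list = field(default_factory=list)  # genes whose promoter gets one N

    def __post_init__(self) -> None:
        for p in (self.error_rate, self.gc_background, self.go_spec.p_background):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.contig_depth_range[0] < 1:
            raise ConfigError("contig depth must be >= 1")
        for term, (genes, p_hi) in self.go_spec.enriched.items():
            if not 0.0 <= p_hi <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
            if p_hi <= self.go_spec.p_background:
                raise ConfigError(
                    f"enriched term {term!r}: p_hi must exceed the background rate"
                )


@dataclass
class TruthTable:
    variants: list = field(default_factory=list)
    islands: list = field(default_factory=list)
    motif_sites: list = field(default_factory=list)
    enriched_terms: list = field(default_factory=list)
    contig_windows: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    genome: dict[str, str]
    genes: list[GeneModel]
    cds: dict[str, str]  # reference spliced CDS per gene
    contigs: dict[str, str]
    go_annotations: dict[str, set[str]]  # term -> genes
    truth: TruthTable
    config: SimulationConfig


def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ["reference", "islands", "motifs", "contigs", "errors", "go"]
    return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


# ---------------------------------------------------------------------------
# Reference genome and gene models
# ---------------------------------------------------------------------------


def generate_reference(config: SimulationConfig):
    """Random genome and gene models; genes alternate loci with intergenic spacing.

    Returns (genome dict, gene models, truth part). Every gene's CDS equals its
    spliced exon union and has length divisible by 3.
    """
    rng = _streams(config.seed)["reference"]
    seq_id = "chr1"
    margin = max(config.intergenic_length, config.promoter_length + 50)
    genes: list[GeneModel] = []
    pos = margin
    for gi in range(config.n_genes):
        gid = f"g{gi + 1:02d}"
        length = int(rng.integers(*_incl(config.gene_length_range)))
        n_exons = int(rng.integers(*_incl(config.exons_per_gene)))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _split_exons(rng, pos, length, n_exons)
        genes.append(
            GeneModel(
                gene_id=gid,
                seq_id=seq_id,
                strand=strand,
                exons=exons,
                cds_start=exons[0][0],
                cds_end=exons[-1][1],
                promoter_length=config.promoter_length,
            )
        )
        pos = exons[-1][1] + margin
    genome_len = pos + margin
    arr = _random_seq(rng, genome_len, config.gc_background)
    genome = {seq_id: "".join(BASES[arr])}
    for gid in config.n_promoters:
        gene = _gene(genes, gid)
        a, b = gene.promoter_interval()
        mid = (a + b) // 2
        s = genome[seq_id]
        genome[seq_id] = s[:mid] + "N" + s[mid + 1 :]
    return genome, genes


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    if lo > hi:
        raise ConfigError(f"invalid range {rng_pair}")
    return lo, hi + 1


def _split_exons(rng, start: int, length: int, n_exons: int) -> list[tuple[int, int]]:
    min_intron, max_intron = 60, 200
    introns = [int(rng.integers(min_intron, max_intron + 1)) for _ in range(n_exons - 1)]
    exon_total = length - sum(introns)
    if exon_total < 90 * n_exons:
        raise ConfigError("gene too short for the requested exon count")
    exon_total -= exon_total % 3
    cuts = sorted(rng.choice(np.arange(1, exon_total // 3), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    sizes = np.diff([0] + [3 * c for c in cuts] + [exon_total])
    sizes = np.maximum(sizes, 3)
    exons = []
    p = start
    for i, sz in enumerate(sizes):
        exons.append((p, p + int(sz)))
        p += int(sz)
        if i < len(introns):
            p += introns[i]
    return exons


def _gene(genes: list[GeneModel], gid: str) -> GeneModel:
    for g in genes:
        if g.gene_id == gid:
            return g
    raise ConfigError(f"unknown gene {gid!r}")


# ---------------------------------------------------------------------------
# Planted regulatory features
# ---------------------------------------------------------------------------


def _resolve_island_location(isl: PlantedIsland, genes: list[GeneModel], genome_len: int) -> int:
    if isinstance(isl.location, int):
        return isl.location
    gid, label = isl.location
    gene = _gene(genes, gid)
    gs, ge = gene.span
    if label == "promoter":
        a, b = gene.promoter_interval()
        return (a + b) // 2 - isl.length // 2
    if label == "5p":
        return gs if gene.strand == "+" else ge - isl.length
    if label == "3p":
        return ge - isl.length if gene.strand == "+" else gs
    if label == "downstream":
        return (ge + 200) if gene.strand == "+" else (gs - 200 - isl.length)
    raise ConfigError(f"unknown island location label {label!r}")


def _synthesize_island(rng, length: int, gc: float, oe: float) -> str:
    """Draw an i.i.d. segment, retrying until it meets both targets."""
    from .cpg import measure_interval

    for boost in np.linspace(0.05, 0.2, 16):
        for _ in range(25):
            arr = _random_seq(rng, length, min(0.95, gc + boost))
            seg = "".join(BASES[arr])
            got_gc, got_oe = measure_interval(seg, 0, length)
            if got_gc >= gc and got_oe >= oe:
                return seg
    raise ConfigError(
        f"cannot synthesize a {length} bp island with GC >= {gc} and O/E >= {oe}"
    )


def plant_regulatory_features(
    genome: dict[str, str], genes: list[GeneModel], config: SimulationConfig
) -> tuple[dict[str, str], TruthTable]:
    """Write planted CpG-rich segments and promoter motif instances into the genome."""
    from .cpg import measure_interval

    truth = TruthTable()
    rng_isl = _streams(config.seed)["islands"]
    rng_mot = _streams(config.seed)["motifs"]
    seq_id = genes[0].seq_id if genes else "chr1"
    seq = list(genome[seq_id])
    occupied: list[tuple[int, int]] = []

    def claim(a: int, b: int, what: str) -> None:
        if a < 0 or b > len(seq):
            raise ConfigError(f"{what} does not fit in the genome ([{a},{b}))")
        for (x, y) in occupied:
            if a < y and x < b:
                raise ConfigError(f"planted features overlap at [{a},{b})")
        occupied.append((a, b))

    for isl in config.planted_islands:
        start = _resolve_island_location(isl, genes, len(seq))
        claim(start, start + isl.length, "planted island")
        seg = _synthesize_island(rng_isl, isl.length, isl.gc, isl.oe)
        seq[start : start + isl.length] = list(seg)
        gc, oe = measure_interval(seg, 0, isl.length)
        truth.islands.append(
            {"seq_id": seq_id, "start": int(start), "end": int(start + isl.length),
             "gc": gc, "oe": oe}
        )

    for mot in config.planted_motifs:
        w = len(mot.consensus)
        if w > config.promoter_length:
            raise ConfigError("motif longer than the promoter window")
        for gid in mot.genes:
            gene = _gene(genes, gid)
            a, b = gene.promoter_interval()
            # uniform over offsets that do not collide with already-planted features
            for _ in range(200):
                offset = int(rng_mot.integers(0, config.promoter_length - w + 1))
                g0_try = (a + offset) if gene.strand == "+" else (b - offset - w)
                if not any(g0_try < y and x < g0_try + w for x, y in occupied):
                    break
            else:
                raise ConfigError(f"no free promoter space for a motif in {gid}")
            inst = list(mot.consensus)
            if mot.mutation_rate > 0:
                for i in range(w):
                    if rng_mot.random() < mot.mutation_rate:
                        inst[i] = str(rng_mot.choice([c for c in "ACGT" if c != inst[i]]))
            inst_s = "".join(inst)
            if gene.strand == "+":
                g0 = a + offset
                planted = inst_s
            else:
                g0 = b - offset - w
                planted = rio.reverse_complement(inst_s)
            claim(g0, g0 + w, f"motif in {gid}")
            seq[g0 : g0 + w] = list(planted)
            truth.motif_sites.append(
                {"motif": mot.consensus, "gene": gid, "offset": int(offset),
                 "instance": inst_s}
            )

    genome = dict(genome)
    genome[seq_id] = "".join(seq)
    return genome, truth


# ---------------------------------------------------------------------------
# Strain contigs
# ---------------------------------------------------------------------------


def _apply_to_window(
    cds: str, w_start: int, w_end: int, variants: list[PlantedVariant]
) -> str:
    """Apply planted variants (CDS coordinates) to the window [w_start, w_end)."""
    out: list[str] = []
    ins_after: dict[int, str] = {}
    sub_at: dict[int, str] = {}
    for v in variants:
        p0 = v.cds_position - 1
        if v.kind == "substitution":
            if w_start <= p0 < w_end:
                sub_at[p0] = v.alt
        else:
            # included only when both flanking bases are inside the window
            if w_start <= p0 and p0 + 1 < w_end:
                ins_after[p0] = v.alt
    for p in range(w_start, w_end):
        out.append(sub_at.get(p, cds[p]))
        if p in ins_after:
            out.append(ins_after[p])
    return "".join(out)


def simulate_strain_contigs(
    genes: list[GeneModel],
    genome: dict[str, str],
    config: SimulationConfig,
) -> tuple[dict[str, str], TruthTable]:
    """Per-gene contig sets cut from the strain transcript.

    Depth is drawn per gene from ``contig_depth_range``; each contig is a
    random substring of the spliced CDS with all overlapping fixed variants
    applied (polymorphic ones with their configured fraction), plus independent
    substitution errors at ``error_rate`` away from planted positions. Contig
    ids encode the source gene for truth lookup only.
    """
    rng = _streams(config.seed)["contigs"]
    rng_err = _streams(config.seed)["errors"]
    truth = TruthTable()
    contigs: dict[str, str] = {}
    by_gene: dict[str, list[PlantedVariant]] = {}
    for v in config.planted_variants:
        by_gene.setdefault(v.gene, []).append(v)

    for gene in genes:
        cds = gene.spliced_cds(genome[gene.seq_id])
        planted = by_gene.get(gene.gene_id, [])
        for i, v in enumerate(planted):
            if not 1 <= v.cds_position <= len(cds):
                raise ConfigError(
                    f"{gene.gene_id}: planted variant position {v.cds_position} "
                    f"outside CDS of length {len(cds)}"
                )
            if v.kind == "substitution":
                if v.alt is None:
                    v = dataclasses.replace(
                        v, alt=_TRANSVERSION[cds[v.cds_position - 1]])
                    planted[i] = v
                if cds[v.cds_position - 1] == v.alt:
                    raise ConfigError(
                        f"{gene.gene_id}: planted substitution equals the reference base"
                    )
            elif v.alt is None:
                raise ConfigError("planted insertions need an explicit inserted string")
            else:
                # store the left-aligned (VCF-convention) form so truth matches calls
                from .variants import normalize_insertion

                pos, ins = normalize_insertion(cds, v.cds_position - 1, v.alt)
                if (pos, ins) != (v.cds_position - 1, v.alt):
                    planted[i] = dataclasses.replace(v, cds_position=pos + 1, alt=ins)
        if config.contig_length_range[0] > len(cds):
            raise ConfigError(
                f"{gene.gene_id}: minimum contig length exceeds transcript length"
            )
        depth = int(rng.integers(*_incl(config.contig_depth_range)))
        for ci in range(depth):
            clen = int(rng.integers(*_incl(config.contig_length_range)))
            clen = min(clen, len(cds))
            start = int(rng.integers(0, len(cds) - clen + 1))
            end = start + clen
            chosen = [
                v for v in planted
                if v.mode == "fixed" or rng.random() < v.fraction
            ]
            raw = _apply_to_window(cds, start, end, chosen)
            # positions safe to perturb: those matching the reference window
            ref_window = cds[start:end]
            arr = list(raw)
            if config.error_rate > 0:
                # map raw indices back: identical length segments only when no
                # insertion applies; walk both to flag planted positions
                planted_idx = _planted_indices(cds, start, end, chosen)
                hits = rng_err.random(len(arr)) < config.error_rate
                for i in np.flatnonzero(hits):
                    if i in planted_idx:
                        continue
                    cur = arr[i]
                    choices = [c for c in "ACGT" if c != cur]
                    arr[i] = choices[int(rng_err.integers(3))]
            cid = f"{gene.gene_id}|c{ci + 1:02d}"
            contigs[cid] = "".join(arr)
            truth.contig_windows.append(  # per-contig provenance for the verifier
                {"contig": cid, "gene": gene.gene_id, "cds_start": start,
                 "cds_end": end,
                 "carries": [dataclasses.asdict(v) for v in chosen
                             if _overlaps_window(v, start, end)]}
            )
        truth.variants.extend(
            {"gene": v.gene, "cds_position": v.cds_position, "kind": v.kind,
             "alt": v.alt, "mode": v.mode}
            for v in planted
        )
    return contigs, truth


def _overlaps_window(v: PlantedVariant, start: int, end: int) -> bool:
    p0 = v.cds_position - 1
    if v.kind == "substitution":
        return start <= p0 < end
    return start <= p0 and p0 + 1 < end


def _planted_indices(cds, start, end, variants) -> set[int]:
    idx: set[int] = set()
    offset = 0
    sub_pos = {v.cds_position - 1 for v in variants if v.kind == "substitution"}
    ins = {v.cds_position - 1: len(v.alt) for v in variants
           if v.kind == "insertion" and start <= v.cds_position - 1 and v.cds_position < end}
    for p in range(start, end):
        if p in sub_pos:
            idx.add(p - start + offset)
        if p in ins:
            for k in range(ins[p]):
                idx.add(p - start + offset + 1 + k)
            offset += ins[p]
    return idx


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------


def generate_go_annotations(
    gene_ids: list[str], config: SimulationConfig
) -> tuple[dict[str, set[str]], TruthTable]:
    """Bernoulli background annotations with designated enriched terms."""
    spec = config.go_spec
    for term, (genes, _) in spec.enriched.items():
        unknown = set(genes) - set(gene_ids)
        if unknown:
            raise ConfigError(f"enriched term {term!r} names unknown genes {unknown}")
    rng = _streams(config.seed)["go"]
    terms = [f"GO:{i + 1:07d}" for i in range(spec.n_terms)]
    annotations: dict[str, set[str]] = {t: set() for t in terms}
    truth = TruthTable(enriched_terms=list(spec.enriched))
    for term in terms:
        enriched_genes, p_hi = spec.enriched.get(term, ((), 0.0))
        enriched_genes = set(enriched_genes)
        for g in gene_ids:
            p = p_hi if g in enriched_genes else spec.p_background
            if rng.random() < p:
                annotations[term].add(g)
    return annotations, truth


# ---------------------------------------------------------------------------
# Orchestration + artifact files
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig, out_dir: str | None = None) -> SyntheticDataset:
    """Generate every pipeline input from one seeded configuration."""
    genome, genes = generate_reference(config)
    genome, truth_reg = plant_regulatory_features(genome, genes, config)
    contigs, truth_ctg = simulate_strain_contigs(genes, genome, config)
    go, truth_go = generate_go_annotations([g.gene_id for g in genes], config)
    truth = TruthTable(
        variants=truth_ctg.variants,
        islands=truth_reg.islands,
        motif_sites=truth_reg.motif_sites,
        enriched_terms=truth_go.enriched_terms,
        contig_windows=truth_ctg.contig_windows,
    )
    ds = SyntheticDataset(
        genome=genome,
        genes=genes,
        cds={g.gene_id: g.spliced_cds(genome[g.seq_id]) for g in genes},
        contigs=contigs,
        go_annotations=go,
        truth=truth,
        config=config,
    )
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: SyntheticDataset, out_dir: str) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def _write(name: str, fn) -> None:
        path = os.path.join(out_dir, name)
        with open(path, "w") as fh:
            fn(fh)
        paths[name] = path

    _write("genome.fasta", lambda fh: rio.write_fasta(
        [SequenceRecord(k, v) for k, v in ds.genome.items()], fh))
    _write("genes.gff3", lambda fh: rio.write_gff3(ds.genes, fh))
    _write("cds.fasta", lambda fh: rio.write_fasta(
        [SequenceRecord(k, v) for k, v in sorted(ds.cds.items())], fh))
    _write("contigs.fasta", lambda fh: rio.write_fasta(
        [SequenceRecord(k, v) for k, v in sorted(ds.contigs.items())], fh))

    def _go(fh):
        fh.write("gene\tterm\n")
        for term in sorted(ds.go_annotations):
            for gene in sorted(ds.go_annotations[term]):
                fh.write(f"{gene}\t{term}\n")

    _write("go_annotations.tsv", _go)
    _write("truth.json", lambda fh: fh.write(ds.truth.to_json()))
    return paths


def read_go_tsv(source) -> dict[str, set[str]]:
    """Read a gene→term TSV (header 'gene\\tterm') into term -> gene sets."""
    import io as _io

    stream = open(source) if isinstance(source, str) and "\n" not in source else _io.StringIO(source)
    annotations: dict[str, set[str]] = {}
    header = stream.readline()
    for line in stream:
        if not line.strip():
            continue
        gene, term = line.rstrip("\n").split("\t")
        annotations.setdefault(term, set()).add(gene)
    return annotations


def verify_dataset(out_dir: str) -> list[str]:
    """Independently re-read the written artifacts and check them against truth.json."""
    from .cpg import measure_interval

    problems: list[str] = []
    genome = rio.fasta_to_dict(os.path.join(out_dir, "genome.fasta"))
    genes = rio.parse_gff3(os.path.join(out_dir, "genes.gff3"))
    contigs = rio.fasta_to_dict(os.path.join(out_dir, "contigs.fasta"))
    with open(os.path.join(out_dir, "truth.json")) as fh:
        truth = json.load(fh)
    for isl in truth["islands"]:
        gc, oe = measure_interval(genome[isl["seq_id"]], isl["start"], isl["end"])
        if abs(gc - isl["gc"]) > 1e-9 or abs(oe - isl["oe"]) > 1e-9:
            problems.append(f"island at {isl['start']} measures differently on re-read")
    by_id = {g.gene_id: g for g in genes}
    from .motifs import extract_promoters

    promoters, _ = extract_promoters(genome, genes)
    for site in truth["motif_sites"]:
        prom = promoters.get(site["gene"])
        if prom is None or prom[site["offset"] : site["offset"] + len(site["instance"])] != site["instance"]:
            problems.append(f"motif site in {site['gene']} not found at offset {site['offset']}")
    for v in truth["variants"]:
        if v.get("mode") != "fixed":
            continue
        gene = by_id[v["gene"]]
        cds = gene.spliced_cds(genome[gene.seq_id])
        p0 = v["cds_position"] - 1
        for cid, seq in contigs.items():
            if not cid.startswith(v["gene"] + "|"):
                continue
            # fixed variants must appear in every contig that contains enough
            # flanking reference context to place them
            if v["kind"] == "substitution":
                probe = cds[max(0, p0 - 12) : p0] + v["alt"] + cds[p0 + 1 : p0 + 13]
            else:
                probe = cds[max(0, p0 - 12) : p0 + 1] + v["alt"] + cds[p0 + 1 : p0 + 13]
            ref_probe = cds[max(0, p0 - 12) : p0 + 13]
            if ref_probe in seq:
                problems.append(f"{cid}: reference allele present where {v['kind']} planted")
    return problems
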