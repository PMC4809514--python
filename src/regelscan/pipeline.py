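"""End-to-end orchestration: simulate → stats → callsnps → effects → cpg →
promoters → motifs → enrich, from one config and one master seed.

The master seed fans out to one child seed per stage (recorded in the run
report), so stages are individually reproducible and identical config+seed
pairs give byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import assembly, cpg, enrichment, motifs as motifs_mod, synthetic
from . import io as rio
from .synthetic import ConfigError, GOSpec, PlantedIsland, PlantedMotif, PlantedVariant
from .variants import annotate_effects, call_gene_variants, variant_to_record

log = logging.getLogger("regelscan")

STAGES = [
    "simulate", "stats", "callsnps", "effects",
    "cpg", "promoters", "motifs", "enrich",
]


def default_demo_config(seed: int = 0) -> dict:
    """The packaged demonstration study: a 10-gene locus with an 8-gene focal panel.

    Mirrors the structure of a strain-vs-reference P450 survey: per-gene contig
    depths of 2-14, fixed substitutions and a 2-bp insertion (including a
    same-codon substitution pair), one polymorphic site as a no-call control,
    planted CpG-rich segments at distinct gene-relative locations, two motifs
    shared by gene subsets, one promoter poisoned with an N, and three GO terms
    enriched in the focal panel against a 500-gene annotated background.
    """
    focal = [f"g{i:02d}" for i in range(1, 9)]
    return {
        "seed": seed,
        "simulate": {
            "n_genes": 10,
            "gene_length_range": [1100, 1500],
            "exons_per_gene": [1, 3],
            "intergenic_length": 1500,
            "contig_depth_range": [2, 14],
            "contig_length_range": [650, 1800],
            "error_rate": 0.001,
            "gc_background": 0.40,
            "promoter_length": 1000,
            "planted_variants": [
                {"gene": "g01", "cds_position": 67, "kind": "substitution"},
                {"gene": "g01", "cds_position": 139, "kind": "insertion", "alt": "AT"},
                {"gene": "g02", "cds_position": 230, "kind": "substitution"},
                {"gene": "g02", "cds_position": 231, "kind": "substitution"},
                {"gene": "g03", "cds_position": 303, "kind": "substitution"},
                {"gene": "g04", "cds_position": 150, "kind": "substitution"},
                {"gene": "g05", "cds_position": 450, "kind": "substitution",
                 "mode": "polymorphic", "fraction": 0.5},
            ],
            "planted_islands": [
                {"location": ["g01", "promoter"], "length": 700, "gc": 0.60, "oe": 0.80},
                {"location": ["g02", "3p"], "length": 650, "gc": 0.60, "oe": 0.80},
                {"location": ["g04", "5p"], "length": 800, "gc": 0.62, "oe": 0.80},
                {"location": ["g06", "downstream"], "length": 600, "gc": 0.60, "oe": 0.80},
            ],
            "planted_motifs": [
                {"consensus": "TTGACGTCAT", "genes": ["g01", "g02", "g03", "g04", "g05", "g06"],
                 "mutation_rate": 0.05},
                {"consensus": "TATAAATGGC", "genes": ["g02", "g05", "g07", "g08"],
                 "mutation_rate": 0.05},
            ],
            "n_promoters": ["g09"],
            "go_spec": {
                "n_terms": 20,
                "p_background": 0.01,
                "n_background_genes": 500,
                "enriched": {
                    "GO:0000001": {"genes": focal, "p_hi": 0.90},
                    "GO:0000002": {"genes": focal, "p_hi": 0.85},
                    "GO:0000003": {"genes": focal, "p_hi": 0.80},
                },
            },
        },
        "focal_genes": focal,
        "calling": {"min_support": 2},
        "cpg": {"min_length": 200, "min_gc": 0.5, "min_oe": 0.6, "window": 200, "step": 1},
        "motifs": {"widths": [6, 8, 10, 12], "n_motifs": 3, "n_seeds": 24,
                   "n_permutations": 49},
        "enrichment": {"kappa_threshold": 0.35, "min_members": 3},
    }


def _simulation_config(section: dict, seed: int) -> synthetic.SimulationConfig:
    sec = dict(section)
    go = sec.pop("go_spec", {})
    enriched = {
        term: (tuple(v["genes"]), float(v["p_hi"]))
        for term, v in go.get("enriched", {}).items()
    }
    n_background = int(go.get("n_background_genes", 0))
    go_spec = GOSpec(
        n_terms=int(go.get("n_terms", 20)),
        p_background=float(go.get("p_background", 0.05)),
        enriched=enriched,
    )
    variants = [PlantedVariant(**v) if "alt" in v else PlantedVariant(alt=None, **v)
                for v in sec.pop("planted_variants", [])]
    islands = [
        PlantedIsland(
            location=tuple(i["location"]) if isinstance(i["location"], (list, tuple)) else int(i["location"]),
            length=int(i["length"]), gc=float(i["gc"]), oe=float(i["oe"]))
        for i in sec.pop("planted_islands", [])
    ]
    planted_motifs = [
        PlantedMotif(consensus=m["consensus"], genes=tuple(m["genes"]),
                     mutation_rate=float(m.get("mutation_rate", 0.0)))
        for m in sec.pop("planted_motifs", [])
    ]
    for key in ("gene_length_range", "exons_per_gene", "contig_depth_range",
                "contig_length_range"):
        if key in sec:
            sec[key] = tuple(sec[key])
    cfg = synthetic.SimulationConfig(
        seed=seed,
        planted_variants=variants,
        planted_islands=islands,
        planted_motifs=planted_motifs,
        go_spec=go_spec,
        **sec,
    )
    cfg.n_background_genes = n_background  # carried for the GO stage
    return cfg


def run_pipeline(config: dict | str, out_dir: str, seed: int | None = None) -> dict:
    """Run every stage in dependency order; returns the run report (also written
    to ``report.json``). Any stage failure aborts with a partial report on disk."""
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    if seed is None:
        seed = int(config.get("seed", 0))
    os.makedirs(out_dir, exist_ok=True)
    stage_seeds = {
        name: int(c.generate_state(1)[0] % (2**31))
        for name, c in zip(STAGES, np.random.SeedSequence(seed).spawn(len(STAGES)))
    }
    report: dict = {"seed": seed, "stage_seeds": stage_seeds, "stages": [],
                    "warnings": []}
    report_path = os.path.join(out_dir, "report.json")

    def _finish_stage(name: str, t0: float, outputs: dict, counts: dict) -> None:
        entry = {"stage": name, "duration_s": round(time.time() - t0, 3),
                 "outputs": outputs, "counts": counts}
        report["stages"].append(entry)
        log.info("stage %-10s %6.2fs %s", name, entry["duration_s"], counts)
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)

    try:
        _run_stages(config, out_dir, stage_seeds, report, _finish_stage)
    except Exception:
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        raise
    return report


def _run_stages(config, out_dir, stage_seeds, report, _finish_stage):
    p = lambda name: os.path.join(out_dir, name)

    # ---- simulate ---------------------------------------------------------
    t0 = time.time()
    if "simulate" in config:
        sim_cfg = _simulation_config(config["simulate"], stage_seeds["simulate"])
        ds = synthetic.simulate_dataset(sim_cfg, out_dir=out_dir)
        genome, genes, contigs = ds.genome, ds.genes, ds.contigs
        gene_ids = [g.gene_id for g in genes]
        background = [f"bg{i + 1:04d}" for i in range(getattr(sim_cfg, "n_background_genes", 0))]
        if background:
            go, _ = synthetic.generate_go_annotations(gene_ids + background, sim_cfg)
            ds.go_annotations = go
            synthetic.write_dataset(ds, out_dir)
        annotations = ds.go_annotations
    else:
        inputs = config.get("inputs", {})
        for key in ("genome", "genes", "contigs", "go_annotations"):
            if key not in inputs:
                raise ConfigError(f"config missing required input: {key}")
        genome = rio.fasta_to_dict(inputs["genome"])
        genes = rio.parse_gff3(inputs["genes"])
        contigs = rio.fasta_to_dict(inputs["contigs"])
        annotations = synthetic.read_go_tsv(inputs["go_annotations"])
    cds = {g.gene_id: g.spliced_cds(genome[g.seq_id]) for g in genes}
    _finish_stage("simulate", t0, {"out_dir": out_dir},
                  {"genes": len(genes), "contigs": len(contigs)})

    # ---- stats ------------------------------------------------------------
    t0 = time.time()
    stats = assembly.contig_stats([len(s) for s in contigs.values()])
    pd.DataFrame(stats.to_rows(), columns=["statistic", "value"]).to_csv(
        p("assembly_stats.tsv"), sep="\t", index=False)
    _finish_stage("stats", t0, {"tsv": p("assembly_stats.tsv")},
                  {"n_contigs": stats.n_contigs, "n50": stats.n50})

    # ---- callsnps ---------------------------------------------------------
    t0 = time.time()
    min_support = int(config.get("calling", {}).get("min_support", 2))
    calls_by_gene = call_gene_variants(contigs, cds, min_support=min_support)
    by_id = {g.gene_id: g for g in genes}
    records = []
    for gid in sorted(calls_by_gene):
        for call in calls_by_gene[gid]:
            if call.kind in ("substitution", "insertion"):
                records.append(variant_to_record(call, by_id[gid], genome))
    with open(p("variants.vcf"), "w") as fh:
        rio.write_variants_vcf(records, fh)
    n_calls = sum(len(v) for v in calls_by_gene.values())
    _finish_stage("callsnps", t0, {"vcf": p("variants.vcf")},
                  {"variants_called": n_calls})

    # ---- effects ----------------------------------------------------------
    t0 = time.time()
    rows = []
    for gid in sorted(calls_by_gene):
        effects = annotate_effects(calls_by_gene[gid], cds[gid], gene_id=gid)
        for e in effects:
            for v in e.contributing:
                rows.append({
                    "gene": gid,
                    "location": v.position + 1,
                    "na_change": (f"{v.ref_allele}→{v.alt_allele}"
                                  if v.kind == "substitution"
                                  else f"ins {v.alt_allele[1:]}"),
                    "aa_change": (f"{e.ref_aa}→{e.alt_aa}" if e.alt_codon else ""),
                    "class": e.effect_class,
                })
    effects_df = pd.DataFrame(rows, columns=["gene", "location", "na_change",
                                             "aa_change", "class"])
    effects_df.to_csv(p("effects.tsv"), sep="\t", index=False)
    _finish_stage("effects", t0, {"tsv": p("effects.tsv")},
                  {"effects": len(effects_df)})

    # ---- cpg --------------------------------------------------------------
    t0 = time.time()
    cpg_cfg = config.get("cpg", {})
    islands = []
    for seq_id, seq in genome.items():
        islands.extend(cpg.scan_islands(seq, seq_id=seq_id, **cpg_cfg))
    locations = cpg.locate_islands(islands, genes)
    with open(p("islands.bed"), "w") as fh:
        rio.write_bed(
            [(i.seq_id, i.start, i.end, f"island_{k + 1}") for k, i in enumerate(islands)],
            fh,
        )
    pd.DataFrame(
        [{"gene": loc.gene_id or "", "size": loc.island.length,
          "gc": round(loc.island.gc_fraction, 4),
          "obs_exp": round(loc.island.obs_exp_cpg, 4),
          "location": loc.location_label,
          "coverage": "; ".join(loc.coverage)}
         for loc in locations]
    ).to_csv(p("islands.tsv"), sep="\t", index=False)
    _finish_stage("cpg", t0, {"bed": p("islands.bed"), "tsv": p("islands.tsv")},
                  {"islands_found": len(islands)})

    # ---- promoters --------------------------------------------------------
    t0 = time.time()
    promoter_length = int(config.get("simulate", {}).get("promoter_length", 1000))
    promoters, excluded = motifs_mod.extract_promoters(genome, genes, length=promoter_length)
    with open(p("promoters.fasta"), "w") as fh:
        rio.write_fasta([rio.SequenceRecord(k, v) for k, v in promoters.items()], fh)
    with open(p("promoter_exclusions.tsv"), "w") as fh:
        fh.write("gene\treason\n")
        for gid, reason in excluded:
            fh.write(f"{gid}\t{reason}\n")
    report["warnings"].extend(f"promoter excluded: {g} ({r})" for g, r in excluded)
    _finish_stage("promoters", t0, {"fasta": p("promoters.fasta")},
                  {"promoters": len(promoters), "excluded": len(excluded)})

    # ---- motifs -----------------------------------------------------------
    t0 = time.time()
    mo_cfg = dict(config.get("motifs", {}))
    n_perm = int(mo_cfg.pop("n_permutations", 0))
    focal = [g for g in config.get("focal_genes", list(promoters)) if g in promoters]
    focal_promoters = {g: promoters[g] for g in focal}
    found = motifs_mod.discover_motifs_zoops(
        focal_promoters, seed=stage_seeds["motifs"], n_permutations=n_perm, **mo_cfg)
    with open(p("motifs.meme"), "w") as fh:
        rio.write_meme_motifs(found, fh, background=found[0].background if found else None)
    presence = motifs_mod.presence_matrix(found, promoters)
    presence.to_csv(p("motif_presence.tsv"), sep="\t")
    go_rows = []
    for m in found:
        scores = motifs_mod.best_site_scores(m, promoters)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            for r in motifs_mod.associate_motif_go(scores, annotations):
                go_rows.append({"motif": m.name, "term": r.term,
                                "statistic": r.statistic, "p": r.p_value,
                                "p_bh": r.p_adjusted})
    pd.DataFrame(go_rows, columns=["motif", "term", "statistic", "p", "p_bh"]).to_csv(
        p("motif_go.tsv"), sep="\t", index=False)
    accepted = [m for m in found if m.permutation_p is None or m.permutation_p < 0.05]
    _finish_stage("motifs", t0, {"meme": p("motifs.meme"),
                                 "presence": p("motif_presence.tsv"),
                                 "go": p("motif_go.tsv")},
                  {"motifs_accepted": len(accepted), "motifs_reported": len(found)})

    # ---- enrich -----------------------------------------------------------
    t0 = time.time()
    en_cfg = config.get("enrichment", {})
    gene_list = set(config.get("focal_genes", [g.gene_id for g in genes]))
    table = enrichment.enrich(gene_list, annotations)
    table.to_csv(p("enrichment.tsv"), sep="\t", index=False)
    sig = table[table["p_value"] < 0.05]
    clusters = []
    if len(table) >= 2:
        all_genes = sorted(set().union(*annotations.values()) | gene_list)
        membership = pd.DataFrame(
            {t: [g in annotations.get(t, set()) for g in all_genes] for t in table["term"]},
            index=all_genes,
        )
        term_ps = dict(zip(table["term"], table["p_value"]))
        clusters = enrichment.kappa_cluster(
            membership,
            kappa_threshold=float(en_cfg.get("kappa_threshold", 0.35)),
            min_members=int(en_cfg.get("min_members", 3)),
            term_ps=term_ps,
        )
    pd.DataFrame(
        [{"cluster": i + 1, "enrichment_score": round(c.enrichment_score, 4),
          "terms": "; ".join(c.members)} for i, c in enumerate(clusters)]
    ).to_csv(p("clusters.tsv"), sep="\t", index=False)
    _finish_stage("enrich", t0, {"tsv": p("enrichment.tsv"),
                                 "clusters": p("clusters.tsv")},
                  {"enriched_terms": int(len(sig)), "clusters": len(clusters)})
    return report
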