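import io

import numpy as np
import pytest

from regelscan import io as rio
from regelscan.cpg import measure_interval
from regelscan.motifs import extract_promoters
from regelscan.synthetic import (
    ConfigError,
    GOSpec,
    PlantedIsland,
    PlantedMotif,
    PlantedVariant,
    SimulationConfig,
    generate_go_annotations,
    generate_reference,
    plant_regulatory_features,
    simulate_dataset,
    simulate_strain_contigs,
    verify_dataset,
    write_dataset,
)


def small_config(seed=0, **kw):
    defaults = dict(
        seed=seed,
        n_genes=4,
        gene_length_range=(700, 1000),
        exons_per_gene=(1, 2),
        intergenic_length=1200,
        contig_depth_range=(3, 6),
        contig_length_range=(400, 1000),
        error_rate=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def genome_bytes(cfg):
    genome, genes = generate_reference(cfg)
    buf = io.StringIO()
    rio.write_fasta([rio.SequenceRecord(k, v) for k, v in genome.items()], buf)
    return buf.getvalue(), genes


class TestReference:
    def test_same_seed_gives_identical_fasta_bytes(self):
        a, _ = genome_bytes(small_config(seed=11))
        b, _ = genome_bytes(small_config(seed=11))
        assert a == b

    def test_different_seed_differs(self):
        a, _ = genome_bytes(small_config(seed=11))
        b, _ = genome_bytes(small_config(seed=12))
        assert a != b

    def test_requested_gene_count_appears_in_gff3(self):
        cfg = small_config(n_genes=8)
        _, genes = generate_reference(cfg)
        buf = io.StringIO()
        rio.write_gff3(genes, buf)
        again = rio.parse_gff3(buf.getvalue())
        assert len(again) == 8

    def test_exon_counts_within_bounds(self):
        cfg = small_config(n_genes=10, exons_per_gene=(1, 3),
                           gene_length_range=(1000, 1400))
        _, genes = generate_reference(cfg)
        assert all(1 <= len(g.exons) <= 3 for g in genes)
        assert any(len(g.exons) > 1 for g in genes)

    def test_cds_lengths_divisible_by_three(self):
        genome, genes = generate_reference(small_config(n_genes=6))
        for g in genes:
            assert len(g.spliced_cds(genome[g.seq_id])) % 3 == 0

    def test_gene_too_short_for_exons_rejected(self):
        with pytest.raises(ConfigError):
            generate_reference(small_config(gene_length_range=(200, 250),
                                            exons_per_gene=(3, 3)))


class TestPlanting:
    def test_island_meets_targets_when_remeasured(self):
        cfg = small_config(planted_islands=[
            PlantedIsland(location=("g02", "promoter"), length=700, gc=0.6, oe=0.8)
        ])
        genome, genes = generate_reference(cfg)
        genome, truth = plant_regulatory_features(genome, genes, cfg)
        (isl,) = truth.islands
        gc, oe = measure_interval(genome["chr1"], isl["start"], isl["end"])
        assert gc >= 0.6 and oe >= 0.8 and isl["end"] - isl["start"] == 700

    def test_island_longer_than_region_rejected(self):
        cfg = small_config(planted_islands=[
            PlantedIsland(location=10**7, length=500, gc=0.6, oe=0.8)
        ])
        genome, genes = generate_reference(cfg)
        with pytest.raises(ConfigError):
            plant_regulatory_features(genome, genes, cfg)

    def test_overlapping_islands_rejected(self):
        cfg = small_config(planted_islands=[
            PlantedIsland(location=100, length=400, gc=0.6, oe=0.8),
            PlantedIsland(location=300, length=400, gc=0.6, oe=0.8),
        ])
        genome, genes = generate_reference(cfg)
        with pytest.raises(ConfigError, match="overlap"):
            plant_regulatory_features(genome, genes, cfg)

    def test_motif_truth_lists_exactly_the_designated_genes(self):
        cfg = small_config(planted_motifs=[
            PlantedMotif(consensus="TATAAT", genes=("g01", "g03"))
        ])
        genome, genes = generate_reference(cfg)
        genome, truth = plant_regulatory_features(genome, genes, cfg)
        assert sorted(s["gene"] for s in truth.motif_sites) == ["g01", "g03"]
        proms, _ = extract_promoters(genome, genes)
        for s in truth.motif_sites:
            assert proms[s["gene"]][s["offset"] : s["offset"] + 6] == s["instance"]


class TestContigs:
    def test_noiseless_planting_puts_variant_in_every_overlapping_contig(self):
        cfg = small_config(
            contig_depth_range=(5, 5),
            contig_length_range=(600, 1000),
            planted_variants=[PlantedVariant("g01", 120, "substitution", "A"),
                              PlantedVariant("g01", 240, "insertion", "CG")],
        )
        genome, genes = generate_reference(cfg)
        contigs, truth = simulate_strain_contigs(genes, genome, cfg)
        g01 = genes[0]
        cds = g01.spliced_cds(genome["chr1"])
        resolved = {(v["cds_position"], v["kind"]): v for v in truth.variants}
        for w in truth.contig_windows:
            if w["gene"] != "g01":
                continue
            seq = contigs[w["contig"]]
            for v in w["carries"]:
                p0 = v["cds_position"] - 1
                if v["kind"] == "substitution":
                    probe = cds[p0 - 8 : p0] + v["alt"] + cds[p0 + 1 : p0 + 9]
                else:
                    probe = cds[p0 - 8 : p0 + 1] + v["alt"] + cds[p0 + 1 : p0 + 9]
                assert probe in seq

    def test_substitution_error_rate_is_binomial(self):
        cfg = small_config(seed=5, error_rate=0.01, n_genes=6,
                           contig_depth_range=(4, 6))
        genome, genes = generate_reference(cfg)
        contigs, truth = simulate_strain_contigs(genes, genome, cfg)
        cds = {g.gene_id: g.spliced_cds(genome["chr1"]) for g in genes}
        mism = total = 0
        for w in truth.contig_windows:
            ref = cds[w["gene"]][w["cds_start"] : w["cds_end"]]
            seq = contigs[w["contig"]]
            assert len(ref) == len(seq)
            mism += sum(a != b for a, b in zip(ref, seq))
            total += len(seq)
        sigma = np.sqrt(total * 0.01 * 0.99)
        assert abs(mism - total * 0.01) <= 3 * sigma

    def test_planted_position_outside_cds_rejected(self):
        cfg = small_config(planted_variants=[
            PlantedVariant("g01", 10**6, "substitution", "A")])
        genome, genes = generate_reference(cfg)
        with pytest.raises(ConfigError):
            simulate_strain_contigs(genes, genome, cfg)

    def test_contig_min_length_above_transcript_rejected(self):
        cfg = small_config(contig_length_range=(10**5, 10**6))
        genome, genes = generate_reference(cfg)
        with pytest.raises(ConfigError):
            simulate_strain_contigs(genes, genome, cfg)


class TestGO:
    def test_background_rate_is_binomial(self):
        cfg = small_config(go_spec=GOSpec(n_terms=1, p_background=0.05))
        genes = [f"g{i}" for i in range(100)]
        ann, _ = generate_go_annotations(genes, cfg)
        count = len(ann["GO:0000001"])
        sigma = np.sqrt(100 * 0.05 * 0.95)
        assert abs(count - 5) <= 3 * sigma

    def test_enriched_term_annotates_most_designated_genes(self):
        designated = tuple(f"g{i}" for i in range(20))
        hits = 0
        for seed in range(20):
            cfg = small_config(
                seed=seed,
                go_spec=GOSpec(n_terms=2, p_background=0.05,
                               enriched={"GO:0000001": (designated, 0.9)}),
            )
            ann, _ = generate_go_annotations(list(designated) + ["x1", "x2"], cfg)
            if len(ann["GO:0000001"] & set(designated)) >= 12:
                hits += 1
        assert hits == 20  # P(<12 of Binomial(20, 0.9)) < 1e-4 per seed

    def test_p_hi_not_above_background_rejected(self):
        with pytest.raises(ConfigError):
            small_config(go_spec=GOSpec(
                n_terms=2, p_background=0.5, enriched={"GO:0000001": (("g01",), 0.3)}))

    def test_empty_enrichment_spec_gives_pure_background(self):
        cfg = small_config(go_spec=GOSpec(n_terms=3, p_background=0.0))
        ann, truth = generate_go_annotations(["g1", "g2"], cfg)
        assert all(not v for v in ann.values())
        assert truth.enriched_terms == []


class TestArtifacts:
    def test_written_dataset_verifies_against_truth(self, tmp_path):
        cfg = small_config(
            planted_variants=[PlantedVariant("g01", 150, "substitution", None)],
            planted_islands=[PlantedIsland(("g02", "3p"), 400, 0.6, 0.8)],
            planted_motifs=[PlantedMotif("TTGACGTCAT", ("g01", "g04"))],
        )
        ds = simulate_dataset(cfg, out_dir=str(tmp_path))
        assert verify_dataset(str(tmp_path)) == []

    def test_full_determinism_of_artifact_set(self, tmp_path):
        cfg = small_config(seed=77)
        a, b = tmp_path / "a", tmp_path / "b"
        write_dataset(simulate_dataset(cfg), str(a))
        write_dataset(simulate_dataset(cfg), str(b))
        for name in ("genome.fasta", "genes.gff3", "contigs.fasta",
                     "cds.fasta", "go_annotations.tsv", "truth.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes()
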