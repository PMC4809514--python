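import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from regelscan.align import align_contig
from regelscan.variants import (
    ColumnMatrix,
    VariantCall,
    annotate_effects,
    build_column_matrix,
    call_variants,
    normalize_insertion,
)


def matrix_from_columns(reference, columns, insertions=None):
    m = ColumnMatrix(ref_id="ref", reference=reference)
    for pos, bases in columns.items():
        m.columns[pos] = [(f"c{i}", b) for i, b in enumerate(bases)]
    for slot, strings in (insertions or {}).items():
        m.insertions[slot] = [(f"c{i}", s) for i, s in enumerate(strings)]
    return m


class TestCaller:
    def test_unanimous_alternate_is_called(self):
        m = matrix_from_columns("CCCC", {1: "TTTTT"})
        (call,) = call_variants(m, min_support=2)
        assert (call.position, call.ref_allele, call.alt_allele) == (1, "C", "T")
        assert call.consensus_ratio == 1.0 and call.depth == 5

    def test_ratio_below_one_is_no_call(self):
        m = matrix_from_columns("CCCC", {1: "TTTC"})
        assert call_variants(m, min_support=2) == []

    def test_two_alternate_alleles_is_no_call(self):
        m = matrix_from_columns("CCCC", {1: "TGTG"})
        assert call_variants(m, min_support=2) == []

    def test_agreement_rule_over_all_two_allele_columns(self):
        # enumerate every depth-4 observation multiset over two alt alleles:
        # a call requires ratio 1.0 AND a single shared alternate base
        for obs in itertools.product("CTG", repeat=4):
            m = matrix_from_columns("ACAA", {1: "".join(obs)})
            calls = call_variants(m, min_support=2)
            alts = set(obs) - {"C"}
            expect_call = len(alts) == 1 and "C" not in obs
            assert bool(calls) == expect_call, obs

    def test_depth_below_min_support_is_no_call(self):
        m = matrix_from_columns("CCCC", {1: "T"})
        assert call_variants(m, min_support=2) == []

    def test_gap_observations_excluded_from_ratio(self):
        m = matrix_from_columns("CCCC", {1: ["T", "T", "-", "-"]})
        (call,) = call_variants(m, min_support=2)
        assert call.depth == 2 and call.consensus_ratio == 1.0

    def test_insertion_requires_unanimity_among_spanning_contigs(self):
        called = call_variants(
            matrix_from_columns("ACGT", {}, insertions={1: ["AT", "AT", "AT"]}), 2
        )
        assert len(called) == 1 and called[0].alt_allele == "CAT"
        assert not call_variants(
            matrix_from_columns("ACGT", {}, insertions={1: ["AT", "AT", ""]}), 2
        )

    def test_min_support_validation(self):
        with pytest.raises(ValueError):
            call_variants(matrix_from_columns("A", {}), min_support=0)

    def test_deletion_calling_behind_flag(self):
        m = matrix_from_columns("ACGT", {2: ["-", "-", "-"]})
        assert call_variants(m, 2) == []
        (d,) = call_variants(m, 2, call_deletions=True)
        assert d.kind == "deletion" and d.position == 2


class TestColumnMatrix:
    def test_depth_follows_contig_overlap(self):
        rng = np.random.default_rng(0)
        ref = "".join(rng.choice(list("ACGT"), size=60))
        alns = [
            align_contig(ref[10:30], ref, contig_id="a"),
            align_contig(ref[20:45], ref, contig_id="b"),
        ]
        m = build_column_matrix(alns, ref)
        assert len(m.columns[25]) == 2
        assert len(m.columns[12]) == 1
        assert 50 not in m.columns  # uncovered reference position

    def test_identical_insertions_share_one_slot(self):
        rng = np.random.default_rng(1)
        ref = "".join(rng.choice(list("ACGT"), size=80))
        mutant = ref[:40] + "CA" + ref[40:]
        alns = [
            align_contig(mutant[5:70], ref, contig_id="a"),
            align_contig(mutant[10:75], ref, contig_id="b"),
        ]
        m = build_column_matrix(alns, ref)
        slots = {k: v for k, v in m.insertions.items() if any(s for _, s in v)}
        assert len(slots) == 1
        (obs,) = slots.values()
        assert sorted(s for _, s in obs) == ["CA", "CA"]

    def test_conflicting_reference_ids_rejected(self):
        aln = align_contig("ACGT", "AACGTT", ref_id="other")
        with pytest.raises(ValueError):
            build_column_matrix([aln], "AACGTT", ref_id="ref")


def test_normalize_insertion_left_aligns_in_repeats():
    #            0123456
    reference = "TTAAAAG"
    # inserting "A" anywhere in the A-run is the same event, left-aligned to slot 1
    for slot in (2, 3, 4, 5):
        assert normalize_insertion(reference, slot, "A") == (1, "A")
    # "CA" after the run end rotates one step left ("AC" after slot 4) and stops
    assert normalize_insertion(reference, 5, "CA") == (4, "AC")


def sub(pos0, ref, alt):
    return VariantCall("g", pos0, "substitution", ref, alt, 1.0, 3)


class TestEffects:
    @pytest.mark.parametrize(
        "cds,pos0,alt,aa,klass",
        [
            ("CAT", 0, "T", ("H", "Y"), "missense"),   # TAT
            ("ACG", 2, "A", ("T", "T"), "synonymous"),  # ACA
            ("AAG", 1, "T", ("K", "M"), "missense"),   # ATG
            ("TGG", 1, "A", ("W", "*"), "nonsense"),   # TAG
        ],
    )
    def test_single_substitutions(self, cds, pos0, alt, aa, klass):
        (e,) = annotate_effects([sub(pos0, cds[pos0], alt)], cds)
        assert (e.ref_aa, e.alt_aa) == aa
        assert e.effect_class == klass

    def test_every_single_base_mutant_of_atg_is_nonsynonymous(self):
        for pos0 in range(3):
            for alt in "ACGT":
                if alt == "ATG"[pos0]:
                    continue
                (e,) = annotate_effects([sub(pos0, "ATG"[pos0], alt)], "ATG")
                assert e.effect_class in ("missense", "nonsense")

    def test_same_codon_substitutions_applied_jointly(self):
        # GAA with G->T and A->C at codon positions 1 and 2 reads TCA (E->S);
        # either substitution alone would read differently (TAA is a stop)
        cds = "GAA"
        (e,) = annotate_effects([sub(0, "G", "T"), sub(1, "A", "C")], cds)
        assert (e.ref_aa, e.alt_aa, e.effect_class) == ("E", "S", "missense")
        singles = annotate_effects([sub(0, "G", "T"), sub(1, "A", "C")], cds, joint=False)
        assert {s.effect_class for s in singles} == {"nonsense", "missense"}

    def test_frameshift_insertion(self):
        ins = VariantCall("g", 1, "insertion", "C", "CG", 1.0, 3)
        (e,) = annotate_effects([ins], "ACT")
        assert e.effect_class == "frameshift"
        in_frame = VariantCall("g", 1, "insertion", "C", "CGGG", 1.0, 3)
        (e,) = annotate_effects([in_frame], "ACT")
        assert e.effect_class != "frameshift"

    def test_input_validation(self):
        with pytest.raises(ValueError):
            annotate_effects([sub(5, "A", "T")], "ACG")  # outside CDS
        with pytest.raises(ValueError):
            annotate_effects([sub(0, "A", "N")], "ACG")  # non-ACGT allele
        with pytest.raises(ValueError):
            annotate_effects([], "ACGT")  # length not divisible by 3

    def test_agrees_with_full_translation_oracle(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            cds = "".join(rng.choice(bases, size=3 * int(rng.integers(5, 60))))
            k = int(rng.integers(1, 5))
            positions = sorted(rng.choice(len(cds), size=k, replace=False))
            variants = []
            mutant = list(cds)
            for p in positions:
                alt = rng.choice([b for b in "ACGT" if b != cds[p]])
                variants.append(sub(int(p), cds[p], str(alt)))
                mutant[p] = str(alt)
            ref_prot = str(Seq(cds).translate())
            alt_prot = str(Seq("".join(mutant)).translate())
            effects = annotate_effects(variants, cds)
            changed = {i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b}
            assert {e.codon_index - 1 for e in effects if e.effect_class != "synonymous"} == changed
            for e in effects:
                assert e.ref_aa == ref_prot[e.codon_index - 1]
                assert e.alt_aa == alt_prot[e.codon_index - 1]
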