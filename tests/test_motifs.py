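from collections import Counter

import numpy as np
import pytest

from regelscan.io import GeneModel, reverse_complement
from regelscan.motifs import (
    MotifModel,
    associate_motif_go,
    background_frequencies,
    compare_motifs,
    discover_motifs_zoops,
    extract_promoters,
    mononucleotide_shuffle,
    motif_significance,
    presence_matrix,
)

BASES = "ACGT"


def random_seqs(rng, n, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return {
        f"s{i:02d}": "".join(rng.choice(list(BASES), size=length, p=p))
        for i in range(n)
    }


def plant(seqs, motif, genes, rng, mutation_rate=0.0):
    """Overwrite one instance per designated sequence at a random offset."""
    out = dict(seqs)
    sites = {}
    for g in genes:
        s = out[g]
        off = int(rng.integers(0, len(s) - len(motif) + 1))
        inst = list(motif)
        for k in range(len(inst)):
            if rng.random() < mutation_rate:
                inst[k] = str(rng.choice([b for b in BASES if b != inst[k]]))
        out[g] = s[:off] + "".join(inst) + s[off + len(motif):]
        sites[g] = off
    return out, sites


def pwm_from_consensus(consensus, p=0.9):
    w = len(consensus)
    pwm = np.full((4, w), (1 - p) / 3)
    for j, b in enumerate(consensus):
        pwm[BASES.index(b), j] = p
    return pwm


def motif_from_consensus(consensus, lam=0.2, bg=None):
    bg = np.full(4, 0.25) if bg is None else bg
    return MotifModel(
        name=consensus, pwm=pwm_from_consensus(consensus), zoops_lambda=lam,
        background=bg, sites=[], log_likelihood_ratio=0.0,
    )


class TestPromoterExtraction:
    def _genome_and_genes(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(BASES), size=9000))
        genes = [
            GeneModel("plus", "chr1", "+", [(5000, 5600)], 5000, 5600),
            GeneModel("minus", "chr1", "-", [(6500, 7000)], 6500, 7000),
            GeneModel("edge", "chr1", "+", [(500, 900)], 500, 900),
        ]
        return {"chr1": seq}, genes

    def test_plus_strand_window(self):
        genome, genes = self._genome_and_genes()
        proms, _ = extract_promoters(genome, genes)
        assert proms["plus"] == genome["chr1"][4000:5000]

    def test_minus_strand_is_reverse_complemented(self):
        genome, genes = self._genome_and_genes()
        proms, _ = extract_promoters(genome, genes)
        assert proms["minus"] == reverse_complement(genome["chr1"][7000:8000])

    def test_window_outside_sequence_is_excluded_with_reason(self):
        genome, genes = self._genome_and_genes()
        proms, excluded = extract_promoters(genome, genes)
        assert "edge" not in proms
        assert ("edge", "upstream window outside sequence") in excluded

    def test_promoter_with_n_is_excluded(self):
        genome, genes = self._genome_and_genes()
        seq = genome["chr1"]
        genome["chr1"] = seq[:4500] + "N" + seq[4501:]
        proms, excluded = extract_promoters(genome, genes)
        assert "plus" not in proms
        assert any(g == "plus" and "N" in r for g, r in excluded)


class TestZoopsEM:
    def test_noiseless_planting_recovers_consensus_and_lambda(self):
        rng = np.random.default_rng(1)
        seqs = random_seqs(rng, 8, 80)
        seqs, _ = plant(seqs, "TTGACA", seqs.keys(), rng)
        (m,) = discover_motifs_zoops(seqs, widths=[6], n_motifs=1, seed=0)
        assert m.consensus == "TTGACA"
        assert m.zoops_lambda > 0.9
        assert len(m.sites) == 8

    def test_mutated_planting_recovers_most_consensus_columns(self):
        rng = np.random.default_rng(2)
        seqs = random_seqs(rng, 10, 200)
        seqs, _ = plant(seqs, "TATAAT", list(seqs)[:8], rng, mutation_rate=0.10)
        (m,) = discover_motifs_zoops(seqs, widths=[6], n_motifs=1, seed=0)
        agree = sum(a == b for a, b in zip(m.consensus, "TATAAT"))
        assert agree >= 5

    def test_em_objective_is_monotone_and_columns_stochastic(self):
        rng = np.random.default_rng(3)
        seqs = random_seqs(rng, 6, 120)
        (m,) = discover_motifs_zoops(seqs, widths=[8], n_motifs=1, seed=1)
        trace = np.array(m.ll_trace)
        assert (np.diff(trace) >= -1e-6).all()
        assert np.allclose(m.pwm.sum(axis=0), 1.0, atol=1e-9)

    def test_input_validation(self):
        rng = np.random.default_rng(4)
        seqs = random_seqs(rng, 4, 30)
        with pytest.raises(ValueError):
            discover_motifs_zoops(seqs, widths=[40], n_motifs=1, seed=0)
        with pytest.raises(ValueError):
            discover_motifs_zoops(seqs, widths=[6], n_motifs=0, seed=0)
        with pytest.raises(ValueError):
            discover_motifs_zoops({"one": "ACGTACGT"}, widths=[6], n_motifs=1, seed=0)

    def test_second_motif_found_after_masking(self):
        rng = np.random.default_rng(5)
        seqs = random_seqs(rng, 8, 120)
        seqs, _ = plant(seqs, "GGGCGCCC", seqs.keys(), rng)
        seqs, _ = plant(seqs, "TTATATAA", seqs.keys(), rng)
        found = discover_motifs_zoops(seqs, widths=[8], n_motifs=2, seed=0)
        consensi = {m.consensus for m in found}
        assert "GGGCGCCC" in consensi and "TTATATAA" in consensi


class TestSignificance:
    def test_shuffle_preserves_base_composition(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGTN"), size=500))
        assert Counter(mononucleotide_shuffle(seq, rng)) == Counter(seq)

    def test_strongly_planted_motif_reaches_minimum_p(self):
        rng = np.random.default_rng(7)
        seqs = random_seqs(rng, 8, 60)
        seqs, _ = plant(seqs, "GGATCC", seqs.keys(), rng)
        (m,) = discover_motifs_zoops(seqs, widths=[6], n_motifs=1, seed=0)
        p = motif_significance(m, seqs, n_permutations=199, seed=0,
                               n_seeds=10, max_iter=30)
        assert p == pytest.approx(1 / 200)

    def test_zero_permutations_rejected(self):
        m = motif_from_consensus("ACGTAC")
        with pytest.raises(ValueError):
            motif_significance(m, {"a": "ACGTACGT", "b": "TTTTACGT"}, 0)

    def test_null_inputs_are_rarely_significant(self):
        insignificant = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            seqs = random_seqs(rng, 6, 50)
            (m,) = discover_motifs_zoops(seqs, widths=[6], n_motifs=1, seed=seed,
                                         n_seeds=10, max_iter=30)
            p = motif_significance(m, seqs, n_permutations=39, seed=seed,
                                   n_seeds=10, max_iter=30)
            if p > 0.05:
                insignificant += 1
        assert insignificant >= 9


class TestPresence:
    def test_planted_subset_recovered_exactly(self):
        rng = np.random.default_rng(8)
        proms = random_seqs(rng, 10, 400)
        designated = ["s00", "s01"]
        proms, _ = plant(proms, "TTGACGTCAT", designated, rng)
        motif = motif_from_consensus("TTGACGTCAT", lam=0.2)
        mat = presence_matrix([motif], proms)
        assert sorted(mat.index[mat.iloc[:, 0]]) == designated

    def test_sharing_pattern_recovery_across_seeds(self):
        motifs = ["TTGACGTCAT", "GGGCACGTGC", "CCGATAAGGC"]
        total = correct = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            proms = random_seqs(rng, 10, 400)
            genes = list(proms)
            planted_in = {}
            for k, cons in enumerate(motifs):
                subset = sorted(rng.choice(genes, size=int(rng.integers(2, 7)),
                                           replace=False))
                proms, _ = plant(proms, cons, subset, rng, mutation_rate=0.05)
                planted_in[cons] = set(subset)
            models = [motif_from_consensus(c, lam=len(planted_in[c]) / 10)
                      for c in motifs]
            mat = presence_matrix(models, proms)
            for c in motifs:
                for g in genes:
                    total += 1
                    correct += mat.loc[g, c] == (g in planted_in[c])
        assert correct / total >= 0.95

    def test_infinite_threshold_means_all_absent(self):
        rng = np.random.default_rng(9)
        proms = random_seqs(rng, 4, 100)
        motif = motif_from_consensus("ACGTAC")
        mat = presence_matrix([motif], proms, score_threshold_quantile=1.0)
        # the top quantile leaves at most the single best promoter present
        assert mat.to_numpy().sum() <= 1

    def test_empty_motif_list_rejected(self):
        with pytest.raises(ValueError):
            presence_matrix([], {"a": "ACGT"})


class TestCompare:
    def test_self_comparison_is_perfect(self):
        pwm = pwm_from_consensus("TTGACA")
        cmp_ = compare_motifs(pwm, pwm, compute_p=False)
        assert cmp_.correlation == pytest.approx(1.0)
        assert (cmp_.offset, cmp_.orientation) == (0, "+")

    def test_reverse_complement_detected(self):
        pwm = pwm_from_consensus("TTGACAGG")
        rc = pwm[::-1, ::-1]
        cmp_ = compare_motifs(pwm, rc, compute_p=False)
        assert cmp_.correlation == pytest.approx(1.0)
        assert cmp_.orientation == "-"

    def test_uniform_motif_has_finite_correlation(self):
        uni = np.full((4, 6), 0.25)
        cmp_ = compare_motifs(uni, pwm_from_consensus("ACGTAC"), compute_p=False)
        assert np.isfinite(cmp_.correlation)

    def test_symmetry_and_self_identity_on_random_pwms(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            w1, w2 = rng.integers(4, 12), rng.integers(4, 12)
            a = rng.dirichlet(np.ones(4), size=w1).T
            b = rng.dirichlet(np.ones(4), size=w2).T
            assert compare_motifs(a, a, compute_p=False).correlation == pytest.approx(1.0)
            ab = compare_motifs(a, b, compute_p=False).correlation
            ba = compare_motifs(b, a, compute_p=False).correlation
            assert ab == pytest.approx(ba)

    def test_planted_match_is_significant(self):
        rng = np.random.default_rng(11)
        pwm = pwm_from_consensus("TTGACGTCAT")
        noisy = 0.8 * pwm + 0.2 * rng.dirichlet(np.ones(4), size=10).T
        cmp_ = compare_motifs(pwm, noisy, n_shuffles=999, seed=0)
        assert cmp_.p_value < 0.05

    def test_too_short_overlap_rejected(self):
        with pytest.raises(ValueError):
            compare_motifs(pwm_from_consensus("ACG"), pwm_from_consensus("ACGTGCA"))


class TestMotifGO:
    def test_shifted_scores_are_detected(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(60)]
        scores = {g: float(rng.normal()) for g in genes}
        members = set(genes[:30])
        for g in members:
            scores[g] += 2.0
        res = associate_motif_go(scores, {"GO:X": members, "GO:Y": set(genes[30:])})
        byterm = {r.term: r for r in res}
        assert byterm["GO:X"].p_adjusted < 0.05
        assert byterm["GO:X"].p_adjusted >= byterm["GO:X"].p_value

    def test_underpowered_term_skipped_with_warning(self):
        scores = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 0.5}
        with pytest.warns(UserWarning, match="skipped"):
            res = associate_motif_go(scores, {"GO:tiny": {"a"}})
        assert res == []


def test_background_frequencies_normalised():
    bg = background_frequencies({"a": "AACG", "b": "TTTT"})
    assert bg.sum() == pytest.approx(1.0)
    assert bg[3] == pytest.approx(4 / 8)
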