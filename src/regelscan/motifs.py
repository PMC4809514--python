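"""Promoter extraction and ZOOPS motif discovery with a seeded EM algorithm.

The occurrence model is Zero-Or-One-Per-Sequence: each promoter carries at most
one site of a motif, governed by an occupancy prior lambda. Motifs are position
probability matrices (4 x w, pseudocount 0.25 per cell) over a 0-order
background estimated from the input. Significance is a seeded permutation test
(per-sequence mononucleotide shuffles, discovery re-run with the same seeding
policy). Motif-motif comparison uses the best mean column-wise Pearson
correlation over ungapped offsets and both orientations; motif-GO association
is a one-sided rank-sum test on per-gene best site scores, BH-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import mannwhitneyu

from .io import GeneModel

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGTN")}
PSEUDOCOUNT = 0.25


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------


def extract_promoters(
    genome: dict[str, str],
    genes: list[GeneModel],
    length: int = 1000,
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Strand-corrected upstream windows of ``length`` bp per gene.

    Minus-strand promoters are reverse-complemented so every returned sequence
    reads 5'->3' toward its gene. Genes whose window leaves the sequence or
    contains any N are excluded and reported with a reason.
    """
    from .io import reverse_complement

    promoters: dict[str, str] = {}
    excluded: list[tuple[str, str]] = []
    for gene in genes:
        seq = genome.get(gene.seq_id)
        if seq is None:
            excluded.append((gene.gene_id, f"sequence {gene.seq_id!r} missing"))
            continue
        gs, ge = gene.span
        if gene.strand == "+":
            a, b = gs - length, gs
        else:
            a, b = ge, ge + length
        if a < 0 or b > len(seq):
            excluded.append((gene.gene_id, "upstream window outside sequence"))
            continue
        window = seq[a:b]
        if "N" in window:
            excluded.append((gene.gene_id, "window contains N"))
            continue
        promoters[gene.gene_id] = window if gene.strand == "+" else reverse_complement(window)
    return promoters, excluded


# ---------------------------------------------------------------------------
# ZOOPS EM
# ---------------------------------------------------------------------------


@dataclass
class MotifModel:
    """A discovered motif: PPM, ZOOPS occupancy, sites and significance."""

    name: str
    pwm: np.ndarray  # 4 x w, columns sum to 1
    zoops_lambda: float
    background: np.ndarray  # length-4 base frequencies
    sites: list[tuple[str, int, str]]  # (sequence name, offset, strand)
    log_likelihood_ratio: float
    ll_trace: list[float] = field(default_factory=list)
    permutation_p: float | None = None

    @property
    def width(self) -> int:
        return int(self.pwm.shape[1])

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        return np.log(self.pwm) - np.log(self.background)[:, None]


class _WindowSet:
    """All width-w windows of a sequence collection, stacked for vector EM."""

    def __init__(self, seqs: dict[str, str], w: int):
        self.names = list(seqs)
        self.w = w
        arrays, slices = [], []
        start = 0
        for name in self.names:
            s = seqs[name]
            if len(s) < w:
                raise ValueError(f"sequence {name!r} shorter than motif width {w}")
            arr = np.fromiter((_CODE[b] for b in s), dtype=np.int8, count=len(s))
            win = sliding_window_view(arr, w)
            arrays.append(win)
            slices.append((start, start + len(win)))
            start += len(win)
        self.X = np.ascontiguousarray(np.concatenate(arrays)).astype(np.intp)
        self.slices = slices
        self.valid = ~(self.X >= 4).any(axis=1)

    @property
    def n_seqs(self) -> int:
        return len(self.names)

    def effective_m(self, mask: np.ndarray) -> np.ndarray:
        return np.array(
            [int((self.valid & mask)[s:e].sum()) for s, e in self.slices]
        )

    def window_scores(self, log_odds: np.ndarray, mask: np.ndarray) -> np.ndarray:
        ok = self.valid & mask
        scores = np.full(len(self.X), -np.inf)
        Xo = self.X[ok]
        scores[ok] = log_odds[Xo, np.arange(self.w)].sum(axis=1)
        return scores


def background_frequencies(seqs: dict[str, str]) -> np.ndarray:
    counts = np.zeros(4)
    for s in seqs.values():
        for i, b in enumerate(BASES):
            counts[i] += s.count(b)
    total = counts.sum()
    if total == 0:
        raise ValueError("no ACGT content to estimate a background from")
    return counts / total


def _pwm_from_kmer(codes: np.ndarray, seed_prob: float = 0.7) -> np.ndarray:
    w = len(codes)
    pwm = np.full((4, w), (1 - seed_prob) / 3)
    pwm[codes, np.arange(w)] = seed_prob
    return pwm


def _em(
    ws: _WindowSet,
    pwm: np.ndarray,
    lam: float,
    bg: np.ndarray,
    mask: np.ndarray,
    max_iter: int,
    tol: float,
):
    """Run ZOOPS EM to convergence; returns (pwm, lambda, llr, posteriors, trace).

    The tracked objective is the observed-data log-likelihood ratio against the
    background-only model plus the Dirichlet pseudocount prior on the matrix;
    MAP-EM guarantees it is non-decreasing, and that is asserted every run.
    """
    log_bg = np.log(bg)
    m_eff = ws.effective_m(mask)
    if (m_eff == 0).any():
        raise ValueError("a sequence has no admissible motif window")
    starts = np.array([s for s, _ in ws.slices])
    lengths = np.array([e - s for s, e in ws.slices])
    trace: list[float] = []
    prev_obj = -np.inf
    llr = -np.inf
    posts = np.zeros(len(ws.X))
    for _ in range(max_iter):
        log_odds = np.log(pwm) - log_bg[:, None]
        scores = ws.window_scores(log_odds, mask)
        c = scores + np.repeat(np.log(lam / m_eff), lengths)
        mx = np.maximum.reduceat(c, starts)
        sums = np.add.reduceat(np.exp(c - np.repeat(mx, lengths)), starts)
        z = np.logaddexp(mx + np.log(sums), np.log1p(-lam))
        posts = np.exp(c - np.repeat(z, lengths))
        llr = float(z.sum())
        obj = llr + PSEUDOCOUNT * np.log(pwm).sum()
        assert obj >= prev_obj - 1e-6, "EM objective decreased"
        trace.append(obj)
        if abs(obj - prev_obj) < tol:
            break
        prev_obj = obj
        counts = np.full((4, ws.w), PSEUDOCOUNT)
        ok = ws.valid & mask
        wts = posts * ok
        for k in range(ws.w):
            counts[:, k] += np.bincount(ws.X[:, k], weights=wts, minlength=5)[:4]
        pwm = counts / counts.sum(axis=0)
        site_mass = np.add.reduceat(wts, starts)
        # cap the occupancy prior so the "no site" alternative keeps non-trivial
        # mass; an uncapped lambda runs away to 1 on weak ubiquitous patterns
        lam = float(np.clip(site_mass.mean(), 1e-6, 1 - 1 / (2 * ws.n_seqs)))
    return pwm, lam, llr, posts, trace


def _candidate_kmers(ws: _WindowSet, n_seeds: int, rng: np.random.Generator):
    """Seed k-mers: the most multi-sequence-repeated windows plus random ones."""
    counts: dict[bytes, set[int]] = {}
    owner = np.concatenate(
        [np.full(e - s, i) for i, (s, e) in enumerate(ws.slices)]
    )
    valid_idx = np.flatnonzero(ws.valid)
    for i in valid_idx:
        key = ws.X[i].tobytes()
        counts.setdefault(key, set()).add(int(owner[i]))
    ranked = sorted(counts, key=lambda k: (-len(counts[k]), k))
    top = ranked[: max(1, n_seeds // 2)]
    n_rand = max(0, n_seeds - len(top))
    picks = list(top)
    if n_rand and len(valid_idx):
        chosen = rng.choice(valid_idx, size=min(n_rand, len(valid_idx)), replace=False)
        picks.extend(ws.X[i].tobytes() for i in chosen)
    return [np.frombuffer(p, dtype=ws.X.dtype) for p in picks]


def _discover_single(
    seqs: dict[str, str],
    width: int,
    seed_rng: np.random.Generator,
    n_seeds: int,
    max_iter: int,
    tol: float,
    bg: np.ndarray,
    mask: np.ndarray | None = None,
    ws: _WindowSet | None = None,
):
    ws = ws if ws is not None else _WindowSet(seqs, width)
    mask = mask if mask is not None else np.ones(len(ws.X), dtype=bool)
    lam0 = 0.5
    best = None
    for codes in _candidate_kmers(ws, n_seeds, seed_rng):
        pwm0 = _pwm_from_kmer(codes)
        pwm1, lam1, llr1, _, _ = _em(ws, pwm0, lam0, bg, mask, max_iter=2, tol=0.0)
        if best is None or llr1 > best[0]:
            best = (llr1, pwm1, lam1)
    _, pwm, lam = best
    pwm, lam, llr, posts, trace = _em(ws, pwm, lam, bg, mask, max_iter, tol)

    sites: list[tuple[str, int, str]] = []
    for name, (s, e) in zip(ws.names, ws.slices):
        seg = posts[s:e]
        if seg.sum() > 0.5:  # posterior says this sequence carries a site
            j = int(np.argmax(seg))
            sites.append((name, j, "+"))
    return pwm, lam, llr, sites, trace, ws


def discover_motifs_zoops(
    sequences: dict[str, str],
    widths=(6, 8, 10, 12, 15),
    n_motifs: int = 3,
    seed: int = 0,
    n_seeds: int = 30,
    max_iter: int = 100,
    tol: float = 1e-5,
    n_permutations: int = 0,
) -> list[MotifModel]:
    """Discover up to ``n_motifs`` motifs by ZOOPS EM across a width set.

    For each motif slot, EM is run per width from the best of ``n_seeds``
    substring-derived starts and the width with the highest log-likelihood
    ratio wins; the accepted motif's sites are then masked before the next
    slot. With ``n_permutations`` > 0 a permutation p-value is attached and the
    output is sorted by significance then LLR.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    if len(sequences) < 2:
        raise ValueError("motif discovery requires at least 2 sequences")
    widths = sorted(set(int(w) for w in widths))
    for w in widths:
        if not 1 <= w <= min(len(s) for s in sequences.values()):
            raise ValueError(f"width {w} exceeds the shortest sequence")
    rng = np.random.default_rng(seed)
    bg = background_frequencies(sequences)
    window_sets = {w: _WindowSet(sequences, w) for w in widths}
    masks = {w: np.ones(len(window_sets[w].X), dtype=bool) for w in widths}
    # excluded intervals per sequence, shared across widths
    blocked: dict[str, list[tuple[int, int]]] = {name: [] for name in sequences}

    motifs: list[MotifModel] = []
    for slot in range(n_motifs):
        slot_rng = np.random.default_rng(rng.integers(2**31))
        best = None
        for w in widths:
            try:
                res = _discover_single(
                    sequences, w, np.random.default_rng(slot_rng.integers(2**31)),
                    n_seeds, max_iter, tol, bg,
                    mask=masks[w], ws=window_sets[w],
                )
            except ValueError:
                continue
            if best is None or res[2] > best[2]:
                best = res + (w,)
        if best is None:
            break
        pwm, lam, llr, sites, trace, _, w = best
        motif = MotifModel(
            name=f"motif_{slot + 1}",
            pwm=pwm,
            zoops_lambda=lam,
            background=bg,
            sites=sites,
            log_likelihood_ratio=llr,
            ll_trace=trace,
        )
        if n_permutations:
            motif.permutation_p = motif_significance(
                motif, sequences, n_permutations=n_permutations,
                seed=int(rng.integers(2**31)), n_seeds=n_seeds,
                max_iter=max_iter, tol=tol,
            )
        motifs.append(motif)
        for name, off, _ in sites:
            blocked[name].append((off - w + 1, off + w))
        for wk, ws_k in window_sets.items():
            for idx, name in enumerate(ws_k.names):
                s, e = ws_k.slices[idx]
                offs = np.arange(e - s)
                for (a, b) in blocked[name]:
                    masks[wk][s:e] &= ~((offs >= a) & (offs < b))
    if any(m.permutation_p is not None for m in motifs):
        motifs.sort(key=lambda m: (m.permutation_p, -m.log_likelihood_ratio))
        for i, m in enumerate(motifs, start=1):
            m.name = f"motif_{i}"
    return motifs


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    letters = np.array(list(seq))
    return "".join(rng.permutation(letters))


def motif_significance(
    motif: MotifModel,
    sequences: dict[str, str],
    n_permutations: int,
    seed: int = 0,
    n_seeds: int = 30,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> float:
    """Permutation p-value for a discovered motif's log-likelihood ratio.

    Each permutation mononucleotide-shuffles every sequence, re-runs single-
    width discovery with the same seeding policy, and scores the permuted LLR;
    p = (1 + #{permuted LLR >= observed}) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    bg = background_frequencies(sequences)
    w = motif.width
    exceed = 0
    for _ in range(n_permutations):
        shuffled = {k: mononucleotide_shuffle(v, rng) for k, v in sequences.items()}
        _, _, llr, _, _, _ = _discover_single(
            shuffled, w, np.random.default_rng(rng.integers(2**31)),
            n_seeds, max_iter, tol, bg,
        )
        if llr >= motif.log_likelihood_ratio:
            exceed += 1
    return (1 + exceed) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Scoring promoters against motifs
# ---------------------------------------------------------------------------


def _revcomp_pwm(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1]


def best_site_scores(motif: MotifModel, sequences: dict[str, str]) -> dict[str, float]:
    """Best log-odds site score per sequence, scanning both strands."""
    out: dict[str, float] = {}
    lo_f = motif.log_odds()
    lo_r = np.log(_revcomp_pwm(motif.pwm)) - np.log(motif.background)[:, None]
    for name, seq in sequences.items():
        arr = np.fromiter((_CODE[b] for b in seq), dtype=np.intp, count=len(seq))
        win = sliding_window_view(arr, motif.width)
        ok = ~(win >= 4).any(axis=1)
        best = -np.inf
        for lo in (lo_f, lo_r):
            if ok.any():
                sc = lo[win[ok], np.arange(motif.width)].sum(axis=1)
                best = max(best, float(sc.max()))
        out[name] = best
    return out


def presence_matrix(
    motifs: list[MotifModel],
    promoters: dict[str, str],
    score_threshold_quantile: float | None = None,
):
    """Gene x motif boolean presence matrix.

    A motif is present in a promoter when its best log-odds site score (both
    strands) exceeds the threshold at which the ZOOPS site posterior passes
    0.5 — ``log(m * (1 - lambda) / lambda)`` for m possible sites — or, if
    ``score_threshold_quantile`` is given, that quantile of the per-gene best
    scores.
    """
    import pandas as pd

    if not motifs:
        raise ValueError("presence_matrix requires at least one motif")
    data = {}
    for m in motifs:
        scores = best_site_scores(m, promoters)
        vals = np.array([scores[g] for g in promoters])
        if score_threshold_quantile is not None:
            thr = float(np.quantile(vals, score_threshold_quantile))
        else:
            # site posterior > 0.5 under the fitted lambda: the inserted site
            # must outweigh both the no-site alternative and the ~m background
            # windows, whose expected summed odds mass is m (E_bg[e^s] = 1)
            lam = min(max(m.zoops_lambda, 1e-9), 1 - 1e-9)
            m_sites = np.mean([len(s) - m.width + 1 for s in promoters.values()])
            competing = (1 - lam) + lam * (m_sites - 1) / m_sites
            thr = float(np.log(m_sites * competing / lam))
        data[m.name] = vals > thr
    return pd.DataFrame(data, index=list(promoters))


# ---------------------------------------------------------------------------
# Motif comparison (Pearson, over offsets and orientations)
# ---------------------------------------------------------------------------


@dataclass
class MotifComparison:
    correlation: float
    offset: int
    orientation: str  # '+' or '-'
    p_value: float | None = None


def _column_correlations(q: np.ndarray, t: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Pearson correlation between every query and target column (4-vectors)."""
    qa = q + eps
    ta = t + eps
    qa = qa - qa.mean(axis=0)
    ta = ta - ta.mean(axis=0)
    qn = np.sqrt((qa**2).sum(axis=0))
    tn = np.sqrt((ta**2).sum(axis=0))
    # an exactly uniform column has no variance even after the pseudocount;
    # its correlation with anything is defined as 0
    qn = np.where(qn < 1e-12, np.inf, qn)
    tn = np.where(tn < 1e-12, np.inf, tn)
    return (qa.T @ ta) / np.outer(qn, tn)


def _best_over_offsets(C: np.ndarray, min_overlap: int) -> tuple[float, int]:
    wq, wt = C.shape
    best, best_off = -np.inf, 0
    for off in range(-(wt - min_overlap), wq - min_overlap + 1):
        qi = np.arange(max(0, off), min(wq, wt + off))
        ti = qi - off
        if len(qi) < min_overlap:
            continue
        score = float(C[qi, ti].mean())
        if score > best:
            best, best_off = score, off
    return best, best_off


def compare_motifs(
    query: np.ndarray,
    target: np.ndarray,
    min_overlap: int = 4,
    n_shuffles: int = 10_000,
    seed: int = 0,
    compute_p: bool = True,
) -> MotifComparison:
    """Best mean column-wise Pearson correlation over offsets and orientations.

    The p-value is the rank of the observed score among ``n_shuffles``
    column-order-shuffled targets (seeded), add-one corrected.
    """
    if query.shape[0] != 4 or target.shape[0] != 4:
        raise ValueError("PWMs must be 4 x w")
    if min(query.shape[1], target.shape[1]) < min_overlap:
        raise ValueError(f"motifs too short for an overlap of {min_overlap} columns")
    C_f = _column_correlations(query, target)
    C_r = _column_correlations(query, _revcomp_pwm(target))
    s_f, off_f = _best_over_offsets(C_f, min_overlap)
    s_r, off_r = _best_over_offsets(C_r, min_overlap)
    if s_f >= s_r:
        best, offset, orient = s_f, off_f, "+"
    else:
        best, offset, orient = s_r, off_r, "-"
    p = None
    if compute_p:
        rng = np.random.default_rng(seed)
        wt = target.shape[1]
        exceed = 0
        for _ in range(n_shuffles):
            perm = rng.permutation(wt)
            sp_f, _ = _best_over_offsets(C_f[:, perm], min_overlap)
            sp_r, _ = _best_over_offsets(C_r[:, perm[::-1]], min_overlap)
            if max(sp_f, sp_r) >= best - 1e-12:
                exceed += 1
        p = (1 + exceed) / (n_shuffles + 1)
    return MotifComparison(correlation=best, offset=offset, orientation=orient, p_value=p)


# ---------------------------------------------------------------------------
# Motif -> GO association (rank-sum over best site scores)
# ---------------------------------------------------------------------------


@dataclass
class MotifGOResult:
    term: str
    statistic: float
    p_value: float
    p_adjusted: float


def associate_motif_go(
    gene_scores: dict[str, float],
    annotations: dict[str, set[str]],
) -> list[MotifGOResult]:
    """Rank-sum association between a motif's per-gene scores and GO terms.

    For each term with >= 2 annotated and >= 2 unannotated genes, tests
    one-sided (annotated genes score higher) with Mann-Whitney U, then applies
    Benjamini-Hochberg across terms. Under-powered terms are skipped with a
    warning.
    """
    from statsmodels.stats.multitest import multipletests

    genes = list(gene_scores)
    results = []
    for term in sorted(annotations):
        members = annotations[term] & set(genes)
        others = [g for g in genes if g not in members]
        if len(members) < 2 or len(others) < 2:
            warnings.warn(f"term {term!r} skipped: fewer than 2 genes on one side")
            continue
        x = [gene_scores[g] for g in sorted(members)]
        y = [gene_scores[g] for g in others]
        stat, p = mannwhitneyu(x, y, alternative="greater")
        results.append([term, float(stat), float(p)])
    if not results:
        return []
    _, adj, _, _ = multipletests([r[2] for r in results], method="fdr_bh")
    return [
        MotifGOResult(term=r[0], statistic=r[1], p_value=r[2], p_adjusted=float(a))
        for r, a in zip(results, adj)
    ]
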