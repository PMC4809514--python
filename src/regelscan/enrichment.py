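"""GO-term enrichment with the EASE-adjusted Fisher test and kappa clustering.

EASE is the conservative variant of the one-sided Fisher exact test in which
the list-hit count is decremented by one before the hypergeometric upper tail
is taken, so single-gene terms can never appear enriched. Terms are grouped
into functional annotation clusters by greedy agglomeration on Cohen's kappa
between their gene-membership vectors; each cluster's enrichment score is
-log10 of the geometric mean of its members' EASE p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class ContingencyInput:
    """list_hits a out of list_size n, against population_hits A of size N."""

    list_hits: int
    list_size: int
    population_hits: int
    population_size: int

    def __post_init__(self) -> None:
        a, n, A, N = (
            self.list_hits,
            self.list_size,
            self.population_hits,
            self.population_size,
        )
        if not (0 <= a <= n <= N and a <= A <= N):
            raise ValueError(f"invalid contingency input a={a} n={n} A={A} N={N}")


def fisher_upper_tail(table: ContingencyInput) -> float:
    """One-sided Fisher exact p: P(X >= a), X ~ Hypergeom(N, A, n)."""
    a, n, A, N = (
        table.list_hits,
        table.list_size,
        table.population_hits,
        table.population_size,
    )
    return float(hypergeom.sf(a - 1, N, A, n))


def ease_score(table: ContingencyInput) -> float:
    """EASE p-value: the Fisher upper tail with list hits decremented by one.

    a = 0 or 1 gives p = 1 by construction.
    """
    a = table.list_hits
    if a <= 1:
        return 1.0
    penalized = ContingencyInput(
        list_hits=a - 1,
        list_size=table.list_size,
        population_hits=table.population_hits,
        population_size=table.population_size,
    )
    return fisher_upper_tail(penalized)


def fold_enrichment(table: ContingencyInput) -> float:
    """(a/n) / (A/N)."""
    if table.population_hits == 0:
        raise ValueError("fold enrichment undefined for population_hits = 0")
    if table.list_size == 0:
        raise ValueError("fold enrichment undefined for an empty list")
    return (table.list_hits / table.list_size) / (
        table.population_hits / table.population_size
    )


def adjust_pvalues(ps, method: str = "benjamini_hochberg") -> list[float]:
    """Bonferroni or Benjamini-Hochberg adjustment, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    ps = list(ps)
    if not ps:
        raise ValueError("adjust_pvalues requires at least one p-value")
    if any(not 0 < p <= 1 for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    key = {"bonferroni": "bonferroni", "benjamini_hochberg": "fdr_bh"}
    if method not in key:
        raise ValueError(f"unknown method {method!r}")
    _, adj, _, _ = multipletests(ps, method=key[method])
    return [float(p) for p in adj]


@dataclass
class EnrichmentResult:
    term: str
    count: int
    ease_p: float
    bonferroni: float
    benjamini_bh: float
    fdr_display: float
    fold_enrichment: float


def enrich(
    gene_list: set[str] | list[str],
    annotations: dict[str, set[str]],
    population: set[str] | None = None,
) -> pd.DataFrame:
    """EASE enrichment of every term against a gene list.

    ``annotations`` maps term -> set of annotated genes. The population
    defaults to all genes appearing in the annotation table. Reported FDR is
    Benjamini-Hochberg. Rows are sorted by EASE p.
    """
    genes = set(gene_list)
    if population is None:
        population = set().union(*annotations.values()) if annotations else set()
    population = set(population) | genes
    N = len(population)
    n = len(genes)
    rows = []
    for term in sorted(annotations):
        members = annotations[term] & population
        a = len(members & genes)
        A = len(members)
        if A == 0:
            continue
        table = ContingencyInput(a, n, A, N)
        rows.append(
            {
                "term": term,
                "count": a,
                "p_value": ease_score(table),
                "fold_enrichment": fold_enrichment(table),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["term", "count", "p_value", "bonferroni", "benjamini", "fdr", "fold_enrichment"]
        )
    df["bonferroni"] = adjust_pvalues(df["p_value"], "bonferroni")
    df["benjamini"] = adjust_pvalues(df["p_value"], "benjamini_hochberg")
    df["fdr"] = df["benjamini"]
    df = df[["term", "count", "p_value", "bonferroni", "benjamini", "fdr", "fold_enrichment"]]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Kappa-similarity functional annotation clustering
# ---------------------------------------------------------------------------


def cohens_kappa(x: np.ndarray, y: np.ndarray) -> float:
    """Chance-corrected agreement between two binary membership vectors."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("membership vectors must have equal length")
    n = x.size
    po = float((x == y).mean())
    pe = float(x.mean() * y.mean() + (1 - x.mean()) * (1 - y.mean()))
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


@dataclass
class AnnotationCluster:
    members: list[str]
    enrichment_score: float


def enrichment_score(member_ease_ps) -> float:
    """-log10 of the geometric mean of a cluster's member p-values."""
    ps = np.asarray(list(member_ease_ps), dtype=float)
    if ps.size == 0:
        raise ValueError("enrichment_score of an empty cluster")
    if ((ps <= 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(-np.log10(ps).mean())


def kappa_cluster(
    membership: pd.DataFrame,
    kappa_threshold: float = 0.35,
    min_members: int = 3,
    term_ps: dict[str, float] | None = None,
) -> list[AnnotationCluster]:
    """Greedy agglomeration of terms by pairwise Cohen's kappa.

    ``membership`` is a genes x terms boolean DataFrame. Clustering seeds with
    the highest-kappa pair at or above the threshold, absorbs any remaining
    term whose mean kappa to current members stays at or above the threshold,
    then repeats on the remainder. Clusters smaller than ``min_members`` are
    dropped. When ``term_ps`` is given each cluster carries its enrichment
    score (else NaN).
    """
    if not 0.0 <= kappa_threshold < 1.0:
        raise ValueError("kappa_threshold must lie in [0, 1)")
    terms = list(membership.columns)
    if len(terms) < 2:
        raise ValueError("kappa clustering requires at least 2 terms")
    M = membership.to_numpy(dtype=bool)
    k = len(terms)
    K = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            K[i, j] = K[j, i] = cohens_kappa(M[:, i], M[:, j])

    remaining = list(range(k))
    clusters: list[AnnotationCluster] = []
    while len(remaining) >= 2:
        best_pair, best_kappa = None, kappa_threshold
        for ai, i in enumerate(remaining):
            for j in remaining[ai + 1 :]:
                if K[i, j] >= best_kappa:
                    if best_pair is None or K[i, j] > best_kappa:
                        best_pair, best_kappa = (i, j), K[i, j]
        if best_pair is None:
            break
        members = list(best_pair)
        changed = True
        while changed:
            changed = False
            for t in remaining:
                if t in members:
                    continue
                if K[t, members].mean() >= kappa_threshold:
                    members.append(t)
                    changed = True
        remaining = [t for t in remaining if t not in members]
        if len(members) >= min_members:
            names = [terms[t] for t in sorted(members)]
            if term_ps is not None:
                score = enrichment_score([term_ps[nm] for nm in names])
            else:
                score = float("nan")
            clusters.append(AnnotationCluster(members=names, enrichment_score=score))
    clusters.sort(
        key=lambda c: (-c.enrichment_score if c.enrichment_score == c.enrichment_score else 0.0)
    )
    return clusters
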