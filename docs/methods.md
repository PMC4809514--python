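# Methods

This note documents the models and procedures regelscan implements, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions that matter for reproducing output.

## Consensus-ratio variant calling

### Alignment

Strain contigs are assembled transcript fragments, expected to be
high-identity substrings of their gene's spliced CDS. Each contig is therefore
aligned pairwise to the reference CDS — a multiple alignment adds nothing once
the reference anchors all columns — by overlap (semi-global) dynamic
programming: linear gap penalty, free end gaps on both sequences, defaults
match +1, mismatch −1, gap −2. These values are deliberately simple; for
contigs at ≥ 95 % identity the optimal alignment is insensitive to them.

Traceback is deterministic: diagonal moves are preferred over a gap in the
contig, which is preferred over a gap in the reference, *except* that an open
gap run is extended on ties. The exception keeps multi-base insertions in one
contiguous run; without it, an inserted base that happens to match nearby
reference sequence can split an insertion into two single-base events of equal
score. Insertions are afterwards left-aligned within repeat context (the VCF
normalization convention), both in the caller and in the simulator's truth
table, so planted and called events are always compared in canonical form.

Because contig identifiers must not carry information, contigs are assigned to
references before alignment by a shared-15-mer vote; a contig sharing no
15-mer with any reference is left unassigned and skipped with a warning. This
prefilter is plumbing, not inference: at transcript-scale identity it is
essentially error-free and saves an all-vs-all alignment.

### Calling

At each reference column, gap observations are excluded from numerator and
denominator (a deletion is absence of evidence about the base, and deletion
calling is a separate, off-by-default flag). A substitution requires
consensus ratio exactly 1.0, depth ≥ `min_support`, and a single shared
alternate base. `min_support` defaults to 2 — the smallest per-gene contig set
the intended use case has. The criterion is deliberately maximally stringent:
it trades sensitivity for near-zero false positives, which suits unphased
contig evidence without quality scores. An insertion requires every contig
spanning both flanking positions to carry the identical inserted string; a
spanning contig without an insertion is counted as contradicting evidence.

Under independent per-base substitution errors at rate *e*, a false positive
at depth *d* requires *d* errors that agree on one alternate:
p ≈ e^d / 3^(d−1) per column (~10⁻¹⁰ at e = 0.01, d = 5), which the acceptance
script confirms empirically on 10⁶ simulated columns.

### Effect annotation

Substitutions are grouped by codon and applied jointly; every contributing
variant inherits the codon's class. The joint rule is not cosmetic: adjacent
same-codon substitutions annotated singly can produce spurious stop codons
(see the cyp6d1 records in the packaged catalogue, where only the joint
reading reproduces the published E→S and L→P changes). Per-variant annotation
remains available (`joint=False`). A stop-to-stop codon change is synonymous,
not nonsense. Frameshifts are classified at the affected codon only;
downstream codons are not re-annotated, matching how such tables are reported
for candidate-gene surveys. In-frame insertions are counted with the
non-synonymous classes.

## CpG islands

The detection criteria are the classical ones (window 200 bp, GC ≥ 0.5,
obs/exp CpG ≥ 0.6 with expected CpG = #C·#G/L, minimum island length 200 bp),
all configurable. Qualifying windows may not contain N. Merged intervals are
trimmed until the whole interval itself satisfies all three criteria; the trim
drops the terminal base that is not C/G, and shrinks one base from *each* end
on ties — the symmetric tie rule makes detection commute with
reverse-complementation, which is also a tested invariant (CpG content is
strand-symmetric). The expected-CpG denominator uses island length L, not
L − 1, matching the original criterion's formula.

Localization labels are a documented convention: "5'-end" when the island
touches the promoter window or the 5'-most quarter of the gene span, "3'-end"
for the 3'-most quarter, "internal" otherwise inside the gene, "intergenic"
when it overlaps no gene or promoter. When several genes overlap an island the
gene with the largest overlap wins, ties broken by identifier. Coverage lists
promoter/exon/intron features in transcription order.

## Promoters and ZOOPS motif discovery

Promoters are the 1,000 bp immediately upstream of the gene span,
strand-corrected (reverse-complemented for minus-strand genes); any window
containing an N, or extending beyond the sequence, excludes its gene with a
logged reason.

The occurrence model is Zero-Or-One-Per-Sequence: sequence *i* with *m*
admissible windows carries a motif site with prior probability λ, uniformly
placed. EM alternates the standard posterior computation with re-estimation of
the 4×w matrix (pseudocount 0.25 per cell, one quarter of a uniform prior
observation) and of λ. The tracked objective is the observed-data
log-likelihood ratio against the background-only model plus the Dirichlet
pseudocount prior; as MAP-EM it is non-decreasing and that is asserted on
every iteration of every run.

Numerical and initialization choices:

* λ starts at 0.5 and is re-estimated each M-step. Starting λ at 1/m (one
  expected site among all windows) looks natural but puts EM in the basin of
  the empty model — the site posterior mass scales with λ/m, so a tiny λ
  shrinks itself monotonically. 0.5 is agnostic and always climbs.
* λ is capped at 1 − 1/(2n) for n sequences. Without the cap, weak ubiquitous
  patterns drive λ → 1, at which point the "no site" alternative has vanishing
  mass and every sequence is assigned a site by construction.
* Seeding: candidate w-mers are the windows repeated in the most distinct
  sequences (plus random windows, `n_seeds` total); each is converted to a
  sharp matrix (0.7 on the seed base), refined by two EM iterations, and the
  best by LLR is run to convergence (`max_iter` 100, tol 1e-5 on the
  objective). This word-based seeding is what classical motif finders use and
  reliably finds planted patterns that exact-repeat in ≥ 2 sequences.
* Widths are a set (default {6, 8, 10, 12, 15} spanning the 6–50 range used
  for promoter scans) rather than every integer, for desk-scale runtime; per
  motif slot the width with the best LLR wins. LLR comparison across widths
  mildly favours wider motifs; significance filtering (below) is what
  ultimately accepts or rejects.
* Multiple motifs: after a motif is accepted its sites are masked (windows
  overlapping any site become inadmissible at every width) and the next slot
  is searched.

**Significance** is a seeded permutation test: each permutation
mononucleotide-shuffles every sequence (exactly preserving base composition),
re-runs single-width discovery with the same seeding policy, and compares the
permuted LLR with the observed one; p = (1 + #{LLR_perm ≥ LLR_obs}) / (B + 1).
This replaces MEME's analytic E-value machinery with something self-contained
whose null calibration is itself testable (type-I error ≈ 0.05, verified at
1,000 null replicates). With B permutations the smallest attainable p is
1/(B+1). Known limitation: a mononucleotide shuffle preserves composition but
not dinucleotide structure, so highly repetitive patterns (e.g. CA-repeats)
are penalized less than a Markov-aware null would penalize them; they do,
however, fail the test in practice (observed p ≈ 0.1–0.9 on the demo data)
while planted motifs reach the minimum attainable p.

**Presence matrix.** A motif is present in a promoter when its best log-odds
site score (both strands scanned, although EM itself runs single-strand on the
orientation-corrected promoters) exceeds the score at which the ZOOPS site
posterior passes 0.5 under the motif's λ. That threshold accounts for the
competition term — the ~m background windows contribute an expected summed
odds mass of m because E_bg[e^score] = 1 — giving
s* = log(m·((1−λ) + λ(m−1)/m)/λ). A quantile-based threshold is available as
an override. Presence discrimination is excellent for calibrated motif models
(the planted-pattern recovery checks run at 100 % cell accuracy); for models
EM-fitted on very small sequence sets the fitted λ tends toward its cap and
the threshold is correspondingly permissive — the motif's permutation p-value,
not its presence row, is the accept/reject signal there.

**Motif comparison** follows the Pearson-correlation approach of standard
motif-comparison tools: best mean column-wise correlation over all ungapped
offsets with ≥ 4 overlapping columns and both orientations, 1e-3 pseudocount
before correlating, a column with no variance even after the pseudocount
correlating as 0, and a seeded column-shuffle null (default 10,000) for the
p-value. The score is symmetric in its arguments.

**Motif→GO association** is a deliberately simplified analogue of
promoter-affinity GO scoring: per term, a one-sided Mann–Whitney U test that
annotated genes have higher best site scores, BH-corrected across terms; terms
with fewer than two genes on either side are skipped with a warning.

## EASE enrichment and kappa clustering

EASE = one-sided Fisher exact upper tail with the list-hit count decremented
by one (a ≤ 1 ⇒ p = 1), computed via the hypergeometric survival function and
verified in tests against explicit binomial-coefficient summation. EASE ≥
Fisher always (tested on random tables). The population defaults to all genes
in the annotation table, unioned with the query list. The reported FDR column
is Benjamini–Hochberg.

Annotation clustering: pairwise Cohen's kappa between term membership vectors
over the gene universe; greedy agglomeration seeds with the highest-kappa pair
at or above the threshold (default 0.35, the published default of the
tool that popularized this analysis), absorbs any term whose mean kappa to
current members stays at or above threshold, then repeats on the remainder;
clusters below `min_members` (3) are dropped. The cluster enrichment score is
−log10 of the geometric mean of member EASE p-values. The original tool's
fuzzy heuristic is unpublished in detail; this greedy variant preserves its
semantics (kappa similarity + geometric-mean score) while being exactly
specifiable and testable.

## Assembly statistics

N50 uses the "cumulative sum ≥ half" convention (ties included), checked
against a from-the-definition oracle; histogram bins are right-open with a
default width of 100 bp.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of a candidate-gene strain
comparison: one reference sequence carrying n genes (default 8) of 1–3 exons
with intergenic spacing and ~50/50 strand assignment; per-gene contig sets
with depth drawn from 2–14 (the per-gene contig counts typical of such
surveys); fixed variants planted in every overlapping contig — the ground
truth for the ratio-1.0 criterion — and optional polymorphic variants in a
fraction of contigs as no-call controls; substitution-only sequencing errors
at a default 0.001/bp (assembled-consensus scale; raw-454-scale 0.01 is used
explicitly in the false-positive checks); CpG-rich segments synthesized i.i.d.
at the target GC with verify-and-retry until the planted interval itself meets
both targets; motif instances at most one per designated promoter, uniformly
placed among positions that do not collide with other planted features; and
Bernoulli GO annotations with designated enriched terms.

One RNG stream per artifact kind, all spawned from the master seed, so adding
genes does not perturb contig noise; (seed, config) determine the artifact
set byte-for-byte, and an independent verifier re-reads the written FASTA/GFF3
artifacts against the truth table.

Deliberately not emulated: read-level data and quality scores, assembly
artifacts (chimeras, collapsed paralogs), homopolymer indel errors
(characteristic of 454 chemistry; off by default to keep the false-positive
analysis substitution-only), genome-scale background heterogeneity
(isochores, repeats), and realistic GO DAG structure. Passing the recovery
tests therefore demonstrates correctness of the algorithms under their stated
assumptions, not robustness to mis-assembly or annotation noise.

The packaged demonstration study uses 10 genes of 1.1–1.5 kb with contig
lengths 0.65–1.8 kb (clipped to the transcript), so contig sets effectively
tile each CDS as they do when assembled transcript contigs are compared
against a reference CDS panel; the variant-recovery property checks use
3-gene configurations with full-length contigs so that every planted column
has calling depth. Null-calibration checks run on deliberately small sequence
sets (6 × 40 bp, 19 shuffles, 1,000 replicates) — the add-one p-value is
exactly 0.05-calibrated at that design and the scale keeps the whole property
suite within a couple of minutes. The motif-recovery check plants a TATA-like
hexamer against a GC-biased (55 %) background: at 2 bits per column the motif
is above the detection limit that a uniform background would impose on w = 6.

## The packaged P450 variant catalogue

`regelscan.p450_catalog` transcribes the published variant records of four
P450 genes from a spinosad-resistant housefly strain (reference codons,
spliced-CDS locations, substitutions, insertions, reported amino-acid
changes, per-gene sequence depths). Each gene's CDS "backbone" is a clearly
synthetic scaffold (GCT filler codons carrying the published codons at the
variant positions) — sufficient for codon-level annotation, which never looks
outside the affected codon. Two published quirks are preserved explicitly:
one record's printed location is its codon start rather than the changed base
(the forced codon offset is stored and flagged), and the cyp6d1 same-codon
pairs require joint annotation (reading one of them singly yields a stop
codon, contradicting the published change — the flag records this). Counting
conventions differ between published tallies ("12 SNPs" counts substitutions
only; the per-gene count of 8 for cyp6d1 includes its insertion), so both
conventions are exposed as options rather than one being silently chosen.

## Pipeline

`regelscan run` executes simulate → stats → callsnps → effects → cpg →
promoters → motifs → enrich from one YAML config. A single master seed spawns
one child seed per stage, all recorded in `report.json` alongside per-stage
outputs, counts, durations and warnings; identical config + seed give
byte-identical artifacts. A failed stage aborts with non-zero status and a
partial report on disk. The demonstration configuration completes in about
half a minute on one CPU, permutation tests included.
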