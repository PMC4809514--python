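"""Semi-global (overlap) pairwise alignment of strain contigs against a reference.

End gaps on both sequences are free, so a contig that is a substring of the
reference aligns without penalty for the uncovered reference flanks. Scoring is
linear-gap with configurable match/mismatch/gap. Traceback tie-breaking is
deterministic: diagonal moves are preferred over a gap in the contig, which is
preferred over a gap in the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_CODE = {b: i for i, b in enumerate("ACGTN")}


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[b] for b in seq), dtype=np.int8, count=len(seq))


@dataclass
class PairwiseAlignment:
    """An overlap alignment of one contig against one reference sequence.

    ``aligned_ref``/``aligned_contig`` cover only the aligned core (free end
    gaps stripped); ``ref_start`` is the 0-based reference offset of the first
    aligned column.
    """

    contig_id: str
    ref_id: str
    aligned_ref: str
    aligned_contig: str
    ref_start: int
    score: float

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(c != "-" for c in self.aligned_ref)

    def ungapped(self) -> tuple[str, str]:
        return (
            self.aligned_ref.replace("-", ""),
            self.aligned_contig.replace("-", ""),
        )


def align_contig(
    contig: str,
    reference: str,
    contig_id: str = "contig",
    ref_id: str = "ref",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> PairwiseAlignment:
    """Optimal overlap alignment by dynamic programming.

    The score matrix is filled row-wise with numpy; the in-row gap recursion
    ``H[i,j] = max(tmp[j], H[i,j-1] + gap)`` is resolved with a running-maximum
    transform, so no Python-level inner loop is needed.
    """
    if not contig or not reference:
        raise ValueError("align_contig requires non-empty sequences")
    x = encode(reference)  # rows
    y = encode(contig)  # columns
    n, m = len(x), len(y)
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    j_idx = np.arange(m + 1, dtype=np.float64)
    y_valid = y < 4  # N never matches
    for i in range(1, n + 1):
        prev = H[i - 1]
        s = np.where((y == x[i - 1]) & y_valid & (x[i - 1] < 4), match, mismatch)
        tmp = np.maximum(prev[:-1] + s, prev[1:] + gap)
        # H[i,j] = max over k<=j of (tmp[k] + (j-k)*gap), with tmp[0] := 0 (free left edge)
        a = np.concatenate(([0.0], tmp - j_idx[1:] * gap))
        H[i] = np.maximum.accumulate(a) + j_idx * gap
    # free trailing end gaps: best cell in the last column, then the last row
    col = H[:, m]
    row = H[n, :]
    best_col_i = int(np.argmax(col))
    best_row_j = int(np.argmax(row))
    if col[best_col_i] >= row[best_row_j]:
        i, j = best_col_i, m
    else:
        i, j = n, best_row_j
    score = float(H[i, j])

    ref_parts: list[str] = []
    ctg_parts: list[str] = []
    ref_chars, ctg_chars = reference, contig
    last = "diag"
    while i > 0 and j > 0:
        here = H[i, j]
        s = match if (x[i - 1] == y[j - 1] and x[i - 1] < 4 and y[j - 1] < 4) else mismatch
        can_diag = here == H[i - 1, j - 1] + s
        can_del = here == H[i - 1, j] + gap  # gap in contig
        can_ins = here == H[i, j - 1] + gap  # gap in reference (insertion)
        # tie preference: diag > gap-in-contig > gap-in-ref, except an open gap
        # run is extended on ties so indels stay contiguous
        if last == "ins" and can_ins:
            move = "ins"
        elif last == "del" and can_del:
            move = "del"
        elif can_diag:
            move = "diag"
        elif can_del:
            move = "del"
        elif can_ins:
            move = "ins"
        else:  # free edge reached (H[i,j] == 0 on a border path)
            break
        if move == "diag":
            ref_parts.append(ref_chars[i - 1])
            ctg_parts.append(ctg_chars[j - 1])
            i -= 1
            j -= 1
        elif move == "del":
            ref_parts.append(ref_chars[i - 1])
            ctg_parts.append("-")
            i -= 1
        else:
            ref_parts.append("-")
            ctg_parts.append(ctg_chars[j - 1])
            j -= 1
        last = move
    return PairwiseAlignment(
        contig_id=contig_id,
        ref_id=ref_id,
        aligned_ref="".join(reversed(ref_parts)),
        aligned_contig="".join(reversed(ctg_parts)),
        ref_start=i,
        score=score,
    )


def assign_contigs(
    contigs: dict[str, str], references: dict[str, str], k: int = 15
) -> dict[str, str | None]:
    """Pick the reference each contig most plausibly derives from by shared k-mers.

    Returns contig_id -> ref_id (or None when no k-mer is shared). This is a
    prefilter so each contig needs only one full alignment.
    """
    index: dict[str, dict[str, int]] = {}
    for rid, seq in references.items():
        for p in range(len(seq) - k + 1):
            index.setdefault(seq[p : p + k], {}).setdefault(rid, 0)
    assignment: dict[str, str | None] = {}
    for cid, seq in contigs.items():
        votes: dict[str, int] = {}
        for p in range(0, max(1, len(seq) - k + 1), 4):
            hit = index.get(seq[p : p + k])
            if hit:
                for rid in hit:
                    votes[rid] = votes.get(rid, 0) + 1
        if votes:
            assignment[cid] = max(sorted(votes), key=lambda r: votes[r])
        else:
            assignment[cid] = None
    return assignment
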