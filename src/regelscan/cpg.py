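"""CpG island detection and gene-relative localisation.

Islands are found with the classic sliding-window criteria (default: 200 bp
windows, GC fraction >= 0.5 and observed/expected CpG >= 0.6, minimum merged
length 200 bp); overlapping qualifying windows are merged and the merged
interval trimmed inward until it satisfies all criteria itself. Location labels
("5'-end" / "3'-end" / "internal" / "intergenic") and feature coverage lists
("promoter part", "exon k", "intron k") mirror how such islands are reported
alongside gene architecture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GeneModel


@dataclass
class CpGIsland:
    seq_id: str
    start: int  # 0-based half-open
    end: int
    gc_fraction: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start


def measure_interval(sequence: str, start: int, end: int) -> tuple[float, float]:
    """(GC fraction, observed/expected CpG) over [start, end).

    Expected CpG = count(C) * count(G) / interval length; obs/expected is 0
    when either base is absent.
    """
    seg = sequence[start:end]
    length = len(seg)
    c = seg.count("C")
    g = seg.count("G")
    obs = seg.count("CG")
    gc = (c + g) / length if length else 0.0
    exp = c * g / length if length else 0.0
    return gc, (obs / exp if exp > 0 else 0.0)


def _satisfies(sequence: str, start: int, end: int, min_length: int,
               min_gc: float, min_oe: float) -> bool:
    if end - start < min_length:
        return False
    gc, oe = measure_interval(sequence, start, end)
    return gc >= min_gc and oe >= min_oe


def scan_islands(
    sequence: str,
    seq_id: str = "seq",
    min_length: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    window: int = 200,
    step: int = 1,
) -> list[CpGIsland]:
    """Exhaustive sliding-window scan for CpG islands.

    Every window of ``window`` bp (stride ``step``) satisfying the GC and
    obs/expected thresholds — and containing no N — qualifies; overlapping or
    adjacent qualifying windows are merged, and each merged interval is trimmed
    inward (dropping the terminal base that is not C/G, else the right one)
    until the whole interval itself satisfies all three criteria.
    """
    for name, t in (("min_gc", min_gc), ("min_oe", min_oe)):
        if not 0.0 < t <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1]")
    if len(sequence) < window:
        raise ValueError("sequence shorter than the scan window")

    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = arr == ord("N")
    is_cpg = np.zeros(len(arr), dtype=bool)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]

    cum = lambda x: np.concatenate(([0], np.cumsum(x)))
    cC, cG, cN, cCpG = cum(is_c), cum(is_g), cum(is_n), cum(is_cpg)

    starts = np.arange(0, len(sequence) - window + 1, step)
    ends = starts + window
    nC = cC[ends] - cC[starts]
    nG = cG[ends] - cG[starts]
    nN = cN[ends] - cN[starts]
    nCpG = cCpG[ends - 1] - cCpG[starts]  # CpG must lie wholly inside the window
    gc_ok = (nC + nG) / window >= min_gc
    exp = nC * nG / window
    oe_ok = (exp > 0) & (nCpG >= min_oe * exp)
    ok = gc_ok & oe_ok & (nN == 0)

    # merge overlapping/adjacent qualifying windows
    intervals: list[list[int]] = []
    for s, e in zip(starts[ok], ends[ok]):
        if intervals and s <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], int(e))
        else:
            intervals.append([int(s), int(e)])

    islands: list[CpGIsland] = []
    for s, e in intervals:
        s, e = _trim(sequence, s, e, min_length, min_gc, min_oe)
        if s is None:
            continue
        gc, oe = measure_interval(sequence, s, e)
        islands.append(CpGIsland(seq_id=seq_id, start=s, end=e,
                                 gc_fraction=gc, obs_exp_cpg=oe))
    return islands


def _trim(sequence, start, end, min_length, min_gc, min_oe):
    """Shrink [start, end) until it satisfies the criteria; None if impossible."""
    while end - start >= min_length:
        if _satisfies(sequence, start, end, min_length, min_gc, min_oe):
            return start, end
        left_gc = sequence[start] in "CG"
        right_gc = sequence[end - 1] in "CG"
        if not left_gc and right_gc:
            start += 1
        elif left_gc and not right_gc:
            end -= 1
        else:
            # tie: shrink symmetrically so the rule commutes with
            # reverse-complementing the sequence
            start += 1
            end -= 1
    return None, None


# ---------------------------------------------------------------------------
# Localisation relative to gene architecture
# ---------------------------------------------------------------------------


@dataclass
class IslandLocation:
    island: CpGIsland
    gene_id: str | None
    location_label: str  # 5'-end | 3'-end | internal | intergenic
    coverage: list[str]


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def locate_islands(
    islands: list[CpGIsland],
    genes: list[GeneModel],
    promoter_length: int | None = None,
) -> list[IslandLocation]:
    """Label each island relative to the gene it overlaps most.

    "5'-end" when the island touches the promoter window or the 5'-most
    quarter of the gene span, "3'-end" when it touches the 3'-most quarter,
    "internal" otherwise inside the gene, "intergenic" when it overlaps no
    gene or promoter. Coverage lists every promoter/exon/intron feature the
    island overlaps, numbered in transcription order.
    """
    out: list[IslandLocation] = []
    for isl in islands:
        best: tuple[int, str, GeneModel] | None = None
        for gene in genes:
            if gene.seq_id != isl.seq_id:
                continue
            plen = promoter_length if promoter_length is not None else gene.promoter_length
            gs, ge = gene.span
            ps, pe = (gs - plen, gs) if gene.strand == "+" else (ge, ge + plen)
            ov = _overlap(isl.start, isl.end, min(gs, ps), max(ge, pe))
            if ov > 0 and (best is None or ov > best[0] or (ov == best[0] and gene.gene_id < best[1])):
                best = (ov, gene.gene_id, gene)
        if best is None:
            out.append(IslandLocation(isl, None, "intergenic", []))
            continue
        gene = best[2]
        plen = promoter_length if promoter_length is not None else gene.promoter_length
        gs, ge = gene.span
        quarter = max(1, (ge - gs) // 4)
        if gene.strand == "+":
            prom = (gs - plen, gs)
            five = (gs, gs + quarter)
            three = (ge - quarter, ge)
        else:
            prom = (ge, ge + plen)
            five = (ge - quarter, ge)
            three = (gs, gs + quarter)

        coverage: list[str] = []
        if _overlap(isl.start, isl.end, *prom) > 0:
            coverage.append("promoter part")
        for k, (a, b) in enumerate(gene.exons_tx_order(), start=1):
            if _overlap(isl.start, isl.end, a, b) > 0:
                coverage.append(f"exon {k}")
        for k, (a, b) in enumerate(gene.introns(), start=1):
            if _overlap(isl.start, isl.end, a, b) > 0:
                coverage.append(f"intron {k}")

        in_gene = _overlap(isl.start, isl.end, gs, ge) > 0
        if _overlap(isl.start, isl.end, *prom) > 0 or _overlap(isl.start, isl.end, *five) > 0:
            label = "5'-end"
        elif _overlap(isl.start, isl.end, *three) > 0:
            label = "3'-end"
        elif in_gene:
            label = "internal"
        else:
            label = "intergenic"
        out.append(IslandLocation(isl, gene.gene_id, label, coverage))
    return out
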