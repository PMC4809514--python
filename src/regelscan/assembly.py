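"""Contig summary statistics: counts, length moments, N50 and a length histogram."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import SequenceRecord


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bases: int
    mean_length: float
    min_length: int
    max_length: int
    n50: int
    bin_edges: list[int]
    histogram: list[int]

    def to_rows(self) -> list[tuple[str, float]]:
        return [
            ("n_contigs", self.n_contigs),
            ("total_bases", self.total_bases),
            ("mean_length", self.mean_length),
            ("min_length", self.min_length),
            ("max_length", self.max_length),
            ("n50", self.n50),
        ]


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L hold at least half of all bases."""
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of an empty length set")
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


def contig_stats(lengths: Sequence[int], bin_width: int = 100) -> AssemblyStats:
    """Summary statistics over contig lengths with a right-open histogram.

    Bins are ``[0, bin_width), [bin_width, 2*bin_width), ...`` covering the
    longest contig.
    """
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("contig_stats requires at least one contig")
    if (arr <= 0).any():
        raise ValueError("contig lengths must be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(arr.max() // bin_width) + 1
    edges = [i * bin_width for i in range(n_bins + 1)]
    hist, _ = np.histogram(arr, bins=edges)
    return AssemblyStats(
        n_contigs=int(arr.size),
        total_bases=int(arr.sum()),
        mean_length=float(arr.mean()),
        min_length=int(arr.min()),
        max_length=int(arr.max()),
        n50=n50(arr),
        bin_edges=edges,
        histogram=[int(c) for c in hist],
    )


def stats_from_records(records: Sequence[SequenceRecord], bin_width: int = 100) -> AssemblyStats:
    return contig_stats([len(r) for r in records], bin_width=bin_width)


def plot_length_histogram(stats: AssemblyStats, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = [(a + b) / 2 for a, b in zip(stats.bin_edges, stats.bin_edges[1:])]
    width = stats.bin_edges[1] - stats.bin_edges[0]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(centers, stats.histogram, width=width * 0.9)
    ax.set_xlabel("contig length (bp)")
    ax.set_ylabel("contigs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
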