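"""Assembly summary statistics for a de novo transcript (unigene) set.

Implements the classical report columns for a short-read assembly: N50 by
the cumulative-sum definition, mean length, a length-class histogram with
percentages, and the RPKM normalisation formula. Operates on plain length
multisets so it can summarise contigs, scaffolds or unigenes alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._util import round_half_up

__all__ = [
    "AssemblyStats",
    "n50",
    "mean_length",
    "length_class_counts",
    "rpkm",
    "assembly_stats",
    "report_mean",
    "report_percent",
]


def n50(lengths: Iterable[int]) -> int:
    """N50: order lengths longest to shortest and accumulate until the sum
    strictly exceeds half the total; the length adding that increment is N50.

    Ties at exactly half the total continue to the next (shorter) length.
    """
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValueError("n50 requires at least one length")
    if any(l < 1 for l in ls):
        raise ValueError("all lengths must be >= 1")
    half = sum(ls) / 2
    acc = 0
    for l in ls:
        acc += l
        if acc > half:
            return l
    # unreachable: the full sum always exceeds half
    raise AssertionError("cumulative scan failed to exceed half the total")


def mean_length(lengths: Iterable[int]) -> float:
    """Arithmetic mean length in nt (unrounded; reports round half-up)."""
    ls = list(lengths)
    if not ls:
        raise ValueError("mean_length requires at least one length")
    return sum(ls) / len(ls)


def report_mean(total_length: int, n_sequences: int) -> int:
    """Mean length as printed in assembly reports: half-up to integer nt."""
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    return int(round_half_up(total_length / n_sequences))


def report_percent(count: int, n: int) -> float:
    """Class percentage as printed: count/n x 100, half-up to 2 dp."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return round_half_up(count / n * 100, 2)


def length_class_counts(
    lengths: Iterable[int], boundaries: Sequence[int]
) -> pd.DataFrame:
    """Histogram of lengths over half-open classes [b_i, b_{i+1}) plus a
    final open-ended class [b_last, inf).

    Returns a DataFrame with columns ``label``, ``count``, ``percent``
    (percent half-up to 2 dp). A boundary value falls in the class it opens,
    so with boundaries (100, 200, ...) a 200 nt sequence is in "200~300".
    """
    bs = list(boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
        raise ValueError("boundaries must be strictly increasing")
    ls = list(lengths)
    n = len(ls)
    edges = bs + [float("inf")]
    labels = [
        f"{lo}~{hi}" if hi != float("inf") else f">={lo}"
        for lo, hi in zip(edges, edges[1:])
    ]
    counts = [0] * len(labels)
    for l in ls:
        for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
            if lo <= l < hi:
                counts[i] += 1
                break
    percents = [report_percent(c, n) if n else 0.0 for c in counts]
    return pd.DataFrame({"label": labels, "count": counts, "percent": percents})


def rpkm(mapped_count: float, total_mapped: int, feature_length: int) -> float:
    """Reads per kilobase of feature per million mapped reads:
    1e9 * C / (N * L)."""
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    if feature_length < 1:
        raise ValueError("feature_length must be >= 1")
    return 1e9 * mapped_count / (total_mapped * feature_length)


@dataclass
class AssemblyStats:
    """Summary of a sequence set, mirroring an assembly report row."""

    n_sequences: int
    total_length: int
    mean_length: int  # report-rounded, nt
    n50: int
    class_counts: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """One-row summary frame (class columns then N50/Mean/Total)."""
        row = {lbl: c for lbl, c in
               zip(self.class_counts["label"], self.class_counts["count"])}
        row.update(
            N50=self.n50, Mean=self.mean_length,
            Total=self.n_sequences, TotalLength=self.total_length,
        )
        return pd.DataFrame([row])


def assembly_stats(
    lengths: Iterable[int], boundaries: Sequence[int] = (100, 200, 300, 400, 500)
) -> AssemblyStats:
    ls = list(lengths)
    return AssemblyStats(
        n_sequences=len(ls),
        total_length=sum(ls),
        mean_length=report_mean(sum(ls), len(ls)),
        n50=n50(ls),
        class_counts=length_class_counts(ls, boundaries),
    )
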