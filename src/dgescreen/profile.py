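"""Stage expression profiling and RNAi-target screening.

Maps clean tags from each developmental-stage library onto the virtual tag
index, aggregates counts per unigene, summarises the copy-number
distribution, partitions tags/unigenes by stage membership (Venn), calls
stage-specific tags and ranks candidate RNAi targets by copy number.

Ambiguous tags (a 17-mer shared by several unigenes) never credit a
unigene and are never eligible as targets; they are tallied separately so
the per-stage conservation identity

    mapped-unique + ambiguous + unmapped = clean_total

holds exactly after every mapping run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tag_filter import CleanTagTable
from .tag_reference import VirtualTagIndex

__all__ = [
    "DEFAULT_COPY_BINS",
    "StageExpressionProfile",
    "TargetCall",
    "CopyNumberDistribution",
    "map_tags",
    "copy_number_distribution",
    "venn_partition",
    "stage_specific_calls",
    "rank_targets",
    "tags_per_million",
]

# Copy-number histogram bin lower edges; each bin is [lo, next_lo), the
# last is open-ended. Clean tags start at copy number 2.
DEFAULT_COPY_BINS = (2, 3, 10, 50, 100, 200, 300, 400, 500, 1000, 2000, 5000, 10000)


@dataclass
class StageExpressionProfile:
    """Tag- and unigene-level counts across stage libraries."""

    stages: list[str]
    tag_counts: pd.DataFrame       # uniquely-mapping tag17 x stage
    unigene_counts: pd.DataFrame   # unigene x stage (sum of its unique tags)
    tag_to_unigene: dict[str, str]
    ambiguous_counts: pd.DataFrame  # ambiguous tag17 x stage, sidecar
    unmapped: dict[str, int]        # stage -> total unmapped tag copies
    ambiguous_totals: dict[str, int]
    clean_totals: dict[str, int]

    def check_conservation(self) -> None:
        for s in self.stages:
            mapped = int(self.tag_counts[s].sum()) if len(self.tag_counts) else 0
            total = mapped + self.ambiguous_totals[s] + self.unmapped[s]
            if total != self.clean_totals[s]:
                raise AssertionError(
                    f"conservation violated in {s}: {total} != {self.clean_totals[s]}"
                )


@dataclass
class TargetCall:
    """A tag judged stage-specific, with the evidence behind the call."""

    unigene_id: str
    tag17: str
    counts: dict[str, int]
    called_stage: str
    mode: str
    fold_dominance: float  # called-stage count / max other stage (inf if 0)
    rank: int | None = None


@dataclass
class CopyNumberDistribution:
    """Unique-tag counts per copy-number bin per stage (report shape)."""

    table: pd.DataFrame  # index bin labels, columns stages
    boundaries: tuple[int, ...]

    @classmethod
    def from_counts(
        cls, table: pd.DataFrame, boundaries: Sequence[int] = DEFAULT_COPY_BINS
    ) -> "CopyNumberDistribution":
        return cls(table=table.copy(), boundaries=tuple(boundaries))

    @property
    def column_totals(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def row_totals(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.table.to_numpy().sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["Total"] = self.row_totals
        out.loc["Total"] = out.sum(axis=0)
        return out


def _as_tables(clean: Mapping[str, CleanTagTable] | Sequence[CleanTagTable]) -> dict[str, CleanTagTable]:
    if isinstance(clean, Mapping):
        for label, t in clean.items():
            if t.library != label:
                raise ValueError(
                    f"stage label {label!r} does not match table library {t.library!r}"
                )
        return dict(clean)
    return {t.library: t for t in clean}


def map_tags(
    clean: Mapping[str, CleanTagTable] | Sequence[CleanTagTable],
    index: VirtualTagIndex,
) -> StageExpressionProfile:
    """Exact tag17 lookup of each stage's clean tags against the index."""
    if len(index) == 0:
        raise ValueError("virtual tag index is empty")
    tables = _as_tables(clean)
    stages = list(tables)
    tag2uni = index.unique_tag_to_unigene

    uniq_rows: dict[str, dict[str, int]] = {}
    ambi_rows: dict[str, dict[str, int]] = {}
    unmapped = {s: 0 for s in stages}
    ambiguous_totals = {s: 0 for s in stages}

    for s, table in tables.items():
        for tag17, count in table.counts.items():
            if tag17 in tag2uni:
                uniq_rows.setdefault(tag17, {})[s] = count
            elif tag17 in index.tags:
                ambi_rows.setdefault(tag17, {})[s] = count
                ambiguous_totals[s] += count
            else:
                unmapped[s] += count

    def _frame(rows: dict[str, dict[str, int]]) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(rows, orient="index", dtype=float).fillna(0)
        for s in stages:
            if s not in df.columns:
                df[s] = 0.0
        return df[stages].astype(int).sort_index()

    tag_counts = _frame(uniq_rows)
    ambiguous_counts = _frame(ambi_rows)

    if len(tag_counts):
        uni_ids = pd.Series({t: tag2uni[t] for t in tag_counts.index})
        unigene_counts = tag_counts.groupby(uni_ids).sum().sort_index()
    else:
        unigene_counts = pd.DataFrame(columns=stages, dtype=int)

    profile = StageExpressionProfile(
        stages=stages,
        tag_counts=tag_counts,
        unigene_counts=unigene_counts,
        tag_to_unigene={t: tag2uni[t] for t in tag_counts.index},
        ambiguous_counts=ambiguous_counts,
        unmapped=unmapped,
        ambiguous_totals=ambiguous_totals,
        clean_totals={s: tables[s].total for s in stages},
    )
    profile.check_conservation()
    return profile


def copy_number_distribution(
    clean: Mapping[str, CleanTagTable] | Sequence[CleanTagTable],
    boundaries: Sequence[int] = DEFAULT_COPY_BINS,
) -> CopyNumberDistribution:
    """Bin each stage's clean tags by copy number (unique-tag units)."""
    bs = list(boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
        raise ValueError("bin boundaries must be strictly increasing")
    if bs[0] != 2:
        raise ValueError("bins must cover [2, inf): first boundary must be 2")
    tables = _as_tables(clean)
    edges = bs + [math.inf]
    labels = [
        (f"{lo}" if hi == lo + 1 else (f"{lo}~{int(hi) - 1}" if hi != math.inf else f">={lo}"))
        for lo, hi in zip(edges, edges[1:])
    ]
    data = {}
    for s, table in tables.items():
        counts = np.asarray(list(table.counts.values()), dtype=int)
        col = []
        for lo, hi in zip(edges, edges[1:]):
            col.append(int(((counts >= lo) & (counts < hi)).sum()))
        data[s] = col
    df = pd.DataFrame(data, index=labels)
    return CopyNumberDistribution(table=df, boundaries=tuple(bs))


def venn_partition(
    matrix: pd.DataFrame | StageExpressionProfile, level: str = "tag"
) -> dict[frozenset, int]:
    """Partition detected items by their exact stage-membership pattern.

    An item is a member of a stage when its count there is > 0. Returns
    counts for every nonempty stage subset (2^k - 1 categories); the
    categories are disjoint and their counts sum to the number of
    detected items.
    """
    if isinstance(matrix, StageExpressionProfile):
        matrix = matrix.tag_counts if level == "tag" else matrix.unigene_counts
    stages = list(matrix.columns)
    out: dict[frozenset, int] = {
        frozenset(c): 0
        for r in range(1, len(stages) + 1)
        for c in combinations(stages, r)
    }
    present = matrix.gt(0)
    for _, row in present.iterrows():
        members = frozenset(s for s in stages if row[s])
        if members:
            out[members] += 1
    return out


def stage_specific_calls(
    profile: StageExpressionProfile,
    mode: str = "dominance",
    min_count: int = 100,
    fold_threshold: float = 3.0,
) -> list[TargetCall]:
    """Call stage-specific tags among uniquely-mapping, unambiguous tags.

    strict: nonzero in exactly one stage, count >= min_count there.
    dominance: called stage is the argmax; its count >= min_count and
    exceeds the best other stage by >= fold_threshold (infinity when all
    other stages are zero).
    """
    if mode not in ("strict", "dominance"):
        raise ValueError(f"unknown mode: {mode!r}")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if mode == "dominance" and fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1 in dominance mode")

    calls: list[TargetCall] = []
    stages = profile.stages
    for tag17, row in profile.tag_counts.iterrows():
        counts = {s: int(row[s]) for s in stages}
        top_stage = max(stages, key=lambda s: (counts[s], s))
        top = counts[top_stage]
        others = [counts[s] for s in stages if s != top_stage]
        best_other = max(others) if others else 0
        fold = math.inf if best_other == 0 else top / best_other
        if top < min_count:
            continue
        if mode == "strict" and best_other != 0:
            continue
        if mode == "dominance" and fold < fold_threshold:
            continue
        calls.append(
            TargetCall(
                unigene_id=profile.tag_to_unigene[tag17],
                tag17=tag17,
                counts=counts,
                called_stage=top_stage,
                mode=mode,
                fold_dominance=fold,
            )
        )
    return calls


def rank_targets(
    calls: Sequence[TargetCall], stage: str, top_k: int | None = None
) -> list[TargetCall]:
    """Rank one stage's calls by called-stage copy number, descending;
    ties broken lexicographically by tag17."""
    stage_calls = [c for c in calls if c.called_stage == stage]
    if not stage_calls:
        raise ValueError(f"no calls for stage {stage!r}")
    ranked = sorted(stage_calls, key=lambda c: (-c.counts[stage], c.tag17))
    if top_k is not None:
        ranked = ranked[:top_k]
    for i, c in enumerate(ranked, start=1):
        c.rank = i
    return ranked


def tags_per_million(table: CleanTagTable) -> pd.Series:
    """Normalise a clean-tag table to tags-per-million library depth."""
    total = table.total
    if total == 0:
        raise ValueError("empty clean-tag table")
    return pd.Series(
        {t: c * 1e6 / total for t, c in table.counts.items()}, name=table.library
    )
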