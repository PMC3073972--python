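"""Clean-tag filtering with full accounting.

Raw DGE-tag observations pass three filters, applied in a fixed order so
every removed tag is attributed to exactly one category and the accounting
is additive in both total-tag and unique-tag units:

1. low quality — the observation contains at least one N;
2. adaptor — the observation matches a declared adaptor sequence;
3. copy number < 2 — after aggregating identical tags, singletons are
   dropped (a tag seen once in a multi-million-tag library is far more
   likely a sequencing artefact than a real transcript).

What survives is the library's clean-tag table (tag17 -> count, every
count >= 2, no Ns).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .tag_reference import ANCHOR, TAG_LEN

__all__ = [
    "FilterAccounting",
    "CleanTagTable",
    "filter_tags",
    "merge_accounting",
]


@dataclass
class FilterAccounting:
    """Per-library filter tallies in total-tag and unique-tag units.

    Invariants (checked by :meth:`validate`):
    raw = lowq + adaptor + singleton + clean in both units, and
    singleton_total == singleton_unique (copy number 1 means one copy).
    """

    library: str
    raw_total: int
    raw_unique: int
    lowq_total: int
    lowq_unique: int
    adaptor_total: int
    adaptor_unique: int
    singleton_total: int
    singleton_unique: int
    clean_total: int
    clean_unique: int

    @classmethod
    def from_removals(
        cls,
        library: str,
        raw_total: int,
        raw_unique: int,
        lowq_total: int,
        lowq_unique: int,
        adaptor_total: int,
        adaptor_unique: int,
        singleton_total: int,
        singleton_unique: int,
    ) -> "FilterAccounting":
        """Build an accounting from raw totals and the removed categories;
        clean counts follow from the additive identities."""
        acc = cls(
            library=library,
            raw_total=raw_total,
            raw_unique=raw_unique,
            lowq_total=lowq_total,
            lowq_unique=lowq_unique,
            adaptor_total=adaptor_total,
            adaptor_unique=adaptor_unique,
            singleton_total=singleton_total,
            singleton_unique=singleton_unique,
            clean_total=raw_total - lowq_total - adaptor_total - singleton_total,
            clean_unique=raw_unique - lowq_unique - adaptor_unique - singleton_unique,
        )
        acc.validate()
        return acc

    def validate(self) -> None:
        if self.raw_total != (
            self.lowq_total + self.adaptor_total + self.singleton_total + self.clean_total
        ):
            raise ValueError(f"total-unit accounting identity violated for {self.library}")
        if self.raw_unique != (
            self.lowq_unique + self.adaptor_unique + self.singleton_unique + self.clean_unique
        ):
            raise ValueError(f"unique-unit accounting identity violated for {self.library}")
        if self.singleton_total != self.singleton_unique:
            raise ValueError(f"singleton counts must match in both units for {self.library}")


@dataclass
class CleanTagTable:
    """Clean tags of one library: tag17 -> copy number (all >= 2)."""

    library: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"tag17": list(self.counts), "count": list(self.counts.values())}
        )
        return df.sort_values(["count", "tag17"], ascending=[False, True]).reset_index(
            drop=True
        )


def _normalize(obs: str, i: int, dialect: str) -> str:
    """Validate one observation and return its tag17 (may contain N)."""
    obs = obs.upper()
    if dialect == "21nt":
        if len(obs) != 4 + TAG_LEN:
            raise ValueError(f"record {i}: expected 21 nt tag, got {len(obs)} nt")
        if "N" not in obs and not obs.startswith(ANCHOR):
            raise ValueError(f"record {i}: 21 nt tag does not start with {ANCHOR}")
        return obs[4:]
    elif dialect == "17nt":
        if len(obs) != TAG_LEN:
            raise ValueError(f"record {i}: expected 17 nt tag, got {len(obs)} nt")
        return obs
    raise ValueError(f"unknown tag dialect: {dialect!r}")


def filter_tags(
    observations: Iterable[str],
    adaptor_sequences: Sequence[str] = (),
    library: str = "library",
    dialect: str = "21nt",
) -> tuple[CleanTagTable, FilterAccounting]:
    """Run the three-stage clean-tag filter over one library.

    ``dialect`` declares the observation format: "21nt" (CATG-prefixed, the
    sequencer's output; the prefix is validated on N-free tags) or "17nt"
    (bare variable region). Tags are keyed internally by their 17-mer.

    Adaptor matching is exact or adaptor-prefix (the observation starts
    with the adaptor sequence), applied to the full observation.
    """
    adaptors = tuple(a.upper() for a in adaptor_sequences)

    raw_total = 0
    raw_seen: set[str] = set()
    lowq_total = 0
    lowq_seen: set[str] = set()
    adaptor_total = 0
    adaptor_seen: set[str] = set()
    survivors: Counter[str] = Counter()

    for i, obs in enumerate(observations):
        obs_u = obs.upper()
        tag17 = _normalize(obs_u, i, dialect)
        raw_total += 1
        raw_seen.add(obs_u)
        if "N" in obs_u:
            lowq_total += 1
            lowq_seen.add(obs_u)
            continue
        if adaptors and any(obs_u == a or obs_u.startswith(a) for a in adaptors):
            adaptor_total += 1
            adaptor_seen.add(obs_u)
            continue
        survivors[tag17] += 1

    clean = {t: c for t, c in survivors.items() if c >= 2}
    singleton = sum(1 for c in survivors.values() if c < 2)

    accounting = FilterAccounting(
        library=library,
        raw_total=raw_total,
        raw_unique=len(raw_seen),
        lowq_total=lowq_total,
        lowq_unique=len(lowq_seen),
        adaptor_total=adaptor_total,
        adaptor_unique=len(adaptor_seen),
        singleton_total=singleton,
        singleton_unique=singleton,
        clean_total=sum(clean.values()),
        clean_unique=len(clean),
    )
    accounting.validate()
    return CleanTagTable(library=library, counts=clean), accounting


_ROWS = [
    ("Raw Data", "raw"),
    ("Low quality", "lowq"),
    ("Adaptors", "adaptor"),
    ("CopyNum<2", "singleton"),
    ("Clean Tag", "clean"),
]


def merge_accounting(accountings: Sequence[FilterAccounting]) -> pd.DataFrame:
    """Combine per-library accountings into one report table: one row per
    filter stage, Total/Unique sub-columns per library."""
    if not accountings:
        raise ValueError("at least one library accounting is required")
    labels = [a.library for a in accountings]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate library labels")
    data = {}
    for a in accountings:
        a.validate()
        data[(a.library, "Total Tags")] = [
            getattr(a, f"{key}_total") for _, key in _ROWS
        ]
        data[(a.library, "Unique Tags")] = [
            getattr(a, f"{key}_unique") for _, key in _ROWS
        ]
    df = pd.DataFrame(data, index=[name for name, _ in _ROWS])
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df
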