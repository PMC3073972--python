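"""Virtual DGE-tag reference built from a transcript set.

NlaIII-anchored digital gene expression tags consist of the CATG
recognition site plus the 17 nt immediately downstream, read on the sense
strand. This module locates every eligible CATG site in each unigene,
extracts the 17 nt tag, marks the canonical (3'-most) site per unigene —
the site the oligo-dT-anchored library chemistry is expected to produce —
and indexes tags by their 17-mer with a uniqueness class for mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

ANCHOR = "CATG"
TAG_LEN = 17

__all__ = [
    "ANCHOR",
    "TAG_LEN",
    "VirtualTag",
    "VirtualTagIndex",
    "extract_virtual_tags",
    "canonical_tag",
    "build_tag_index",
]


@dataclass(frozen=True)
class VirtualTag:
    """One CATG site with its downstream 17-mer.

    ``site_position`` is the 0-based offset of the C of CATG on the sense
    strand; ``rank_from_3prime`` is 1 for the site closest to the 3' end.
    """

    tag17: str
    unigene_id: str
    site_position: int
    rank_from_3prime: int
    is_canonical: bool

    @property
    def full21(self) -> str:
        return ANCHOR + self.tag17


def extract_virtual_tags(unigene_id: str, sequence: str) -> list[VirtualTag]:
    """All virtual tags of one transcript, 5'->3' site order.

    A site is eligible when >= 17 nt follow the CATG on the sense strand
    and the 17-mer contains no N. Case-insensitive.
    """
    seq = sequence.upper()
    positions: list[int] = []
    start = 0
    while True:
        pos = seq.find(ANCHOR, start)
        if pos == -1:
            break
        tag = seq[pos + 4 : pos + 4 + TAG_LEN]
        if len(tag) == TAG_LEN and "N" not in tag:
            positions.append(pos)
        start = pos + 1
    n = len(positions)
    return [
        VirtualTag(
            tag17=seq[p + 4 : p + 4 + TAG_LEN],
            unigene_id=unigene_id,
            site_position=p,
            rank_from_3prime=n - i,
            is_canonical=(i == n - 1),
        )
        for i, p in enumerate(positions)
    ]


def canonical_tag(unigene_id: str, sequence: str) -> VirtualTag | None:
    """The 3'-most eligible site (rank 1), or None when no site exists."""
    tags = extract_virtual_tags(unigene_id, sequence)
    return tags[-1] if tags else None


@dataclass
class VirtualTagIndex:
    """tag17 -> sites lookup over a unigene set.

    A tag is ``unique`` when exactly one unigene carries it, ``ambiguous``
    otherwise. Unigenes with no eligible site are recorded separately so
    that every input unigene is accounted for.
    """

    tags: dict[str, list[VirtualTag]] = field(default_factory=dict)
    unigenes_without_sites: list[str] = field(default_factory=list)
    mode: str = "canonical"

    def __len__(self) -> int:
        return len(self.tags)

    def uniqueness(self, tag17: str) -> str:
        hits = self.tags[tag17]
        return "unique" if len({t.unigene_id for t in hits}) == 1 else "ambiguous"

    def lookup(self, tag17: str) -> list[VirtualTag]:
        return self.tags.get(tag17, [])

    @property
    def unique_tag_to_unigene(self) -> dict[str, str]:
        """Mapping restricted to unambiguous tags."""
        out = {}
        for tag17, hits in self.tags.items():
            ids = {t.unigene_id for t in hits}
            if len(ids) == 1:
                out[tag17] = next(iter(ids))
        return out


def build_tag_index(
    unigenes: Mapping[str, str] | Iterable[tuple[str, str]],
    mode: str = "canonical",
) -> VirtualTagIndex:
    """Index virtual tags over a unigene set.

    Parameters
    ----------
    unigenes : mapping id -> sequence, or iterable of (id, sequence)
    mode : "canonical" indexes only the 3'-most tag per unigene (the tag
        the library chemistry produces); "all-sites" indexes every site
        (sensitivity analysis).
    """
    if mode not in ("canonical", "all-sites"):
        raise ValueError(f"unknown mode: {mode!r}")
    pairs = unigenes.items() if isinstance(unigenes, Mapping) else unigenes
    index = VirtualTagIndex(mode=mode)
    seen: set[str] = set()
    for uid, seq in pairs:
        if uid in seen:
            raise ValueError(f"duplicate unigene id: {uid!r}")
        seen.add(uid)
        sites = extract_virtual_tags(uid, seq)
        if not sites:
            index.unigenes_without_sites.append(uid)
            continue
        if mode == "canonical":
            sites = [sites[-1]]
        for t in sites:
            index.tags.setdefault(t.tag17, []).append(t)
    return index
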