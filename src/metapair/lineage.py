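"""Ranked taxonomic lineages with prefix semantics.

A lineage is an ordered assignment of names to the fixed rank schema
``kingdom > phylum > class > order > family > subfamily > genus > species``.
Partial assignments are allowed, but only as prefixes: once a rank is
unnamed, every deeper rank must be unnamed too.  This is the property that
lets "assigned at family level" mean exactly "named down to family and no
further".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "subfamily",
    "genus",
    "species",
)

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

# single-letter prefixes used by the `k__Animalia;p__...` serialization style
_RANK_PREFIXES = ("k", "p", "c", "o", "f", "sf", "g", "s")


@dataclass(frozen=True)
class Lineage:
    """An ordered tuple of taxon names following :data:`RANKS`.

    ``names[i]`` is the name at ``RANKS[i]``; the tuple may be shorter than
    the schema (a partial assignment) but never contains empty entries.
    """

    names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.names) > len(RANKS):
            raise ValueError(
                f"lineage has {len(self.names)} ranks; schema allows {len(RANKS)}"
            )
        for name in self.names:
            if not name:
                raise ValueError(
                    "empty taxon name inside lineage violates the prefix property"
                )

    # -- constructors -------------------------------------------------
    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Lineage":
        """Build from (rank, name) pairs; ranks must follow the schema order."""
        names = []
        last = -1
        for rank, name in pairs:
            idx = _RANK_INDEX.get(rank)
            if idx is None:
                raise ValueError(f"unknown rank {rank!r}")
            if idx != last + 1:
                raise ValueError(f"rank {rank!r} out of schema order")
            names.append(name)
            last = idx
        return cls(tuple(names))

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "Lineage":
        """Parse a shallow→deep separated string, e.g. ``Animalia;Arthropoda``.

        Trailing empty fields are dropped; an interior empty field is an
        error (it would create a gap).  ``k__``-style rank prefixes are
        stripped if present.
        """
        fields = [f.strip() for f in text.split(sep)]
        while fields and not fields[-1]:
            fields.pop()
        names = []
        for f in fields:
            if "__" in f:
                f = f.split("__", 1)[1]
            names.append(f)
        if any(not n for n in names):
            raise ValueError(f"interior empty rank in lineage {text!r}")
        return cls(tuple(names))

    # -- accessors ----------------------------------------------------
    def name_at(self, rank: str) -> Optional[str]:
        idx = _RANK_INDEX[rank]
        return self.names[idx] if idx < len(self.names) else None

    @property
    def depth(self) -> int:
        """Number of named ranks (0 = fully unassigned)."""
        return len(self.names)

    @property
    def deepest_rank(self) -> Optional[str]:
        return RANKS[len(self.names) - 1] if self.names else None

    def truncate(self, depth: int) -> "Lineage":
        return Lineage(self.names[:depth])

    def is_prefix_of(self, other: "Lineage") -> bool:
        return other.names[: len(self.names)] == self.names

    def common_prefix(self, other: "Lineage") -> "Lineage":
        names = []
        for a, b in zip(self.names, other.names):
            if a != b:
                break
            names.append(a)
        return Lineage(tuple(names))

    def pairs(self) -> Iterator[tuple[str, str]]:
        return iter(zip(RANKS, self.names))

    # -- serialization ------------------------------------------------
    def to_string(self, sep: str = ";", rank_prefixes: bool = False) -> str:
        if rank_prefixes:
            return sep.join(
                f"{_RANK_PREFIXES[i]}__{n}" for i, n in enumerate(self.names)
            )
        return sep.join(self.names)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()

    def __len__(self) -> int:
        return len(self.names)

    def __bool__(self) -> bool:
        return bool(self.names)


def common_prefix_of(lineages: Sequence[Lineage]) -> Lineage:
    """Longest lineage prefix shared by all inputs (the LCA lineage)."""
    if not lineages:
        return Lineage()
    acc = lineages[0]
    for lin in lineages[1:]:
        acc = acc.common_prefix(lin)
        if not acc:
            break
    return acc
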