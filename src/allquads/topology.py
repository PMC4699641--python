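"""Topology classes of quadruplex-forming sequences in double-stranded DNA.

A putative quadruplex-forming sequence (PQS) consists of four tracts of
guanine.  In duplex DNA the four guanine tracts may sit on either strand:
reading along the scanned strand, each tract is either a run of G (the
guanine tract is on the scanned strand, symbol ``A``) or a run of C (the
guanine tract is on the complementary strand, symbol ``B``).  The order of
the four tract symbols, read 5'->3' on the scanned strand, defines the
topology of the quadruplex.

Because a duplex locus is the same physical object whichever strand is
scanned, two 4-letter words that are reverse complements of each other
(reverse the order, swap A<->B) describe the same topology and are not
distinguished.  Under this equivalence the sixteen words over {A, B}
partition into ten classes: the classical intrastrand class AAAA (with
member BBBB, the same motif read from the other strand) and nine
interstrand classes, conventionally labelled AABB, ABAA, ABAB, ABBA, ABBB,
BAAA, BABA, BABB and BBAA.  Exchanging A<->B *without* reversal maps a
class onto its "mirror" class (the quadruplex seeded from the opposite
strand); ignoring that distinction the nine interstrand classes collapse
to five groups.

The nine interstrand classes also carry the historical numbering of
Cao, Ryvkin & Johnson (BAAA=1, ABBB=2, BBAA=3, AABB=4, BABA=5, ABAB=6,
ABBA=7, ABAA=8, BABB=9), exposed as :attr:`TopologyClass.cao_number`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "TractPattern",
    "TopologyClass",
    "reverse_complement_pattern",
    "strand_swap_pattern",
    "enumerate_classes",
    "get_class",
    "CLASS_NAMES",
    "INTERSTRAND_CLASS_NAMES",
    "INTRASTRAND_CLASS",
]

#: Canonical class labels: the intrastrand class first, then the nine
#: interstrand classes in their conventional (alphabetical) order.
INTRASTRAND_CLASS = "AAAA"
INTERSTRAND_CLASS_NAMES = (
    "AABB", "ABAA", "ABAB", "ABBA", "ABBB", "BAAA", "BABA", "BABB", "BBAA",
)
CLASS_NAMES = (INTRASTRAND_CLASS,) + INTERSTRAND_CLASS_NAMES

#: Historical interstrand class numbering of Cao et al.
_CAO_NUMBERS = {
    "BAAA": 1, "ABBB": 2, "BBAA": 3, "AABB": 4, "BABA": 5,
    "ABAB": 6, "ABBA": 7, "ABAA": 8, "BABB": 9,
}

_SWAP = str.maketrans("AB", "BA")


@dataclass(frozen=True)
class TractPattern:
    """An ordered word of four tract symbols over {A, B}.

    ``A`` = guanine tract on the scanned strand, ``B`` = cytosine tract on
    the scanned strand (i.e. a guanine tract on the complement), counted
    from the 5' end of the scanned strand.
    """

    letters: str

    def __post_init__(self) -> None:
        if len(self.letters) != 4 or set(self.letters) - {"A", "B"}:
            raise ValueError(
                f"tract pattern must be 4 letters over {{A,B}}, got {self.letters!r}"
            )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.letters


def reverse_complement_pattern(p: TractPattern) -> TractPattern:
    """Pattern seen when the same duplex locus is read from the other strand.

    Reverses the tract order and swaps A<->B; an involution on the sixteen
    patterns.  E.g. AABA -> BABB.
    """
    return TractPattern(p.letters[::-1].translate(_SWAP))


def strand_swap_pattern(p: TractPattern) -> TractPattern:
    """Swap A<->B keeping the order: the mirror-image topology.

    Relates a quadruplex "starting" from the positive strand to the one
    starting from the negative strand; an involution.
    """
    return TractPattern(p.letters.translate(_SWAP))


@dataclass(frozen=True)
class TopologyClass:
    """One equivalence class of tract patterns under reverse complement.

    ``canonical_pattern`` is the member whose letters give the class its
    name; ``alternative_pattern`` is the reverse-complement member when it
    differs (None for the four self-reverse-complementary interstrand
    classes).  ``strand_swap_partner`` names the class obtained by swapping
    A<->B without reversal.
    """

    name: str
    canonical_pattern: TractPattern
    alternative_pattern: Optional[TractPattern]
    cao_number: Optional[int]
    strand_swap_partner: str = field(default="")

    @property
    def members(self) -> tuple[TractPattern, ...]:
        """Member patterns, canonical first."""
        if self.alternative_pattern is None:
            return (self.canonical_pattern,)
        return (self.canonical_pattern, self.alternative_pattern)

    @property
    def is_interstrand(self) -> bool:
        return self.name != INTRASTRAND_CLASS

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def enumerate_classes() -> list[TopologyClass]:
    """Partition the sixteen 4-letter patterns into the ten topology classes.

    Returns AAAA first, then the nine interstrand classes in canonical
    order.  Exhaustively groups every pattern with its reverse complement
    and names each group by the member in :data:`CLASS_NAMES`.
    """
    all_patterns = [
        TractPattern("".join(w)) for w in itertools.product("AB", repeat=4)
    ]
    groups: dict[frozenset[str], set[str]] = {}
    for p in all_patterns:
        rc = reverse_complement_pattern(p)
        key = frozenset({p.letters, rc.letters})
        groups.setdefault(key, set()).update(key)
    # AAAA and BBBB are each self-reverse-complementary only as a pair:
    # rc(AAAA)=BBBB, so they already share one group.
    named: dict[str, set[str]] = {}
    for members in groups.values():
        canon = [m for m in members if m in CLASS_NAMES]
        if len(canon) != 1:
            raise AssertionError(f"group {sorted(members)} has no unique canonical name")
        named[canon[0]] = members

    classes: list[TopologyClass] = []
    for name in CLASS_NAMES:
        members = named[name]
        canonical = TractPattern(name)
        rc = reverse_complement_pattern(canonical)
        alternative = rc if rc.letters != name else None
        classes.append(
            TopologyClass(
                name=name,
                canonical_pattern=canonical,
                alternative_pattern=alternative,
                cao_number=_CAO_NUMBERS.get(name),
                strand_swap_partner="",  # filled below
            )
        )
    # Resolve strand-swap partners at class level: the class containing the
    # letter-swapped canonical pattern.
    member_to_class = {m: c.name for c in classes for m in named[c.name]}
    resolved = [
        TopologyClass(
            name=c.name,
            canonical_pattern=c.canonical_pattern,
            alternative_pattern=c.alternative_pattern,
            cao_number=c.cao_number,
            strand_swap_partner=member_to_class[
                strand_swap_pattern(c.canonical_pattern).letters
            ],
        )
        for c in classes
    ]
    return resolved


_CLASSES_BY_NAME: dict[str, TopologyClass] = {c.name: c for c in enumerate_classes()}


def get_class(name: str) -> TopologyClass:
    """Look up a topology class by canonical name (raises KeyError otherwise)."""
    try:
        return _CLASSES_BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown topology class {name!r}; expected one of {CLASS_NAMES}"
        ) from None
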