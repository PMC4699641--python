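"""Regex-based scanning for quadruplex-forming sequences of every topology.

Each topology class is searched with a single Perl-style regular
expression built from its member tract patterns:

* a guanine tract is ``G{t,}`` (``C{t,}`` for a B tract), greedy, with
  ``t`` the minimum tract length (default 3);
* the first occurrence of each letter in a pattern is a capturing group;
  every later occurrence of that letter is a backreference to it, so all
  same-letter tracts of one match repeat the identical string;
* the gap between consecutive tracts is ``.{1,7}`` when they carry the
  same letter (a loop on one strand) and ``.{0,7}`` when the letters
  differ (the quadruplex crosses between strands, so a zero-length gap is
  legal);
* a class with two member patterns is the alternation canonical-first;
  the intrastrand class AAAA is the alternation of the all-G and all-C
  expressions.

Matches are collected with global leftmost semantics (Perl ``m//g``):
each search resumes at the end of the previous match, so matches of one
class never overlap each other.  Matches of *different* classes may
overlap; resolving those overlaps is the job of :mod:`allquads.intervals`.

The backreference semantics are deliberate and load-bearing: ``\\1``
requires exact repetition of the captured tract, and with greedy capture
plus backtracking this admits later tracts at least as long as the
shortest viable first tract, surplus letters being absorbed by the
adjacent gaps.  Counts would change genome-wide if the backreferences
were "normalised" to independent ``{t,}`` quantifiers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .topology import (
    CLASS_NAMES,
    TopologyClass,
    TractPattern,
    get_class,
)

__all__ = [
    "ScanParams",
    "PQSRecord",
    "ClassMatcher",
    "build_pattern_expression",
    "scan_class",
    "scan_all",
    "guanines_in_quadruplex",
    "validate_record",
    "DEFAULT_PARAMS",
]

_TRACT_CHAR = {"A": "G", "B": "C"}


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the motif search.

    min_tract
        Minimum G/C run length per tract (the ``{3,}`` in the patterns).
    same_loop_min, same_loop_max
        Loop-length bounds between two tracts of the same letter (1-7 by
        default: a loop on a single strand needs at least one nucleotide).
    cross_gap_min, cross_gap_max
        Gap bounds between tracts of different letters (0-7 by default:
        the structure switches strands, so adjacency is allowed).
    loop_max_alt
        When set (e.g. 12, the relaxed variant used for functional
        analyses), replaces both maxima.
    case_mode
        ``"fold"`` uppercases the sequence before scanning; ``"strict"``
        scans case-sensitively, so soft-masked lowercase never forms a
        tract (it may still sit in a loop).
    ambiguous_in_loops
        If True (default), loops behave like ``.`` and accept any letter,
        including N; if False, loops only accept A/C/G/T.
    """

    min_tract: int = 3
    same_loop_min: int = 1
    same_loop_max: int = 7
    cross_gap_min: int = 0
    cross_gap_max: int = 7
    loop_max_alt: Optional[int] = None
    case_mode: str = "fold"
    ambiguous_in_loops: bool = True

    def __post_init__(self) -> None:
        if self.min_tract < 2:
            raise ValueError("min_tract must be >= 2")
        if not (0 <= self.cross_gap_min <= self.effective_cross_gap_max):
            raise ValueError("invalid cross-strand gap bounds")
        if not (1 <= self.same_loop_min <= self.effective_same_loop_max):
            raise ValueError("invalid same-strand loop bounds")
        if self.case_mode not in ("fold", "strict"):
            raise ValueError("case_mode must be 'fold' or 'strict'")

    @property
    def effective_same_loop_max(self) -> int:
        return self.loop_max_alt if self.loop_max_alt is not None else self.same_loop_max

    @property
    def effective_cross_gap_max(self) -> int:
        return self.loop_max_alt if self.loop_max_alt is not None else self.cross_gap_max

    def gap_bounds(self, prev_letter: str, next_letter: str) -> tuple[int, int]:
        """Loop/gap bounds between two adjacent tracts given their letters."""
        if prev_letter == next_letter:
            return self.same_loop_min, self.effective_same_loop_max
        return self.cross_gap_min, self.effective_cross_gap_max


DEFAULT_PARAMS = ScanParams()


@dataclass
class PQSRecord:
    """One predicted quadruplex-forming locus on the scanned strand.

    Coordinates are 0-based half-open.  ``tract_spans`` holds the four
    matched tract sub-intervals (absolute coordinates); records
    reconstructed from BED, where tract positions are lost, carry None.
    """

    seq_id: str
    start: int
    end: int
    topology: str
    pattern_matched: str
    matched_seq: str
    tract_spans: Optional[tuple[tuple[int, int], ...]] = None

    @property
    def is_interstrand(self) -> bool:
        return self.topology != "AAAA"


def guanines_in_quadruplex(r: PQSRecord) -> int:
    """Total guanines contributed by both strands to the four tetrad columns.

    A-tracts contribute guanines from the scanned strand; B-tracts (runs
    of C) contribute the guanines of their complement.  Equal to the sum
    of the four tract lengths, e.g. 12 for a minimal 4x3 motif.
    """
    if r.tract_spans is None:
        raise ValueError("record has no tract spans (BED-derived?)")
    return sum(e - s for s, e in r.tract_spans)


@dataclass(frozen=True)
class ClassMatcher:
    """Compiled search expression for one topology class."""

    topology: TopologyClass
    regex: "re.Pattern[str]"
    members: tuple[TractPattern, ...]
    source: str  # the regex text, for logging/headers


def _member_expression(letters: str, alt_index: int, params: ScanParams) -> str:
    """Regex for one member pattern; tract j is named group ``t{alt_index}{j}``."""
    dot = "." if params.ambiguous_in_loops else "[ACGTacgt]"
    first_seen: dict[str, str] = {}
    parts: list[str] = []
    for j, letter in enumerate(letters):
        if j > 0:
            lo, hi = params.gap_bounds(letters[j - 1], letter)
            parts.append(f"{dot}{{{lo},{hi}}}")
        name = f"t{alt_index}{j}"
        if letter in first_seen:
            parts.append(f"(?P<{name}>(?P={first_seen[letter]}))")
        else:
            first_seen[letter] = name
            parts.append(f"(?P<{name}>{_TRACT_CHAR[letter]}{{{params.min_tract},}})")
    return "".join(parts)


def build_pattern_expression(
    cls: Union[str, TopologyClass], params: ScanParams = DEFAULT_PARAMS
) -> ClassMatcher:
    """Build the search expression for a topology class.

    For a class with two member patterns the expression is the alternation
    canonical-then-alternative, matching the published per-class
    expressions; AAAA alternates its all-G member with its all-C member.
    """
    if isinstance(cls, str):
        cls = get_class(cls)
    members = cls.members
    source = "|".join(
        _member_expression(m.letters, i, params) for i, m in enumerate(members)
    )
    return ClassMatcher(
        topology=cls, regex=re.compile(source), members=members, source=source
    )


def _records_from_matcher(
    text: str, seq_id: str, matcher: ClassMatcher
) -> list[PQSRecord]:
    records: list[PQSRecord] = []
    for m in matcher.regex.finditer(text):
        for i, member in enumerate(matcher.members):
            if m.start(f"t{i}0") != -1:
                spans = tuple(m.span(f"t{i}{j}") for j in range(4))
                records.append(
                    PQSRecord(
                        seq_id=seq_id,
                        start=m.start(),
                        end=m.end(),
                        topology=matcher.topology.name,
                        pattern_matched=member.letters,
                        matched_seq=m.group(0),
                        tract_spans=spans,
                    )
                )
                break
    return records


def scan_class(
    seq: str,
    seq_id: str,
    cls: Union[str, TopologyClass],
    params: ScanParams = DEFAULT_PARAMS,
) -> list[PQSRecord]:
    """All global (non-overlapping, leftmost) matches of one class in a sequence."""
    matcher = build_pattern_expression(cls, params)
    text = seq.upper() if params.case_mode == "fold" else seq
    return _records_from_matcher(text, seq_id, matcher)


def scan_all(
    seq: str,
    seq_id: str,
    params: ScanParams = DEFAULT_PARAMS,
    classes: Optional[Sequence[Union[str, TopologyClass]]] = None,
) -> list[PQSRecord]:
    """Scan a sequence with every topology class (a one-step search per class).

    Records from different classes may overlap; merging overlapping
    records into unique sites is handled by :mod:`allquads.intervals`.
    Results are sorted by coordinate, then class name.
    """
    if classes is None:
        classes = CLASS_NAMES
    text = seq.upper() if params.case_mode == "fold" else seq
    records: list[PQSRecord] = []
    for cls in classes:
        matcher = build_pattern_expression(cls, params)
        records.extend(_records_from_matcher(text, seq_id, matcher))
    records.sort(key=lambda r: (r.seq_id, r.start, r.end, r.topology))
    return records


def validate_record(
    r: PQSRecord, params: ScanParams = DEFAULT_PARAMS, seq: Optional[str] = None
) -> None:
    """Assert the structural invariants of a scanned record (testing aid).

    Checks span arithmetic, tract ordering/disjointness, minimum tract
    length, per-adjacency gap bounds, letter agreement between
    ``pattern_matched`` and tract content, and backreference equality of
    same-letter tracts.  Raises AssertionError on violation.
    """
    assert r.end - r.start == len(r.matched_seq), "span/sequence length mismatch"
    assert r.tract_spans is not None and len(r.tract_spans) == 4
    letters = r.pattern_matched
    text = seq if seq is not None else None
    if text is not None and params.case_mode == "fold":
        text = text.upper()
    prev_end = None
    first_tract: dict[str, str] = {}
    for j, (s, e) in enumerate(r.tract_spans):
        assert r.start <= s < e <= r.end, "tract outside match span"
        assert e - s >= params.min_tract, "tract below minimum length"
        if prev_end is not None:
            lo, hi = params.gap_bounds(letters[j - 1], letters[j])
            gap = s - prev_end
            assert lo <= gap <= hi, f"gap {gap} outside [{lo},{hi}]"
        prev_end = e
        content = (
            text[s:e] if text is not None else r.matched_seq[s - r.start : e - r.start]
        )
        assert set(content) == {_TRACT_CHAR[letters[j]]}, "tract content mismatch"
        if letters[j] in first_tract:
            assert content == first_tract[letters[j]], "backreference violated"
        else:
            first_tract[letters[j]] = content
    assert r.tract_spans[0][0] == r.start and r.tract_spans[3][1] == r.end, (
        "match must begin and end on a tract"
    )
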