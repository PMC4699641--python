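"""Synthetic sequences with known ground truth, and brute-force oracles.

Provides (a) i.i.d. random nucleotide sequences at a chosen GC content,
(b) motif planting: writing a quadruplex-forming motif of a chosen
topology, tract lengths and gap lengths into a sequence, with truth
coordinates returned, (c) PQS-free backgrounds in which no G/C run of
tract length exists anywhere (so no class can match, certifiably), and
(d) an exhaustive placement oracle that enumerates every way the four
tracts of a topology class can be placed in a short sequence.

The oracle shares no matching code with the scanner: it enumerates
candidate tract substrings directly and applies the adjacency gap rules
and the backreference constraint (all same-letter tracts of one
placement repeat the first tract's exact string) combinatorially.  It is
the independent referee for the regex engine's semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Union

import numpy as np

from .scanner import DEFAULT_PARAMS, PQSRecord, ScanParams
from .topology import CLASS_NAMES, TopologyClass, TractPattern, get_class

__all__ = [
    "PlantSpec",
    "random_sequence",
    "pqs_free_background",
    "build_motif",
    "plant_pqs",
    "make_planted_genome",
    "Placement",
    "brute_force_placements",
    "has_placement",
]

_TRACT_CHAR = {"A": "G", "B": "C"}


def random_sequence(
    length: int,
    gc_content: float,
    seed: Union[int, np.random.Generator, None] = None,
) -> str:
    """I.i.d. nucleotide string with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc_content <= 1.0):
        raise ValueError("gc_content must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = gc_content / 2.0
    a = (1.0 - gc_content) / 2.0
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    idx = rng.choice(4, size=length, p=[a, g, g, a])
    return letters[idx].tobytes().decode("ascii")


def pqs_free_background(
    length: int,
    gc_content: float = 0.4,
    seed: Union[int, np.random.Generator, None] = None,
    min_tract: int = 3,
) -> str:
    """Random sequence guaranteed to contain no G or C run of tract length.

    Generated i.i.d., then every position that would complete a run of
    ``min_tract`` identical G/C letters is rewritten to A or T.  Absence
    of any run >= min_tract is a *necessary* condition for a quadruplex
    motif of any topology class, so the result is certifiably free of
    matches and of oracle placements; the function asserts this by direct
    substring inspection.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = list(random_sequence(length, gc_content, rng))
    run = 1
    for i in range(1, length):
        if s[i] in "GC" and s[i] == s[i - 1]:
            run += 1
        else:
            run = 1
        if run >= min_tract:
            s[i] = "A" if rng.integers(2) == 0 else "T"
            run = 1
    out = "".join(s)
    assert "G" * min_tract not in out and "C" * min_tract not in out
    return out


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one planted quadruplex-forming motif.

    Tract lengths must be equal within each letter (the scanner's
    backreference requires same-letter tracts to repeat the first tract's
    string exactly); gap lengths must respect the per-adjacency bounds of
    the chosen member pattern.
    """

    topology: str
    tract_lengths: tuple[int, int, int, int]
    gap_lengths: tuple[int, int, int]
    position: int
    use_alternative: bool = False

    def member(self) -> TractPattern:
        cls = get_class(self.topology)
        if self.use_alternative:
            if cls.alternative_pattern is None:
                raise ValueError(f"class {self.topology} has a single member pattern")
            return cls.alternative_pattern
        return cls.canonical_pattern

    def validate(self, params: ScanParams = DEFAULT_PARAMS) -> None:
        letters = self.member().letters
        per_letter: dict[str, int] = {}
        for letter, tl in zip(letters, self.tract_lengths):
            if tl < params.min_tract:
                raise ValueError(f"tract length {tl} < min_tract {params.min_tract}")
            if per_letter.setdefault(letter, tl) != tl:
                raise ValueError("same-letter tracts must have equal lengths")
        for j, gap in enumerate(self.gap_lengths):
            lo, hi = params.gap_bounds(letters[j], letters[j + 1])
            if not (lo <= gap <= hi):
                raise ValueError(
                    f"gap {gap} between tracts {j},{j+1} outside [{lo},{hi}]"
                )

    @property
    def motif_length(self) -> int:
        return sum(self.tract_lengths) + sum(self.gap_lengths)


def build_motif(
    spec: PlantSpec,
    loop_alphabet: str = "AT",
    params: ScanParams = DEFAULT_PARAMS,
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, tuple[tuple[int, int], ...]]:
    """Motif string and motif-relative tract spans for a plant recipe.

    Loop positions are filled from ``loop_alphabet`` ({A, T} by default so
    loops can never extend a tract); deterministic (first letter) unless
    an rng is given.
    """
    spec.validate(params)
    letters = spec.member().letters
    pieces: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    for j in range(4):
        if j > 0:
            gap = spec.gap_lengths[j - 1]
            if rng is None:
                pieces.append(loop_alphabet[0] * gap)
            else:
                pieces.append(
                    "".join(loop_alphabet[int(i)] for i in rng.integers(0, len(loop_alphabet), gap))
                )
            pos += gap
        tl = spec.tract_lengths[j]
        pieces.append(_TRACT_CHAR[letters[j]] * tl)
        spans.append((pos, pos + tl))
        pos += tl
    return "".join(pieces), tuple(spans)


def plant_pqs(
    seq: str,
    spec: PlantSpec,
    loop_alphabet: str = "AT",
    params: ScanParams = DEFAULT_PARAMS,
    rng: Optional[np.random.Generator] = None,
    seq_id: str = "synthetic",
    guard: bool = True,
) -> tuple[str, PQSRecord]:
    """Overwrite a window of ``seq`` with a motif; return (sequence, truth).

    With ``guard`` (default), the single flanking base on each side of
    the motif is rewritten to T so that background G/C cannot extend the
    terminal tracts and shift the match start.
    """
    motif, rel_spans = build_motif(spec, loop_alphabet, params, rng)
    start = spec.position
    end = start + len(motif)
    if start < 0 or end > len(seq):
        raise ValueError("motif does not fit in the sequence")
    s = list(seq)
    s[start:end] = motif
    if guard:
        if start > 0:
            s[start - 1] = "T"
        if end < len(s):
            s[end] = "T"
    truth = PQSRecord(
        seq_id=seq_id,
        start=start,
        end=end,
        topology=spec.topology,
        pattern_matched=spec.member().letters,
        matched_seq=motif,
        tract_spans=tuple((start + a, start + b) for a, b in rel_spans),
    )
    return "".join(s), truth


def make_planted_genome(
    length: int,
    per_class: int,
    seed: int,
    classes: Sequence[str] = CLASS_NAMES,
    params: ScanParams = DEFAULT_PARAMS,
    gc_content: float = 0.4,
    min_spacing: int = 50,
    seq_id: str = "synthetic",
) -> tuple[str, list[PQSRecord]]:
    """A PQS-free background with ``per_class`` motifs of each class planted.

    Motifs are placed on an evenly spaced grid (shuffled assignment of
    class/geometry to slots) with at least ``min_spacing`` background
    bases between consecutive motifs, so planted tracts can never combine
    across motifs (gaps are bounded by the loop maxima, far below the
    spacing).  Gap lengths are drawn randomly within bounds; tract
    lengths are fixed at ``min_tract`` so that truth coordinates are
    unambiguous: with longer tracts a greedy inter-tract gap may consume
    a leading tract base and legitimately truncate the final
    backreference, shifting the match end (Perl semantics).
    Returns the sequence and the truth records sorted by coordinate.
    """
    rng = np.random.default_rng(seed)
    seq = pqs_free_background(length, gc_content, rng, params.min_tract)

    plan: list[tuple[str, bool]] = []
    for name in classes:
        cls = get_class(name)
        for _ in range(per_class):
            use_alt = bool(cls.alternative_pattern is not None and rng.integers(2))
            plan.append((name, use_alt))
    order = rng.permutation(len(plan))

    max_motif = 4 * (params.min_tract + 1) + 3 * min(7, params.effective_same_loop_max)
    slot = max_motif + min_spacing
    if slot * len(plan) > length:
        raise ValueError("sequence too short for the requested number of motifs")
    stride = length // len(plan)

    truths: list[PQSRecord] = []
    for i, which in enumerate(order):
        name, use_alt = plan[which]
        cls = get_class(name)
        letters = (
            cls.alternative_pattern if use_alt else cls.canonical_pattern
        ).letters
        tracts = (params.min_tract,) * 4
        gaps = []
        for j in range(3):
            lo, hi = params.gap_bounds(letters[j], letters[j + 1])
            gaps.append(int(rng.integers(lo, min(hi, 7) + 1)))
        spec = PlantSpec(
            topology=name,
            tract_lengths=tracts,
            gap_lengths=tuple(gaps),
            position=i * stride + 1,
            use_alternative=use_alt,
        )
        seq, truth = plant_pqs(seq, spec, params=params, rng=rng, seq_id=seq_id)
        truths.append(truth)
    truths.sort(key=lambda r: (r.start, r.topology))
    return seq, truths


@dataclass(frozen=True)
class Placement:
    """One exhaustively enumerated tract placement."""

    member: str
    tract_spans: tuple[tuple[int, int], ...]


def _tract_candidates(text: str, char: str, min_tract: int) -> list[tuple[int, int]]:
    """All (start, end) substrings of >= min_tract identical ``char`` letters."""
    out: list[tuple[int, int]] = []
    n = len(text)
    i = 0
    while i < n:
        if text[i] == char:
            j = i
            while j < n and text[j] == char:
                j += 1
            run_len = j - i
            for length in range(min_tract, run_len + 1):
                for s in range(i, j - length + 1):
                    out.append((s, s + length))
            i = j
        else:
            i += 1
    out.sort()
    return out


def brute_force_placements(
    seq: str,
    cls: Union[str, TopologyClass],
    params: ScanParams = DEFAULT_PARAMS,
    max_len: int = 500,
) -> list[Placement]:
    """Exhaustive enumeration of valid 4-tract placements for one class.

    A placement fixes, for one member pattern of the class, four ordered
    non-overlapping tract substrings such that (a) each tract is a run of
    the letter's nucleotide of length >= min_tract, (b) all tracts of one
    letter are the same length (exact-string backreference: identical
    runs of one character), and (c) every inter-tract gap respects the
    same-letter / cross-letter bounds.  Existence of a placement is
    equivalent to existence of a regex match; placement counts exceed
    match counts because global matching is non-overlapping and greedy.
    """
    if len(seq) > max_len:
        raise ValueError(f"sequence longer than {max_len}; exhaustive search refused")
    return list(_iter_placements(seq, cls, params))


def has_placement(
    seq: str,
    cls: Union[str, TopologyClass],
    params: ScanParams = DEFAULT_PARAMS,
    max_len: int = 500,
) -> bool:
    """True iff at least one valid placement exists (short-circuiting)."""
    if len(seq) > max_len:
        raise ValueError(f"sequence longer than {max_len}; exhaustive search refused")
    for _ in _iter_placements(seq, cls, params):
        return True
    return False


def _iter_placements(
    seq: str,
    cls: Union[str, TopologyClass],
    params: ScanParams,
) -> Iterator[Placement]:
    if isinstance(cls, str):
        cls = get_class(cls)
    text = seq.upper() if params.case_mode == "fold" else seq
    if not params.ambiguous_in_loops:
        # loops may only contain A/C/G/T: positions with other letters
        # cannot sit inside a placement's gaps
        bad = [i for i, ch in enumerate(text) if ch.upper() not in "ACGT"]
    else:
        bad = []

    for member in cls.members:
        letters = member.letters
        cands = {
            letter: _tract_candidates(text, _TRACT_CHAR[letter], params.min_tract)
            for letter in set(letters)
        }

        def extend(
            j: int, chosen: list[tuple[int, int]], lengths: dict[str, int]
        ) -> Iterator[Placement]:
            if j == 4:
                yield Placement(member=letters, tract_spans=tuple(chosen))
                return
            letter = letters[j]
            for s, e in cands[letter]:
                if letter in lengths and e - s != lengths[letter]:
                    continue
                if j > 0:
                    prev_end = chosen[-1][1]
                    lo, hi = params.gap_bounds(letters[j - 1], letter)
                    gap = s - prev_end
                    if gap < lo:
                        continue
                    if gap > hi:
                        break  # candidates sorted: all later starts worse
                    if bad and any(prev_end <= b < s for b in bad):
                        continue
                new_lengths = lengths
                if letter not in lengths:
                    new_lengths = dict(lengths)
                    new_lengths[letter] = e - s
                yield from extend(j + 1, chosen + [(s, e)], new_lengths)

        yield from extend(0, [], {})
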