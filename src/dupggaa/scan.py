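"""Spacer-constrained duplicated-motif scanning.

The query is a pair of 4-mer cores — the ETS-family GGAA core by default, or
its reverse complement TTCC — separated by a bounded spacer of N positions.
A *pair type* records the orientation of the two cores as seen on the sense
strand: F is the core word, R its reverse complement, so FF = GGAA..GGAA,
FR = GGAA..TTCC, RF = TTCC..GGAA and RR = TTCC..TTCC.

Searching the two strings GGAAN{0,10}GGAA and GGAAN{0,10}TTCC on both strands
is equivalent, on the sense strand, to pair types {FF, FR, RR}: RR is the
antisense image of FF, and FR is its own reverse complement.  RF is matched by
neither string on either strand, so the default ("faithful") pattern excludes
it; :meth:`MotifPattern.all_pairs` opts into the RF arrangement explicitly.

Strand-equivalent hits are deduplicated: an FR hit, visible identically from
both strands, is one match whose ``strand_set`` records both strands.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

from .io import SequenceRecord, revcomp

PAIR_TYPES = ("FF", "FR", "RF", "RR")

#: sense-view pair types discoverable by a plus-strand-only search
_SENSE_VISIBLE = frozenset({"FF", "FR", "RF"})


@dataclass(frozen=True)
class MotifPattern:
    """A duplicated-motif query: core word, spacer bounds, pair types, strands."""

    core: str = "GGAA"
    spacer_min: int = 0
    spacer_max: int = 10
    pair_types: frozenset = frozenset({"FF", "FR", "RR"})
    both_strands: bool = True

    def __post_init__(self) -> None:
        if len(self.core) != 4 or any(c not in "ACGT" for c in self.core):
            raise ValueError(f"core must be a 4-mer over ACGT, got {self.core!r}")
        if self.spacer_min < 0 or self.spacer_min > self.spacer_max:
            raise ValueError(
                f"need 0 <= spacer_min <= spacer_max, got ({self.spacer_min}, {self.spacer_max})"
            )
        pts = frozenset(self.pair_types)
        if not pts or not pts <= set(PAIR_TYPES):
            raise ValueError(f"pair_types must be a non-empty subset of {PAIR_TYPES}")
        object.__setattr__(self, "pair_types", pts)

    @classmethod
    def faithful(cls, **kw) -> "MotifPattern":
        """The default search: GGAAN{0,10}GGAA and GGAAN{0,10}TTCC on both strands."""
        return cls(**kw)

    @classmethod
    def all_pairs(cls, **kw) -> "MotifPattern":
        """All four core arrangements, including TTCC..GGAA (RF)."""
        return cls(pair_types=frozenset(PAIR_TYPES), **kw)

    @property
    def words(self) -> dict[str, str]:
        return {"F": self.core, "R": revcomp(self.core)}

    @property
    def max_span(self) -> int:
        return 8 + self.spacer_max

    def effective_pair_types(self) -> frozenset:
        """Pair types actually reportable under the strand policy."""
        if self.both_strands:
            return self.pair_types
        return self.pair_types & _SENSE_VISIBLE

    def strand_set_for(self, pair_type: str) -> frozenset:
        """Which scanned strand(s) produce a sense-view hit of this pair type.

        FF arises from the plus-strand search, RR from the minus-strand search;
        FR and RF are their own reverse complements and arise from both.
        """
        if not self.both_strands:
            return frozenset("+")
        return {
            "FF": frozenset("+"),
            "RR": frozenset("-"),
            "FR": frozenset("+-"),
            "RF": frozenset("+-"),
        }[pair_type]


@dataclass(frozen=True)
class MotifMatch:
    """One deduplicated duplicated-motif hit on the sense-strand coordinate frame.

    ``start``/``end`` span (0-based, half-open) the first base of the first
    core through the last base of the second core, so end - start = 8 + spacer.
    """

    seq_id: str
    start: int
    end: int
    spacer: int
    pair_type: str
    strand_set: frozenset

    def __post_init__(self) -> None:
        assert self.end - self.start == 8 + self.spacer


_PATTERN_STRING_RE = re.compile(r"^([ACGTacgt]{4})N\{(\d+),(\d+)\}([ACGTacgt]{4})$")


def parse_pattern_strings(
    strings: Iterable[str], both_strands: bool = True
) -> MotifPattern:
    """Build a :class:`MotifPattern` from pattern strings like ``GGAAN{0,10}GGAA``.

    Each string contributes the sense-view pair type of its two words (plus the
    reverse-complement image when ``both_strands``); all strings must share the
    same core and spacer bounds.
    """
    strings = list(strings)
    if not strings:
        raise ValueError("at least one pattern string required")
    core = None
    bounds = None
    pair_types: set[str] = set()
    for s in strings:
        m = _PATTERN_STRING_RE.match(s.strip())
        if not m:
            raise ValueError(f"cannot parse pattern string {s!r} (expected e.g. GGAAN{{0,10}}GGAA)")
        w1, lo, hi, w2 = m.group(1).upper(), int(m.group(2)), int(m.group(3)), m.group(4).upper()
        if lo > hi:
            raise ValueError(f"pattern {s!r}: spacer bounds out of order ({lo} > {hi})")
        this_core = w1 if core is None else core
        letters = {}
        for word, slot in ((w1, 0), (w2, 1)):
            if word == this_core:
                letters[slot] = "F"
            elif word == revcomp(this_core):
                letters[slot] = "R"
            else:
                raise ValueError(
                    f"pattern {s!r}: word {word!r} is neither the core {this_core!r} "
                    f"nor its reverse complement"
                )
        if core is None:
            core = this_core
        if bounds is None:
            bounds = (lo, hi)
        elif bounds != (lo, hi):
            raise ValueError("all pattern strings must share the same spacer bounds")
        pt = letters[0] + letters[1]
        pair_types.add(pt)
        if both_strands:
            pair_types.add(_rc_pair_type(pt))
    return MotifPattern(core, bounds[0], bounds[1], frozenset(pair_types), both_strands)


def _rc_pair_type(pt: str) -> str:
    flip = {"F": "R", "R": "F"}
    return flip[pt[1]] + flip[pt[0]]


def _find_all(seq: str, word: str) -> list[int]:
    """All (overlap-allowing) start positions of ``word`` in ``seq``."""
    out = []
    i = seq.find(word)
    while i != -1:
        out.append(i)
        i = seq.find(word, i + 1)
    return out


def scan_sequence(
    record: SequenceRecord, pattern: MotifPattern | None = None
) -> list[MotifMatch]:
    """All duplicated-motif matches in one sequence, sorted by (start, spacer).

    Overlapping and nested matches are all reported; N never matches a core
    position; strand-equivalent hits collapse into one match.
    """
    if pattern is None:
        pattern = MotifPattern()
    seq = record.seq
    words = pattern.words
    positions = {w: _find_all(seq, w) for w in set(words.values())}
    palindromic = words["F"] == words["R"]
    if palindromic:
        pair_iter = [("FF", frozenset("+-") if pattern.both_strands else frozenset("+"))]
    else:
        pair_iter = [
            (pt, pattern.strand_set_for(pt))
            for pt in sorted(pattern.effective_pair_types())
        ]
    matches: list[MotifMatch] = []
    for pt, strands in pair_iter:
        p1 = positions[words[pt[0]]]
        p2 = positions[words[pt[1]]]
        for i in p1:
            lo = bisect_left(p2, i + 4 + pattern.spacer_min)
            hi = bisect_right(p2, i + 4 + pattern.spacer_max)
            for j in p2[lo:hi]:
                matches.append(
                    MotifMatch(record.id, i, j + 4, j - i - 4, pt, strands)
                )
    matches.sort(key=lambda m: (m.start, m.spacer, m.pair_type))
    return matches


def has_duplicated_motif(
    record: SequenceRecord, pattern: MotifPattern | None = None
) -> bool:
    """Presence call: does the sequence contain at least one duplicated motif?

    This per-sequence boolean is the statistic aggregated across promoter sets.
    """
    if pattern is None:
        pattern = MotifPattern()
    seq = record.seq
    words = pattern.words
    positions = {w: _find_all(seq, w) for w in set(words.values())}
    pts = {"FF"} if words["F"] == words["R"] else pattern.effective_pair_types()
    for pt in pts:
        p1 = positions[words[pt[0]]]
        p2 = positions[words[pt[1]]]
        for i in p1:
            lo = bisect_left(p2, i + 4 + pattern.spacer_min)
            hi = bisect_right(p2, i + 4 + pattern.spacer_max)
            if hi > lo:
                return True
    return False


class ScanResult(NamedTuple):
    """Per-sequence presence calls plus the full match list for a record set."""

    presence: pd.Series
    matches: list

    @property
    def n_present(self) -> int:
        return int(self.presence.sum())

    @property
    def n_total(self) -> int:
        return len(self.presence)


def scan_set(
    records: Iterable[SequenceRecord], pattern: MotifPattern | None = None
) -> ScanResult:
    """Scan a set of sequences; returns a presence table and all matches."""
    records = list(records)
    if not records:
        raise ValueError("record set is empty")
    seen: set[str] = set()
    dupes = {r.id for r in records if r.id in seen or seen.add(r.id)}
    if dupes:
        raise ValueError(f"duplicate sequence id(s): {sorted(dupes)}")
    presence = {}
    matches: list[MotifMatch] = []
    for r in records:
        hits = scan_sequence(r, pattern)
        presence[r.id] = bool(hits)
        matches.extend(hits)
    return ScanResult(pd.Series(presence, name="present", dtype=bool), matches)
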