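"""PROSITE-dialect cysteine-spacing patterns and an exhaustive scanner.

Insect odorant-binding-protein (OBP) subclasses are defined by the
spacing of their conserved cysteines, written in ScanProsite notation:
literal residue letters anchored by ``x(m,n)`` wildcard runs, e.g. the
classic-OBP motif ``Cx(15,39)Cx(3)Cx(21,44)Cx(7,12)Cx(8)C``.

The scanner enumerates *all* distinct (start, end, anchor-assignment)
occurrences by backtracking over wildcard lengths, with a reachability
table so dead branches are pruned and the worst case stays polynomial
in sequence length times pattern size (plus output size).

Semantics, chosen to mirror ScanProsite:

* a wildcard ``x`` matches ANY residue, including C, P and the unknown
  residue X;
* a literal anchor does NOT match X — anchors are the conserved-cysteine
  evidence and an unknown residue cannot supply it;
* matching is substring search, not full-sequence;
* the PROSITE termini operators ``<``/``>`` and character classes are
  not part of this dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqio import SequenceRecord


class PatternError(ValueError):
    """Raised on malformed pattern text; message carries the offset."""


@dataclass(frozen=True)
class PatternElement:
    """One token of a parsed pattern: a literal residue or a wildcard run."""

    kind: str  # "literal" | "wildcard"
    repeat_min: int
    repeat_max: int
    residue: str = ""  # literal only

    def __post_init__(self):
        if self.repeat_min > self.repeat_max or self.repeat_min < 0:
            raise PatternError(
                f"invalid repeat range ({self.repeat_min},{self.repeat_max})"
            )
        if self.kind == "literal" and (self.repeat_min, self.repeat_max) != (1, 1):
            raise PatternError("literal elements are single residues")


@dataclass(frozen=True)
class PrositePattern:
    name: str
    elements: tuple[PatternElement, ...]
    source_text: str

    @property
    def min_span(self) -> int:
        return sum(e.repeat_min for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.repeat_max for e in self.elements)

    @property
    def literal_residues(self) -> tuple[str, ...]:
        return tuple(e.residue for e in self.elements if e.kind == "literal")

    def to_text(self) -> str:
        """Re-serialize the element list (equals source_text up to whitespace)."""
        parts = []
        for e in self.elements:
            if e.kind == "literal":
                parts.append(e.residue)
            elif e.repeat_min == e.repeat_max:
                parts.append("x" if e.repeat_min == 1 else f"x({e.repeat_min})")
            else:
                parts.append(f"x({e.repeat_min},{e.repeat_max})")
        return "".join(parts)


@dataclass(frozen=True)
class MotifMatch:
    """One located occurrence; all coordinates are 1-based inclusive."""

    pattern_name: str
    start: int
    end: int
    anchor_positions: tuple[int, ...] = field(default=())

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def parse_pattern(text: str, name: str = "") -> PrositePattern:
    """Parse pattern text into ordered :class:`PatternElement` tokens.

    Grammar: residue letters are literals; ``x`` is a single-position
    wildcard; ``x(k)`` a fixed run of k; ``x(m,n)`` a run of m to n.
    Errors report the 0-based character offset.
    """
    source = text
    text = "".join(text.split())
    elements: list[PatternElement] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in ("x", "X") and (i + 1 == len(text) or text[i + 1] != "("):
            elements.append(PatternElement("wildcard", 1, 1))
            i += 1
        elif ch in ("x", "X"):
            close = text.find(")", i + 2)
            if close == -1:
                raise PatternError(f"{name or source}: unbalanced parenthesis at offset {i + 1}")
            body = text[i + 2:close]
            parts = body.split(",")
            try:
                if len(parts) == 1:
                    lo = hi = int(parts[0])
                elif len(parts) == 2:
                    lo, hi = int(parts[0]), int(parts[1])
                else:
                    raise ValueError
            except ValueError:
                raise PatternError(
                    f"{name or source}: malformed repeat {body!r} at offset {i + 2}"
                ) from None
            if lo > hi:
                raise PatternError(
                    f"{name or source}: repeat minimum {lo} exceeds maximum {hi} at offset {i + 2}"
                )
            elements.append(PatternElement("wildcard", lo, hi))
            i = close + 1
        elif ch.isalpha() and ch.isupper():
            elements.append(PatternElement("literal", 1, 1, residue=ch))
            i += 1
        elif ch == "-":
            i += 1  # PROSITE element separator, cosmetic
        else:
            raise PatternError(f"{name or source}: unexpected character {ch!r} at offset {i}")
    if not elements:
        raise PatternError(f"{name or source}: empty pattern")
    pat = PrositePattern(name=name or source, elements=tuple(elements), source_text=source)
    if pat.min_span <= 0:
        raise PatternError(f"{name or source}: pattern spans zero residues")
    return pat


def _reachable(elements: Sequence[PatternElement], seq: str) -> list[set[int]]:
    """reach[i] = positions (0-based) from which elements[i:] can complete.

    Computed backwards; used to prune the enumeration so every explored
    branch leads to at least one reported match.
    """
    n = len(seq)
    reach: list[set[int]] = [set() for _ in range(len(elements) + 1)]
    reach[len(elements)] = set(range(n + 1))
    for i in range(len(elements) - 1, -1, -1):
        e = elements[i]
        nxt = reach[i + 1]
        cur = reach[i]
        if e.kind == "literal":
            for p in range(n):
                if seq[p] == e.residue and (p + 1) in nxt:
                    cur.add(p)
        else:
            for p in range(n + 1):
                if any((p + g) in nxt for g in range(e.repeat_min,
                                                    min(e.repeat_max, n - p) + 1)):
                    cur.add(p)
    return reach


def scan(pattern: PrositePattern, sequence: SequenceRecord | str) -> list[MotifMatch]:
    """Enumerate every distinct occurrence of ``pattern`` in ``sequence``.

    Returns matches sorted by (start, end, anchors); distinct wildcard
    splittings that place the literal anchors identically are reported
    once.  Substring semantics: a match may begin anywhere.
    """
    seq = sequence.residues if isinstance(sequence, SequenceRecord) else str(sequence).upper()
    elements = pattern.elements
    n = len(seq)
    if n < pattern.min_span:
        return []
    reach = _reachable(elements, seq)
    results: set[tuple[int, int, tuple[int, ...]]] = set()

    def walk(i: int, pos: int, anchors: tuple[int, ...], start: int) -> None:
        if i == len(elements):
            results.add((start, pos, anchors))  # pos is 0-based one-past-last = 1-based last
            return
        e = elements[i]
        if e.kind == "literal":
            if pos < n and seq[pos] == e.residue and (pos + 1) in reach[i + 1]:
                walk(i + 1, pos + 1, anchors + (pos + 1,), start)
        else:
            for g in range(e.repeat_min, min(e.repeat_max, n - pos) + 1):
                if (pos + g) in reach[i + 1]:
                    walk(i + 1, pos + g, anchors, start)

    for p in sorted(reach[0]):
        if p < n or pattern.min_span == 0:
            walk(0, p, (), p + 1)

    # a match must actually consume residues from its start; dedupe by
    # (start, end, anchors) — wildcard-only repartitions collapse here
    matches = [
        MotifMatch(pattern_name=pattern.name, start=s, end=t, anchor_positions=a)
        for (s, t, a) in results
        if t >= s
    ]
    matches.sort(key=lambda m: (m.start, m.end, m.anchor_positions))
    return matches


def has_complete_motif(sequence: SequenceRecord | str,
                       patterns: Iterable[PrositePattern]) -> bool:
    """True iff at least one pattern occurs at least once in the sequence."""
    seq = sequence.residues if isinstance(sequence, SequenceRecord) else str(sequence).upper()
    n = len(seq)
    for pattern in patterns:
        if n < pattern.min_span:
            continue
        if _reachable(pattern.elements, seq)[0]:
            return True
    return False
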