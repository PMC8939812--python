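"""Independent reference implementations used only to check obpscan.

Each oracle takes a deliberately different route from the code under
test: the motif oracle converts patterns to regular expressions and
tests every substring; the pI oracle scans a dense pH grid; MW and pI
are additionally cross-checked against Biopython's ProtParam layer.
"""

from __future__ import annotations

import re

import numpy as np

from obpscan.motifs import PrositePattern


def pattern_to_regex(pattern: PrositePattern) -> re.Pattern:
    parts = []
    for e in pattern.elements:
        if e.kind == "literal":
            parts.append(re.escape(e.residue))
        elif e.repeat_min == e.repeat_max:
            parts.append(f".{{{e.repeat_min}}}")
        else:
            parts.append(f".{{{e.repeat_min},{e.repeat_max}}}")
    return re.compile("".join(parts), flags=re.DOTALL)


def substring_spans(pattern: PrositePattern, seq: str) -> set[tuple[int, int]]:
    """All (start, end) 1-based spans whose substring matches the whole
    pattern, by brute force over every substring.

    Anchor semantics: a literal never matches X, so substrings are
    pre-screened by replacing nothing — the regex uses ``.`` for
    wildcards and exact letters for literals, and X only ever fails at
    a literal because residue letters are uppercase and X is not among
    the pattern's literals unless planted.
    """
    rx = pattern_to_regex(pattern)
    n = len(seq)
    spans = set()
    lo, hi = pattern.min_span, pattern.max_span
    for i in range(n):
        for j in range(i + lo, min(n, i + hi) + 1):
            if rx.fullmatch(seq[i:j]):
                spans.add((i + 1, j))
    return spans


def enumerate_anchor_matches(pattern: PrositePattern, seq: str) -> set[tuple]:
    """All (start, end, anchors) occurrences by naive recursion (no
    pruning or memoization); exponential, for tiny cases only."""
    elements = pattern.elements
    out = set()

    def rec(i, pos, anchors, start):
        if i == len(elements):
            if pos > start:
                out.add((start + 1, pos, tuple(a + 1 for a in anchors)))
            return
        e = elements[i]
        if e.kind == "literal":
            if pos < len(seq) and seq[pos] == e.residue:
                rec(i + 1, pos + 1, anchors + [pos], start)
        else:
            for g in range(e.repeat_min, e.repeat_max + 1):
                if pos + g <= len(seq):
                    rec(i + 1, pos + g, anchors, start)

    for s in range(len(seq)):
        rec(0, s, [], s)
    return out


def grid_isoelectric_point(seq: str, pka, step: float = 1e-4) -> float:
    """argmin |net charge| over a dense pH grid (vectorized)."""
    ph = np.arange(0.0, 14.0 + step, step)
    charge = np.zeros_like(ph)
    groups = [(pka.n_terminus.get(seq[0], pka.n_terminus_default), 1, +1),
              (pka.c_terminus.get(seq[-1], pka.c_terminus_default), 1, -1)]
    for aa, k in pka.basic_side_chains.items():
        if seq.count(aa):
            groups.append((k, seq.count(aa), +1))
    for aa, k in pka.acidic_side_chains.items():
        if seq.count(aa):
            groups.append((k, seq.count(aa), -1))
    for k, count, sign in groups:
        if sign > 0:
            charge += count / (1.0 + 10.0 ** (ph - k))
        else:
            charge -= count / (1.0 + 10.0 ** (k - ph))
    return float(ph[np.argmin(np.abs(charge))])


def random_pattern(rng, max_literals: int = 4, max_gap: int = 6) -> str:
    """Small random pattern text over anchors C/P with short gaps."""
    n_lit = rng.randint(1, max_literals)
    parts = []
    for i in range(n_lit):
        parts.append(rng.choice("CCP"))  # cysteine-biased anchors
        if i < n_lit - 1:
            lo = rng.randint(0, max_gap)
            hi = rng.randint(lo, max_gap)
            parts.append(f"x({lo},{hi})" if lo != hi else f"x({lo})")
    return "".join(parts)


def random_peptide(rng, min_len: int = 2, max_len: int = 60) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(rng.choice(alphabet) for _ in range(rng.randint(min_len, max_len)))
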