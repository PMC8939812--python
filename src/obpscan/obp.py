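"""Odorant-binding-protein subclass calling from cysteine-spacing motifs.

Three OBP subclasses are recognised, each defined by a ScanProsite-style
pattern over the conserved cysteine scaffold:

* classic  — six cysteines, ``Cx(15,39)Cx(3)Cx(21,44)Cx(7,12)Cx(8)C``
* atypical — six cysteines with tighter gaps,
  ``Cx(26,27)Cx(3)Cx(36,38)Cx(11,15)Cx(8)C``
* plus-C   — eight cysteines (extra C4a and C6a) and a conserved proline
  immediately after C6,
  ``Cx(8,41)Cx(3)Cx(39,47)Cx(17,29)Cx(9)Cx(8)CPx(9,11)C``

In every subclass the C2–C3 gap is exactly 3 residues and the C5–C6 gap
exactly 8 (C6–C6a for plus-C), the family's diagnostic spacings.

A protein matching more than one pattern is assigned the
highest-precedence class; the default precedence plus-C > atypical >
classic puts the most-constrained pattern first (classic's wide ranges
contain much of atypical's, so the reverse order would make atypical
unreachable in the overlap).  The precedence is a configuration switch
on :class:`ObpMotifClassifier`.

Proteins with fewer than six cysteines (the minus-C group) have no
pattern here and come back labelled ``none``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .motifs import MotifMatch, PrositePattern, parse_pattern, scan
from .seqio import DomainHit, SequenceRecord

PBP_GOBP_ACCESSION = "PF01395"

CLASSIC_MOTIF = "Cx(15,39)Cx(3)Cx(21,44)Cx(7,12)Cx(8)C"
ATYPICAL_MOTIF = "Cx(26,27)Cx(3)Cx(36,38)Cx(11,15)Cx(8)C"
PLUS_C_MOTIF = "Cx(8,41)Cx(3)Cx(39,47)Cx(17,29)Cx(9)Cx(8)CPx(9,11)C"

#: anchor labels in pattern order (plus-C: C4a/C6a are the extra
#: cysteines, "P" the conserved proline immediately after C6)
CLASSIC_ANCHORS = ("C1", "C2", "C3", "C4", "C5", "C6")
PLUS_C_ANCHORS = ("C1", "C2", "C3", "C4", "C4a", "C5", "C6", "P", "C6a")

DEFAULT_PRECEDENCE = ("plus_c", "atypical", "classic")


@dataclass(frozen=True)
class ObpClassDefinition:
    label: str
    pattern: PrositePattern
    cysteine_names: tuple[str, ...]
    precedence_rank: int  # lower rank wins

    def __post_init__(self):
        n_literals = sum(1 for e in self.pattern.elements if e.kind == "literal")
        if len(self.cysteine_names) != n_literals:
            raise ValueError(
                f"{self.label}: {len(self.cysteine_names)} anchor names for "
                f"{n_literals} pattern literals"
            )


@dataclass
class ObpAnnotation:
    """Per-sequence classification result with conserved-cysteine map."""

    sequence_id: str
    label: str | None
    match: MotifMatch | None = None
    cysteine_positions: dict[str, int] = field(default_factory=dict)
    spacing_vector: tuple[int, ...] = ()
    complete: bool = False
    domain_supported: bool | None = None  # None when no hits were provided
    classes_matched: tuple[str, ...] = ()


def builtin_class_definitions(
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> list[ObpClassDefinition]:
    """The three built-in subclass definitions, ranked by ``precedence``."""
    order = list(precedence)
    if sorted(order) != sorted(DEFAULT_PRECEDENCE):
        raise ValueError(f"precedence must permute {DEFAULT_PRECEDENCE}, got {precedence}")
    specs = {
        "classic": (CLASSIC_MOTIF, CLASSIC_ANCHORS),
        "atypical": (ATYPICAL_MOTIF, CLASSIC_ANCHORS),
        "plus_c": (PLUS_C_MOTIF, PLUS_C_ANCHORS),
    }
    defs = [
        ObpClassDefinition(
            label=label,
            pattern=parse_pattern(text, name=label),
            cysteine_names=anchors,
            precedence_rank=order.index(label),
        )
        for label, (text, anchors) in specs.items()
    ]
    defs.sort(key=lambda d: d.precedence_rank)
    return defs


def _canonical_match(matches: Sequence[MotifMatch]) -> MotifMatch:
    # leftmost, then shortest, then lexicographic anchors: deterministic
    return min(matches, key=lambda m: (m.start, m.end, m.anchor_positions))


def _domain_supported(anchors: Sequence[int], hits: Sequence[DomainHit]) -> bool:
    for h in hits:
        if h.domain_accession == PBP_GOBP_ACCESSION and not h.flagged:
            if any(h.start <= a <= h.end for a in anchors):
                return True
    return False


def classify(
    sequence: SequenceRecord,
    definitions: Sequence[ObpClassDefinition] | None = None,
    domain_hits: Mapping[str, Sequence[DomainHit]] | None = None,
) -> ObpAnnotation:
    """Assign one protein to a subclass (or ``None``) and map its cysteines.

    The label is the highest-precedence class whose pattern matches; of
    that class's matches the leftmost-then-shortest one is recorded.
    ``domain_supported`` is filled only when ``domain_hits`` is given:
    true iff an unflagged PBP/GOBP (PF01395) hit covers at least one
    anchor.  Domain support is advisory — plus-C OBPs routinely score
    poorly against PF01395 yet are genuine family members.
    """
    if definitions is None:
        definitions = builtin_class_definitions()
    matched: dict[str, list[MotifMatch]] = {}
    for d in sorted(definitions, key=lambda d: d.precedence_rank):
        hits = scan(d.pattern, sequence)
        if hits:
            matched[d.label] = hits
    ann = ObpAnnotation(sequence_id=sequence.id, label=None,
                        classes_matched=tuple(matched))
    if not matched:
        return ann
    winner = next(d for d in sorted(definitions, key=lambda d: d.precedence_rank)
                  if d.label in matched)
    best = _canonical_match(matched[winner.label])
    ann.label = winner.label
    ann.match = best
    ann.complete = True
    ann.cysteine_positions = dict(zip(winner.cysteine_names, best.anchor_positions))
    ann.spacing_vector = tuple(
        b - a - 1 for a, b in zip(best.anchor_positions, best.anchor_positions[1:])
    )
    if domain_hits is not None:
        ann.domain_supported = _domain_supported(
            best.anchor_positions, domain_hits.get(sequence.id, ())
        )
    return ann


def classify_set(
    sequences: Iterable[SequenceRecord],
    definitions: Sequence[ObpClassDefinition] | None = None,
    domain_hits: Mapping[str, Sequence[DomainHit]] | None = None,
) -> tuple[list[ObpAnnotation], Counter]:
    """Classify a collection; returns per-sequence annotations and a tally.

    The tally counts labels over classified sequences only (``none``
    results are excluded).  Deterministic under input permutation.
    """
    if definitions is None:
        definitions = builtin_class_definitions()
    annotations = [classify(s, definitions, domain_hits) for s in sequences]
    tally = Counter(a.label for a in annotations if a.label is not None)
    return annotations, tally


class ObpMotifClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based OBP subclass classifier with a scikit-learn interface.

    Samples are protein sequences (strings or :class:`SequenceRecord`);
    there is nothing to estimate, so :meth:`fit` only compiles the
    patterns and records the label set.  ``predict`` returns one of
    ``classic`` / ``atypical`` / ``plus_c`` / ``none`` per sequence.

    Parameters
    ----------
    precedence : tuple of str
        Class priority for sequences matching several patterns, most
        preferred first.
    """

    def __init__(self, precedence: Sequence[str] = DEFAULT_PRECEDENCE):
        self.precedence = tuple(precedence)

    def fit(self, X, y=None):
        self.definitions_ = builtin_class_definitions(self.precedence)
        self.classes_ = np.array(sorted(DEFAULT_PRECEDENCE) + ["none"], dtype=object)
        return self

    def _check_fitted(self):
        if not hasattr(self, "definitions_"):
            raise RuntimeError("ObpMotifClassifier instance is not fitted yet; call fit first")

    @staticmethod
    def _as_records(X) -> list[SequenceRecord]:
        records = []
        for i, x in enumerate(X):
            if isinstance(x, SequenceRecord):
                records.append(x)
            else:
                records.append(SequenceRecord(id=f"seq{i}", residues=str(x).upper()))
        return records

    def annotate(self, X, domain_hits=None) -> list[ObpAnnotation]:
        """Full per-sequence annotations (label, cysteine map, spacing)."""
        self._check_fitted()
        return [classify(r, self.definitions_, domain_hits) for r in self._as_records(X)]

    def predict(self, X):
        self._check_fitted()
        return np.array(
            [a.label if a.label is not None else "none" for a in self.annotate(X)],
            dtype=object,
        )

    def tally(self, X) -> Counter:
        ann = self.annotate(X)
        return Counter(a.label for a in ann if a.label is not None)
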