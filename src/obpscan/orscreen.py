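"""Odorant-receptor candidate screening.

ORs are seven-transmembrane proteins carrying the insect-specific 7tm_6
domain (Pfam PF02949).  The screen retains candidates with a qualifying
7tm_6 hit, removes exact-duplicate sequences (first occurrence kept),
and can report a Kyte–Doolittle transmembrane-segment count as an
advisory sanity check — the hydropathy heuristic never gates inclusion.

"100% sequence identity" is interpreted as full-length exact string
equality of the residues, not alignment-local identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import DomainHit, SequenceRecord

SEVEN_TM_ACCESSION = "PF02949"

# Kyte & Doolittle (1982) J Mol Biol 157:105 hydropathy scale
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass
class OrAnnotation:
    sequence_id: str
    domain_hit: DomainHit | None = None
    duplicate_of: str | None = None
    tm_segment_count: int | None = None
    partial: bool = False  # domain coverage below the configured fraction


def filter_by_domain(
    sequences: Sequence[SequenceRecord],
    domain_hits: Iterable[DomainHit],
    accession: str = SEVEN_TM_ACCESSION,
    evalue_threshold: float = 1e-3,
    partial_fraction: float = 0.5,
) -> list[OrAnnotation]:
    """Retain sequences with a qualifying domain hit.

    A sequence is retained iff it has at least one hit with the target
    accession and e-value <= threshold; the best (lowest e-value) such
    hit is recorded.  ``partial`` marks hits covering less than
    ``partial_fraction`` of the sequence — fragments stay in the set but
    flagged.  Hits naming unknown sequence ids are ignored with a
    warning.  Output order follows the input sequence order, so the
    retained set is independent of hit-file row order.
    """
    by_id = {s.id: s for s in sequences}
    best: dict[str, DomainHit] = {}
    for h in domain_hits:
        if h.sequence_id not in by_id:
            warnings.warn(
                f"domain hit references unknown sequence id {h.sequence_id!r}; ignored",
                stacklevel=2,
            )
            continue
        if h.domain_accession != accession or h.evalue > evalue_threshold:
            continue
        prev = best.get(h.sequence_id)
        if prev is None or (h.evalue, h.start, h.end) < (prev.evalue, prev.start, prev.end):
            best[h.sequence_id] = h
    retained = []
    for s in sequences:
        hit = best.get(s.id)
        if hit is None:
            continue
        coverage = hit.length() / len(s)
        retained.append(OrAnnotation(
            sequence_id=s.id, domain_hit=hit, partial=coverage < partial_fraction,
        ))
    return retained


def dedupe_identical(
    sequences: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], list[OrAnnotation]]:
    """Remove byte-identical duplicate sequences, keeping the first seen.

    Returns (retained records, one annotation per *input* record); a
    duplicate's annotation carries ``duplicate_of`` naming the retained
    record.  Idempotent and order-stable.
    """
    first_by_residues: dict[str, str] = {}
    retained: list[SequenceRecord] = []
    annotations: list[OrAnnotation] = []
    for s in sequences:
        keeper = first_by_residues.get(s.residues)
        if keeper is None:
            first_by_residues[s.residues] = s.id
            retained.append(s)
            annotations.append(OrAnnotation(sequence_id=s.id))
        else:
            annotations.append(OrAnnotation(sequence_id=s.id, duplicate_of=keeper))
    return retained, annotations


def count_tm_segments(
    sequence: SequenceRecord | str,
    window: int = 19,
    threshold: float = 1.6,
) -> int | None:
    """Advisory transmembrane-helix count from Kyte–Doolittle hydropathy.

    Slides a ``window``-residue window, marks centre positions whose
    mean hydropathy is >= ``threshold``, and counts maximal runs of
    marked centres, merging runs separated by fewer than ``window/2``
    unmarked centres (one helix rarely yields two disjoint peaks).
    Returns None (unset) for sequences shorter than the window.
    Residues outside the 20-letter scale score 0.
    """
    seq = sequence.residues if isinstance(sequence, SequenceRecord) else str(sequence).upper()
    n = len(seq)
    if n < window:
        return None
    values = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq]
    running = sum(values[:window])
    marked = [running / window >= threshold]
    for i in range(window, n):
        running += values[i] - values[i - window]
        marked.append(running / window >= threshold)

    runs: list[tuple[int, int]] = []  # [start, end] centre indices, inclusive
    for i, m in enumerate(marked):
        if not m:
            continue
        if runs and i - runs[-1][1] - 1 < window / 2:
            runs[-1] = (runs[-1][0], i)
        else:
            runs.append((i, i))
    return len(runs)
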