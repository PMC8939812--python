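"""Synthetic proteomes and gene sets with known ground truth.

Every pipeline stage is testable offline against data whose answer is
known by construction:

* OBP proteomes plant cysteine scaffolds whose gaps are drawn uniformly
  from one subclass's wildcard ranges, embedded in cysteine-free random
  flanks, so the planted anchors are the only cysteines and the planted
  class is unambiguous.  Classic-planted gap vectors that would also
  satisfy the (higher-precedence) atypical ranges are resampled, so
  ground-truth recovery is exact under the default precedence.
* Decoys either carry no cysteine at all or a six-cysteine scaffold
  whose C2–C3 gap is not 3, which violates the classic and atypical
  patterns (both demand exactly 3) and leaves too few cysteines for
  plus-C; each decoy is verified against all three patterns before it
  is emitted.
* OR sets pair receptor-like records with synthetic 7tm_6 (PF02949)
  domain hits covering at least half the sequence; duplicates are exact
  residue copies inheriting their source's domain status.
* Gene loci realize a requested cluster layout exactly: intra-cluster
  gaps at or below the clustering threshold, everything else separated
  by much more.

Randomness is drawn from ``random.Random(seed)`` with integer-only
structural decisions and residue sampling from fixed-order alphabets,
so outputs are byte-identical across platforms for a given seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

from .motifs import has_complete_motif, parse_pattern
from .obp import ATYPICAL_MOTIF, CLASSIC_MOTIF, PLUS_C_MOTIF
from .seqio import DomainHit, GeneLocus, SequenceRecord

#: fixed-order residue alphabets (C excluded from backgrounds so planted
#: cysteine scaffolds stay unambiguous)
NON_CYSTEINE = "ADEFGHIKLMNPQRSTVWY"
ALL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: per-class gap ranges between successive anchors, in pattern order
CLASS_GAP_RANGES: dict[str, tuple[tuple[int, int], ...]] = {
    "classic": ((15, 39), (3, 3), (21, 44), (7, 12), (8, 8)),
    "atypical": ((26, 27), (3, 3), (36, 38), (11, 15), (8, 8)),
    # C1..C4a..C6, then the conserved proline right after C6, then C6a
    "plus_c": ((8, 41), (3, 3), (39, 47), (17, 29), (9, 9), (8, 8), (0, 0), (9, 11)),
}
CLASS_ANCHOR_RESIDUES: dict[str, str] = {
    "classic": "CCCCCC",
    "atypical": "CCCCCC",
    "plus_c": "CCCCCCCPC",
}


@dataclass(frozen=True)
class PlantedTruth:
    record_id: str
    planted_class: str  # classic | atypical | plus_c | decoy | or_like | background | duplicate
    motif_start: int | None = None  # 1-based, None for decoys
    motif_end: int | None = None
    spacing_used: tuple[int, ...] = ()
    source_id: str | None = None  # duplicates: the copied record
    expected_retained: bool | None = None  # OR sets only


def _random_stretch(rng: random.Random, length: int, alphabet: str = NON_CYSTEINE) -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def _draw_gaps(rng: random.Random, label: str) -> tuple[int, ...]:
    while True:
        gaps = tuple(rng.randint(lo, hi) for lo, hi in CLASS_GAP_RANGES[label])
        if label == "classic":
            # avoid the atypical-compatible corner so the planted class
            # survives the plus_c > atypical > classic precedence
            g1, _, g3, g4, _ = gaps
            if 26 <= g1 <= 27 and 36 <= g3 <= 38 and 11 <= g4 <= 15:
                continue
        return gaps


def _scaffold(anchors: str, gaps: Sequence[int], rng: random.Random,
              adversarial: bool = False) -> str:
    parts = []
    for i, aa in enumerate(anchors):
        parts.append(aa)
        if i < len(gaps):
            gap = _random_stretch(rng, gaps[i])
            if adversarial and gaps[i] >= 3 and rng.random() < 0.5:
                k = rng.randrange(len(gap))
                gap = gap[:k] + "C" + gap[k + 1:]
            parts.append(gap)
    return "".join(parts)


def generate_obp_proteome(
    n_classic: int,
    n_atypical: int,
    n_plusc: int,
    n_decoys: int,
    seed: int,
    flank_range: tuple[int, int] = (5, 30),
    adversarial: bool = False,
) -> tuple[list[SequenceRecord], list[PlantedTruth]]:
    """Proteome of planted OBPs plus decoys, with a per-record truth table.

    ``adversarial`` sprinkles extra cysteines into the wildcard gaps —
    the planted match survives (wildcards match any residue) but the
    scanner sees additional candidate anchors; leave it off when exact
    class recovery is the point, since extra cysteines can create
    higher-precedence matches.
    """
    rng = random.Random(seed)
    records: list[SequenceRecord] = []
    truths: list[PlantedTruth] = []
    plan = (["classic"] * n_classic + ["atypical"] * n_atypical
            + ["plus_c"] * n_plusc + ["decoy"] * n_decoys)
    patterns = [parse_pattern(t, n) for n, t in
                (("classic", CLASSIC_MOTIF), ("atypical", ATYPICAL_MOTIF),
                 ("plus_c", PLUS_C_MOTIF))]
    for idx, label in enumerate(plan, start=1):
        rid = f"syn{idx:04d}"
        if label == "decoy":
            residues = _make_decoy(rng, patterns, flank_range)
            records.append(SequenceRecord(id=rid, residues=residues,
                                          description="decoy"))
            truths.append(PlantedTruth(record_id=rid, planted_class="decoy"))
            continue
        gaps = _draw_gaps(rng, label)
        core = _scaffold(CLASS_ANCHOR_RESIDUES[label], gaps, rng, adversarial)
        left = _random_stretch(rng, rng.randint(*flank_range))
        right = _random_stretch(rng, rng.randint(*flank_range))
        residues = left + core + right
        records.append(SequenceRecord(id=rid, residues=residues,
                                      description=f"planted {label}"))
        truths.append(PlantedTruth(
            record_id=rid, planted_class=label,
            motif_start=len(left) + 1, motif_end=len(left) + len(core),
            spacing_used=gaps,
        ))
    return records, truths


def _make_decoy(rng: random.Random, patterns, flank_range) -> str:
    for _ in range(64):
        if rng.random() < 0.5:
            residues = _random_stretch(rng, rng.randint(80, 260))
        else:
            # six cysteines with a C2-C3 gap of 4-6: no class allows it
            gaps = (rng.randint(15, 39), rng.randint(4, 6), rng.randint(21, 44),
                    rng.randint(7, 12), 8)
            core = _scaffold("CCCCCC", gaps, rng)
            left = _random_stretch(rng, rng.randint(*flank_range))
            right = _random_stretch(rng, rng.randint(*flank_range))
            residues = left + core + right
        if not has_complete_motif(residues, patterns):
            return residues
    raise RuntimeError("could not construct a motif-free decoy")  # pragma: no cover


def generate_or_set(
    n_or: int,
    n_duplicates: int,
    seed: int,
    n_background: int = 0,
    length_range: tuple[int, int] = (360, 440),
) -> tuple[list[SequenceRecord], list[DomainHit], list[PlantedTruth]]:
    """Receptor-like records with synthetic 7tm_6 hits, plus duplicates.

    ``n_background`` adds records without any domain hit (screen should
    drop them).  Duplicates copy a randomly chosen earlier record,
    inheriting its domain-hit status under a fresh id, so duplicates of
    non-retained records are themselves not retained (the screen filters
    before it dedupes).
    """
    rng = random.Random(seed)
    records: list[SequenceRecord] = []
    hits: list[DomainHit] = []
    truths: list[PlantedTruth] = []
    has_domain: dict[str, bool] = {}
    for i in range(1, n_or + 1):
        rid = f"synOR{i:03d}"
        length = rng.randint(*length_range)
        records.append(SequenceRecord(id=rid, residues=_random_stretch(rng, length, ALL_RESIDUES),
                                      description="receptor-like"))
        start = rng.randint(1, max(1, length // 5))
        end = min(length, start + int(0.55 * length))
        hits.append(DomainHit(sequence_id=rid, domain_name="7tm_6",
                              domain_accession="PF02949", start=start, end=end,
                              evalue=10.0 ** -rng.randint(20, 60)))
        has_domain[rid] = True
        truths.append(PlantedTruth(record_id=rid, planted_class="or_like",
                                   expected_retained=True))
    for i in range(1, n_background + 1):
        rid = f"synBG{i:03d}"
        length = rng.randint(*length_range)
        records.append(SequenceRecord(id=rid, residues=_random_stretch(rng, length, ALL_RESIDUES),
                                      description="background"))
        has_domain[rid] = False
        truths.append(PlantedTruth(record_id=rid, planted_class="background",
                                   expected_retained=False))
    sources = list(records)
    for i in range(1, n_duplicates + 1):
        if not sources:
            raise ValueError("cannot plant duplicates into an empty record set")
        src = sources[rng.randrange(len(sources))]
        rid = f"synDUP{i:03d}"
        records.append(SequenceRecord(id=rid, residues=src.residues,
                                      description=f"duplicate of {src.id}"))
        if has_domain[src.id]:
            base = next(h for h in hits if h.sequence_id == src.id)
            hits.append(DomainHit(sequence_id=rid, domain_name=base.domain_name,
                                  domain_accession=base.domain_accession,
                                  start=base.start, end=base.end, evalue=base.evalue))
        truths.append(PlantedTruth(record_id=rid, planted_class="duplicate",
                                   source_id=src.id, expected_retained=False))
    return records, hits, truths


def generate_gene_loci(
    entries: Sequence[str],
    cluster_spec: Sequence[tuple[str, int, int]],
    chromosome_set: Sequence[str] = ("X", "2", "3"),
    seed: int = 0,
    scatter_gap_bp: int = 2_000_000,
    gene_length_range: tuple[int, int] = (1_000, 5_000),
) -> list[GeneLocus]:
    """Loci realizing exactly the requested cluster layout.

    ``cluster_spec`` lists (chromosome, member_count, intra_gap_bp)
    triples; clustered genes sit ``intra_gap_bp`` apart, every other
    adjacency (cluster-to-cluster, scattered genes) is separated by
    ``scatter_gap_bp``, which must exceed the clustering threshold used
    downstream for the layout to be recovered exactly.
    """
    needed = sum(count for _, count, _ in cluster_spec)
    if needed > len(entries):
        raise ValueError(f"cluster spec requests {needed} genes but only "
                         f"{len(entries)} entries were given")
    rng = random.Random(seed)
    ids = list(entries)
    loci: list[GeneLocus] = []
    cursor: dict[str, int] = {c: 1 for c in chromosome_set}

    def place(chrom: str, gap: int) -> tuple[int, int]:
        start = cursor.get(chrom, 1) + gap
        length = rng.randint(*gene_length_range)
        cursor[chrom] = start + length
        return start, start + length - 1

    i = 0
    for chrom, count, intra_gap in cluster_spec:
        for k in range(count):
            gap = scatter_gap_bp if k == 0 else intra_gap
            start, end = place(chrom, gap)
            loci.append(GeneLocus(sequence_id=ids[i], chromosome=chrom,
                                  start=start, end=end,
                                  strand="+-"[rng.randint(0, 1)]))
            i += 1
    for rid in ids[i:]:
        chrom = chromosome_set[rng.randrange(len(chromosome_set))]
        start, end = place(chrom, scatter_gap_bp)
        loci.append(GeneLocus(sequence_id=rid, chromosome=chrom,
                              start=start, end=end,
                              strand="+-"[rng.randint(0, 1)]))
    return loci


def verify_planted_spacing(record: SequenceRecord, truth: PlantedTruth) -> bool:
    """Re-measure the planted cysteine gaps from the emitted sequence."""
    if truth.planted_class not in CLASS_GAP_RANGES:
        return True
    anchors = CLASS_ANCHOR_RESIDUES[truth.planted_class]
    pos = truth.motif_start
    measured = []
    core = record.residues[truth.motif_start - 1:truth.motif_end]
    idx = 0
    positions = []
    for i, aa in enumerate(anchors):
        if core[idx] != aa:
            return False
        positions.append(idx)
        if i < len(truth.spacing_used):
            idx += truth.spacing_used[i] + 1
    measured = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
    return measured == truth.spacing_used and pos is not None
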