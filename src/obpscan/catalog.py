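"""Catalog building: positional naming, chromosome tallies, gene
clusters and ORF finding.

Family members are named positionally — AsteOBP1..N, AsteOR1..N —
walking the chromosomes in the karyotype order X < 2 < 3, then start
coordinate; records without a placed locus are numbered last.  The
label "1" is accepted as a synonym rank for the X chromosome, as some
assemblies number the sex chromosome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .seqio import CatalogEntry, GeneLocus, SequenceRecord

UNPLACED_LABELS = {"unplaced", "unknown", ""}

#: karyotype order used for positional naming
CHROMOSOME_RANKS: dict[str, int] = {"X": 0, "1": 0, "2": 1, "3": 2}
UNPLACED_RANK = 3


def chromosome_rank(label: str | None) -> int:
    if label is None or label.strip().lower() in UNPLACED_LABELS:
        return UNPLACED_RANK
    return CHROMOSOME_RANKS.get(label.strip(), UNPLACED_RANK)


def assign_names(
    annotations: Sequence,
    loci: Mapping[str, GeneLocus],
    prefix: str = "AsteOBP",
) -> list[CatalogEntry]:
    """Name family members 1..N by chromosome rank, then locus start.

    ``annotations`` need only expose ``sequence_id`` (plus optionally
    ``label`` for the class column).  Records absent from ``loci`` are
    treated as unplaced and numbered after all placed ones (ties broken
    by sequence id, so naming is invariant to input order).  Two records
    sharing one locus is an error.
    """
    seen_loci: dict[tuple[str, int, int], str] = {}
    rows = []
    for ann in annotations:
        sid = getattr(ann, "sequence_id", None) or getattr(ann, "id", None) or str(ann)
        locus = loci.get(sid)
        if locus is not None:
            key = (locus.chromosome, locus.start, locus.end)
            if key in seen_loci:
                raise ValueError(
                    f"records {seen_loci[key]!r} and {sid!r} share locus "
                    f"{locus.chromosome}:{locus.start}-{locus.end}"
                )
            seen_loci[key] = sid
        rows.append((ann, sid, locus))

    def sort_key(row):
        _, sid, locus = row
        if locus is None:
            return (UNPLACED_RANK, 0, sid)
        return (chromosome_rank(locus.chromosome), locus.start, sid)

    entries = []
    for number, (ann, sid, locus) in enumerate(sorted(rows, key=sort_key), start=1):
        label = getattr(ann, "label", None)
        entries.append(CatalogEntry(
            name=f"{prefix}{number}",
            source_id=sid,
            class_label=label,
            chromosome=locus.chromosome if locus is not None else "Unknown",
            locus=locus,
        ))
    return entries


def chromosome_tally(entries: Iterable[CatalogEntry]) -> Counter:
    """Exact member counts per chromosome label."""
    return Counter(e.chromosome for e in entries)


@dataclass(frozen=True)
class GeneCluster:
    chromosome: str
    member_names: tuple[str, ...]
    span_bp: int  # first member start to last member end

    def __len__(self) -> int:
        return len(self.member_names)


def detect_clusters(loci: Iterable[GeneLocus], max_gap_bp: int = 100_000) -> list[GeneCluster]:
    """Single-linkage chaining of genes along each chromosome.

    Consecutive genes (by start coordinate) whose inter-gene gap — next
    start minus previous end — is <= ``max_gap_bp`` are chained; chains
    with at least two members are reported, coordinate-sorted.  Input
    order does not matter.
    """
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom, key=lambda c: (chromosome_rank(c), c)):
        members = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.sequence_id))
        chain: list[GeneLocus] = [members[0]]
        for locus in members[1:]:
            gap = locus.start - chain[-1].end
            if gap <= max_gap_bp:
                chain.append(locus)
            else:
                if len(chain) >= 2:
                    clusters.append(_as_cluster(chrom, chain))
                chain = [locus]
        if len(chain) >= 2:
            clusters.append(_as_cluster(chrom, chain))
    return clusters


def _as_cluster(chrom: str, chain: list[GeneLocus]) -> GeneCluster:
    return GeneCluster(
        chromosome=chrom,
        member_names=tuple(l.sequence_id for l in chain),
        span_bp=chain[-1].end - chain[0].start + 1,
    )


@dataclass(frozen=True)
class Orf:
    """One open reading frame; coordinates are 1-based on the forward strand.

    ``frame`` is 1..3 on the plus strand, -1..-3 on the minus strand;
    ``length_nt`` includes the stop codon, ``peptide`` does not.
    """

    frame: int
    start: int
    end: int
    strand: str
    peptide: str
    longest: bool = False

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


_STOPS = {"TAA", "TAG", "TGA"}


def _orfs_in_frame(seq: str, offset: int) -> list[tuple[int, int, str]]:
    """(0-based start, 0-based end inclusive, peptide) for one frame."""
    out = []
    codons = [(i, seq[i:i + 3]) for i in range(offset, len(seq) - 2, 3)]
    open_starts: list[int] = []
    for i, codon in codons:
        if codon == "ATG":
            open_starts.append(i)
        if codon in _STOPS and open_starts:
            for s in open_starts:
                nt = seq[s:i + 3]
                peptide = str(Seq(nt[:-3]).translate())
                out.append((s, i + 2, peptide))
            open_starts = []
    return out


def find_orfs(
    sequence: SequenceRecord | str,
    min_length_nt: int = 150,
    both_strands: bool = True,
    allow_open_ended: bool = False,
) -> list[Orf]:
    """All ATG-to-stop spans of at least ``min_length_nt`` nucleotides.

    Standard genetic code; every in-frame ATG upstream of a stop opens
    its own ORF (nested starts included).  N inside a codon translates
    as X.  With ``allow_open_ended``, ATGs never reaching a stop are
    reported running to the end of their frame.  Minus-strand ORFs are
    reported in forward-strand coordinates with start < end.  The
    longest ORF (ties: leftmost) is flagged.
    """
    seq = sequence.residues if isinstance(sequence, SequenceRecord) else str(sequence).upper()
    n = len(seq)
    orfs: list[Orf] = []

    def emit(strand: str, frame: int, work: str):
        for offset in range(3):
            found = _orfs_in_frame(work, offset)
            if allow_open_ended:
                found += _open_ended(work, offset)
            for s0, e0, pep in found:
                if e0 - s0 + 1 < min_length_nt:
                    continue
                if strand == "+":
                    start, end = s0 + 1, e0 + 1
                else:
                    start, end = n - e0, n - s0
                orfs.append(Orf(frame=(offset + 1) * (1 if strand == "+" else -1),
                                start=start, end=end, strand=strand, peptide=pep))

    emit("+", 0, seq)
    if both_strands:
        emit("-", 0, str(Seq(seq).reverse_complement()))

    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    if orfs:
        best = max(range(len(orfs)), key=lambda i: (orfs[i].length_nt, -orfs[i].start))
        orfs[best] = replace(orfs[best], longest=True)
    return orfs


def _open_ended(seq: str, offset: int) -> list[tuple[int, int, str]]:
    out = []
    open_starts: list[int] = []
    last_full = None
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        last_full = i
        if codon == "ATG":
            open_starts.append(i)
        if codon in _STOPS:
            open_starts = []
    if last_full is None:
        return out
    end = last_full + 2
    for s in open_starts:
        nt = seq[s:end + 1]
        out.append((s, end, str(Seq(nt).translate())))
    return out


def plot_chromosome_map(entries: Sequence[CatalogEntry], path,
                        title: str = "Chromosomal gene positions") -> None:
    """Cosmetic ideogram-style scatter of catalog entries along chromosomes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    placed = [e for e in entries if e.locus is not None]
    chroms = sorted({e.locus.chromosome for e in placed},
                    key=lambda c: (chromosome_rank(c), c))
    fig, ax = plt.subplots(figsize=(6, 1 + len(chroms)))
    for y, chrom in enumerate(chroms):
        members = [e for e in placed if e.locus.chromosome == chrom]
        xs = [e.locus.start for e in members]
        ax.hlines(y, 0, max(xs) * 1.05, color="lightgrey", lw=6)
        ax.plot(xs, [y] * len(xs), "|", markersize=18, color="crimson")
        for e in members:
            ax.annotate(e.name, (e.locus.start, y + 0.12), fontsize=6,
                        rotation=45, ha="left")
    ax.set_yticks(range(len(chroms)), chroms)
    ax.set_xlabel("position (bp)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
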