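"""Readers and writers for every external format the pipeline touches.

No science lives here: FASTA in/out (via Biopython), 12-column BLAST
tabular hits, a simple 6-column domain-hit TSV standing in for Pfam
output, GFF3 gene loci, and the output catalog TSV.

All coordinates are 1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY" + "XBZUO")
DNA_ALPHABET = set("ACGTN")

#: columns of the standard BLAST tabular (-outfmt 6) dialect
BLAST_TAB_COLUMNS = (
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bitscore",
)


class SeqIOError(ValueError):
    """Raised for malformed input files (message names file, record, offset)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein or nucleotide sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` is the remainder (possibly empty).  Residues are
    upper-cased on ingest and validated against the declared alphabet.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str = "protein"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HitRecord:
    """One line of 12-column BLAST tabular output."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    extra: tuple = ()  # remaining standard columns, kept opaquely

    def __post_init__(self):
        if self.evalue < 0:
            raise SeqIOError(f"negative e-value for hit {self.query_id}/{self.subject_id}")
        if not 0 <= self.percent_identity <= 100:
            raise SeqIOError(
                f"percent identity {self.percent_identity} outside [0,100] "
                f"for hit {self.query_id}/{self.subject_id}"
            )


@dataclass(frozen=True)
class DomainHit:
    """One domain annotation on a protein (1-based inclusive coordinates)."""

    sequence_id: str
    domain_name: str
    domain_accession: str
    start: int
    end: int
    evalue: float
    flagged: bool = False  # e-value above the configured threshold

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise SeqIOError(
                f"invalid domain coordinates {self.start}..{self.end} on {self.sequence_id}"
            )
        if self.evalue < 0:
            raise SeqIOError(f"negative e-value for domain hit on {self.sequence_id}")

    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneLocus:
    """Chromosomal position of one gene (1-based bp, inclusive)."""

    sequence_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self):
        if self.start > self.end:
            raise SeqIOError(
                f"locus start {self.start} > end {self.end} for {self.sequence_id}"
            )
        if not self.chromosome:
            raise SeqIOError(f"empty chromosome label for {self.sequence_id}")


@dataclass
class CatalogEntry:
    """One output row of the family catalog (Table-style schema)."""

    name: str
    source_id: str
    gene_id: str | None = None
    class_label: str | None = None  # OBP subclass; ORs carry None
    chromosome: str = "unplaced"
    mw_da: float | None = None
    pi: float | None = None
    locus: GeneLocus | None = field(default=None, repr=False)


def read_fasta(path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Order is preserved, multi-line bodies are concatenated, gaps and
    whitespace are stripped, and residues are upper-cased.  Duplicate ids
    and characters outside the declared alphabet are hard errors; an
    empty file yields an empty list with a warning.
    """
    if alphabet not in ("protein", "dna"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else DNA_ALPHABET
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).replace("-", "").replace(".", "").upper()
        residues = "".join(residues.split())
        if not residues:
            raise SeqIOError(f"{path}: record {rec.id!r} has an empty sequence body")
        for pos, ch in enumerate(residues, start=1):
            if ch not in allowed:
                raise SeqIOError(
                    f"{path}: illegal {alphabet} character {ch!r} "
                    f"in record {rec.id!r} at position {pos}"
                )
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=residues,
                                      description=desc, alphabet=alphabet))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as FASTA with fixed line width (round-trips read_fasta)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_blast_tab(path) -> list[HitRecord]:
    """Parse standard 12-column BLAST tabular output.

    Lines starting with ``#`` are skipped; extra trailing columns are
    tolerated and ignored; fewer than 12 columns is an error naming the
    line number.
    """
    path = Path(path)
    hits: list[HitRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise SeqIOError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hits.append(HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    extra=tuple(fields[4:10]),
                ))
            except ValueError as exc:
                if isinstance(exc, SeqIOError):
                    raise
                raise SeqIOError(f"{path}:{lineno}: {exc}") from exc
    return hits


def read_domain_hits(path, evalue_threshold: float = 1e-3) -> list[DomainHit]:
    """Parse the 6-column domain-hit TSV.

    Columns: sequence_id, domain_name, domain_accession, start, end,
    evalue.  Rows with e-value above ``evalue_threshold`` are *flagged*,
    not dropped, so downstream stages can report why a candidate failed.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise SeqIOError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
                )
            try:
                start, end, evalue = int(fields[3]), int(fields[4]), float(fields[5])
            except ValueError as exc:
                raise SeqIOError(f"{path}:{lineno}: non-numeric coordinate or e-value") from exc
            try:
                hits.append(DomainHit(
                    sequence_id=fields[0], domain_name=fields[1],
                    domain_accession=fields[2], start=start, end=end,
                    evalue=evalue, flagged=evalue > evalue_threshold,
                ))
            except SeqIOError as exc:
                raise SeqIOError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path) -> None:
    with Path(path).open("w") as fh:
        for h in hits:
            fh.write(f"{h.sequence_id}\t{h.domain_name}\t{h.domain_accession}"
                     f"\t{h.start}\t{h.end}\t{h.evalue:g}\n")


def read_gff_loci(path, feature_type: str = "gene", id_attribute: str = "ID") -> list[GeneLocus]:
    """Extract :class:`GeneLocus` records for one feature type from GFF3.

    ``sequence_id`` is taken from ``id_attribute`` (default ``ID``); a
    matching feature without that attribute is an error naming the line.
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    loci: list[GeneLocus] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype != feature_type:
            continue
        values = feat.attributes.get(id_attribute)
        if not values:
            raise SeqIOError(
                f"{path}: feature at {feat.seqid}:{feat.start}-{feat.end} "
                f"lacks attribute {id_attribute!r}"
            )
        strand = feat.strand if feat.strand in "+-" else "unknown"
        loci.append(GeneLocus(sequence_id=values[0], chromosome=feat.seqid,
                              start=feat.start, end=feat.end, strand=strand))
    return loci


def write_gff3(loci: Iterable[GeneLocus], path, feature_type: str = "gene",
               source: str = "obpscan") -> None:
    """Write gene loci as minimal GFF3 (round-trips read_gff_loci)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for l in loci:
            strand = l.strand if l.strand in "+-" else "."
            fh.write(f"{l.chromosome}\t{source}\t{feature_type}\t{l.start}\t{l.end}"
                     f"\t.\t{strand}\t.\tID={l.sequence_id}\n")


CATALOG_COLUMNS = ("name", "source_id", "gene_id", "class", "chromosome", "mw_da", "pi")


def write_catalog(entries: Sequence[CatalogEntry], path,
                  style: str = "obp") -> None:
    """Write the catalog TSV (header + one row per entry, sorted by name).

    ``style`` controls display rounding: ``obp`` prints MW as integer Da
    and pI to 1 decimal; ``or`` prints MW in kDa to 3 decimals and pI to
    2 decimals.  Full precision stays internal to :class:`CatalogEntry`.
    """
    from .physchem import format_mw, format_pi

    def _name_key(entry: CatalogEntry):
        # numeric suffix sort so e.g. AsteOBP10 follows AsteOBP9
        prefix = entry.name.rstrip("0123456789")
        suffix = entry.name[len(prefix):]
        return (prefix, int(suffix) if suffix else 0)

    with Path(path).open("w") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for e in sorted(entries, key=_name_key):
            mw = "" if e.mw_da is None else format_mw(e.mw_da, style)
            pi = "" if e.pi is None else format_pi(e.pi, style)
            fh.write("\t".join([
                e.name, e.source_id, e.gene_id or "",
                e.class_label or "", e.chromosome, mw, pi,
            ]) + "\n")
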