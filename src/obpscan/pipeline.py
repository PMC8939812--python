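"""End-to-end identify → classify → profile → name pipelines.

The OBP flow: optional BLAST-hit prefilter → motif scan and subclass
call → optional PBP/GOBP domain annotation → molecular weight and pI →
positional naming → catalog TSV plus a stage-count run report.

The OR flow: 7tm_6 domain filter → exact-duplicate removal → physchem →
positional naming → catalog TSV plus report.

Re-running with the same config and inputs is byte-identical: every
iteration order is fixed and the seed only affects synthetic
generation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import catalog as cat
from . import orscreen, physchem, seqio
from .obp import DEFAULT_PRECEDENCE, ObpMotifClassifier

logger = logging.getLogger("obpscan")


@dataclass
class PipelineConfig:
    """Effective settings of one pipeline run; YAML round-trippable."""

    fasta: str = ""
    blast_hits: str | None = None
    domain_hits: str | None = None
    gff: str | None = None
    out_dir: str = "."
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
    domain_evalue_threshold: float = 1e-3
    blast_evalue_threshold: float | None = None
    blast_identity_threshold: float | None = None
    dedupe: bool = True
    cluster_max_gap_bp: int = 100_000
    orf_min_length_nt: int = 150
    display_style: str = "obp"
    name_prefix: str = "AsteOBP"
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["precedence"] = list(self.precedence)
        with Path(path).open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if "precedence" in data:
            data["precedence"] = tuple(data["precedence"])
        return cls(**data)


@dataclass
class RunReport:
    """Stage-by-stage record counts; counts never increase downstream."""

    n_input: int = 0
    n_prefilter_retained: int = 0
    n_motif_complete: int = 0
    per_class: dict = field(default_factory=dict)
    n_domain_retained: int = 0
    n_dedupe_removed: int = 0
    n_catalog: int = 0
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _load_loci(config: PipelineConfig) -> dict[str, seqio.GeneLocus]:
    if not config.gff:
        return {}
    return {l.sequence_id: l for l in seqio.read_gff_loci(config.gff)}


def _prefilter(records, config: PipelineConfig, report: RunReport):
    if not config.blast_hits:
        report.n_prefilter_retained = len(records)
        return records
    hits = seqio.read_blast_tab(config.blast_hits)
    keep = set()
    for h in hits:
        if (config.blast_evalue_threshold is not None
                and h.evalue > config.blast_evalue_threshold):
            continue
        if (config.blast_identity_threshold is not None
                and h.percent_identity < config.blast_identity_threshold):
            continue
        keep.add(h.subject_id)
    retained = [r for r in records if r.id in keep]
    report.n_prefilter_retained = len(retained)
    logger.info("BLAST prefilter: %d of %d records retained", len(retained), len(records))
    return retained


def run_obp_pipeline(config: PipelineConfig) -> tuple[list[seqio.CatalogEntry], RunReport]:
    """Classify a protein set into OBP subclasses and emit the catalog."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    records = seqio.read_fasta(config.fasta, alphabet="protein")
    report.n_input = len(records)
    records = _prefilter(records, config, report)

    domain_hits = None
    if config.domain_hits:
        parsed = seqio.read_domain_hits(config.domain_hits, config.domain_evalue_threshold)
        domain_hits = {}
        for h in parsed:
            domain_hits.setdefault(h.sequence_id, []).append(h)

    clf = ObpMotifClassifier(precedence=config.precedence).fit([])
    annotations = clf.annotate(records, domain_hits=domain_hits)
    kept = [a for a in annotations if a.label is not None]
    report.n_motif_complete = len(kept)
    report.per_class = dict(sorted(Counter(a.label for a in kept).items()))
    logger.info("motif classification: %d of %d complete (%s)",
                len(kept), len(records), report.per_class)

    loci = _load_loci(config)
    entries = cat.assign_names(kept, loci, prefix=config.name_prefix)
    by_id = {r.id: r for r in records}
    ann_by_id = {a.sequence_id: a for a in kept}
    for e in entries:
        prof = physchem.profile(by_id[e.source_id])
        e.mw_da, e.pi = prof.mw_da, prof.pi
        ann = ann_by_id[e.source_id]
        if ann.domain_supported is False:
            report.warnings.append(
                f"{e.name} ({e.source_id}): no PBP/GOBP domain support at the motif anchors"
            )
    report.n_catalog = len(entries)

    seqio.write_catalog(entries, out_dir / "obp_catalog.tsv", style=config.display_style)
    config.to_yaml(out_dir / "effective_config.yaml")
    _write_report(report, out_dir / "run_report.yaml")
    return entries, report


def run_or_pipeline(config: PipelineConfig) -> tuple[list[seqio.CatalogEntry], RunReport]:
    """Screen a protein set for 7tm_6 receptors and emit the catalog."""
    if not config.domain_hits:
        raise ValueError("the OR pipeline requires a domain-hit table (7tm_6/PF02949)")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    records = seqio.read_fasta(config.fasta, alphabet="protein")
    report.n_input = len(records)
    records = _prefilter(records, config, report)

    hits = seqio.read_domain_hits(config.domain_hits, config.domain_evalue_threshold)
    screened = orscreen.filter_by_domain(
        records, hits, evalue_threshold=config.domain_evalue_threshold)
    screened_ids = {a.sequence_id for a in screened}
    retained = [r for r in records if r.id in screened_ids]
    report.n_domain_retained = len(retained)
    if not retained:
        report.warnings.append("no sequence carried a qualifying 7tm_6 (PF02949) hit")

    if config.dedupe:
        retained, dedupe_ann = orscreen.dedupe_identical(retained)
        report.n_dedupe_removed = sum(1 for a in dedupe_ann if a.duplicate_of)
    for a in screened:
        if a.partial:
            report.warnings.append(
                f"{a.sequence_id}: 7tm_6 hit covers under half the sequence (fragment?)"
            )

    loci = _load_loci(config)
    entries = cat.assign_names(retained, loci,
                               prefix=config.name_prefix if config.name_prefix != "AsteOBP"
                               else "AsteOR")
    by_id = {r.id: r for r in records}
    for e in entries:
        prof = physchem.profile(by_id[e.source_id])
        e.mw_da, e.pi = prof.mw_da, prof.pi
    report.n_catalog = len(entries)

    style = "or" if config.display_style == "obp" else config.display_style
    seqio.write_catalog(entries, out_dir / "or_catalog.tsv", style=style)
    config.to_yaml(out_dir / "effective_config.yaml")
    _write_report(report, out_dir / "run_report.yaml")
    return entries, report


def _write_report(report: RunReport, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(report.to_dict(), fh, sort_keys=True)
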