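"""Packaged reference catalogs for *Anopheles stephensi* chemosensory genes.

Two TSVs ship with the package, transcribed from the published
genome-wide annotation of the Indian-strain *An. stephensi* assembly
(RefSeq GCF_013141755.1): the 44 odorant-binding proteins (positional
name, RefSeq protein accession, gene ID, subclass, chromosome, reported
molecular weight in Da and pI) and the 45 odorant receptors (same
schema without a subclass, molecular weight reported in kDa).

These are *reported* values for cross-checking catalog bookkeeping
(chromosome tallies, class composition, display conventions); the
underlying protein sequences are not redistributed here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("obpscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chromosome": str})


def load_reference_obp_catalog() -> pd.DataFrame:
    """The 44 AsteOBPs: name, accession, gene_id, class, chromosome, MW (Da), pI."""
    return _load("aste_obp_catalog.tsv")


def load_reference_or_catalog() -> pd.DataFrame:
    """The 45 AsteORs: name, accession, gene_id, chromosome, MW (kDa), pI."""
    return _load("aste_or_catalog.tsv")
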