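from __future__ import annotations

import random

import pytest

from obpscan.obp import builtin_class_definitions
from obpscan.seqio import SequenceRecord


@pytest.fixture(scope="session")
def class_definitions():
    return builtin_class_definitions()


@pytest.fixture(scope="session")
def patterns(class_definitions):
    return [d.pattern for d in class_definitions]


@pytest.fixture
def rng():
    return random.Random(20240917)


def make_classic(gaps=(15, 3, 21, 7, 8), flank=("", "")) -> str:
    """Cysteine scaffold with the given gaps, alanine filler."""
    core = "C"
    for g in gaps:
        core += "A" * g + "C"
    return flank[0] + core + flank[1]


@pytest.fixture
def minimal_classic() -> SequenceRecord:
    return SequenceRecord(id="minimal", residues=make_classic())


def write_lines(path, text: str):
    path.write_text(text)
    return path
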