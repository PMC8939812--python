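"""Pattern parsing and exhaustive motif scanning."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from obpscan.motifs import (
    PatternError, parse_pattern, scan, has_complete_motif,
)
from obpscan.obp import CLASSIC_MOTIF, PLUS_C_MOTIF

from .conftest import make_classic
from .oracles import (
    enumerate_anchor_matches, random_pattern, substring_spans,
)


class TestParse:
    def test_classic_motif_structure(self):
        p = parse_pattern(CLASSIC_MOTIF, "classic")
        assert len(p.elements) == 11
        assert p.literal_residues == ("C",) * 6
        runs = [(e.repeat_min, e.repeat_max) for e in p.elements if e.kind == "wildcard"]
        assert runs == [(15, 39), (3, 3), (21, 44), (7, 12), (8, 8)]
        assert (p.min_span, p.max_span) == (60, 112)

    def test_plus_c_motif_structure(self):
        p = parse_pattern(PLUS_C_MOTIF, "plus_c")
        assert p.literal_residues == ("C",) * 7 + ("P", "C")
        runs = [(e.repeat_min, e.repeat_max) for e in p.elements if e.kind == "wildcard"]
        assert runs == [(8, 41), (3, 3), (39, 47), (17, 29), (9, 9), (8, 8), (9, 11)]

    @pytest.mark.parametrize("text,n_elements", [
        ("C", 1),
        ("CxC", 3),
        ("Cx(3)C", 3),
        ("C-x(2,4)-C", 3),  # PROSITE dashes tolerated
    ])
    def test_small_patterns(self, text, n_elements):
        p = parse_pattern(text)
        assert len(p.elements) == n_elements

    @pytest.mark.parametrize("bad", ["Cx(5,3)C", "Cx(3C", "C?(3)", "", "Cx(a)C"])
    def test_malformed_patterns_raise(self, bad):
        with pytest.raises(PatternError):
            parse_pattern(bad)

    def test_round_trip_serialization(self):
        for text in (CLASSIC_MOTIF, PLUS_C_MOTIF, "CxCx(3)P"):
            assert parse_pattern(text).to_text() == text


class TestScan:
    def test_minimal_classic_single_match(self, minimal_classic):
        p = parse_pattern(CLASSIC_MOTIF, "classic")
        matches = scan(p, minimal_classic)
        assert len(matches) == 1
        m = matches[0]
        assert (m.start, m.end) == (1, 60)
        assert m.anchor_positions == (1, 17, 21, 43, 51, 60)

    def test_no_anchor_residue_no_match(self, patterns):
        for p in patterns:
            assert scan(p, "A" * 200) == []

    def test_overlapping_matches_enumerated(self):
        p = parse_pattern("Cx(1,2)C", "p")
        spans = {(m.start, m.end) for m in scan(p, "CACAC")}
        assert spans == {(1, 3), (3, 5)}

    def test_exact_gap_is_exact(self):
        # C2-C3 spacing of 4 instead of 3 breaks the classic frame
        seq = make_classic(gaps=(15, 4, 21, 7, 8))
        assert not has_complete_motif(seq, [parse_pattern(CLASSIC_MOTIF, "classic")])

    def test_has_complete_motif(self, minimal_classic, patterns):
        assert has_complete_motif(minimal_classic, patterns)
        assert not has_complete_motif("A" * 120, patterns)

    def test_literal_anchor_rejects_unknown_residue(self):
        p = parse_pattern("CxC", "p")
        assert scan(p, "XAC") == []        # X cannot supply an anchor
        assert scan(p, "CXC")              # but wildcards accept X

    def test_wildcard_matches_cysteine(self):
        # extra C inside the gap: still exactly one (start,end) span,
        # plus the extra anchor assignments the scanner must enumerate
        p = parse_pattern("Cx(3)C", "p")
        matches = scan(p, "ACACCC")  # gap region holds two cysteines
        assert {(m.start, m.end) for m in matches} == {(2, 6)}

    def test_matches_sorted_and_within_span_bounds(self, rng, patterns):
        for _ in range(20):
            seq = "".join(rng.choice("ACP") for _ in range(rng.randint(10, 80)))
            p = parse_pattern(random_pattern(rng), "r")
            ms = scan(p, seq)
            assert ms == sorted(ms, key=lambda m: (m.start, m.end, m.anchor_positions))
            for m in ms:
                assert p.min_span <= m.span <= p.max_span


class TestOracleEquivalence:
    def test_spans_match_regex_oracle_random(self, rng):
        """Scanner spans equal brute-force substring matching."""
        for _ in range(300):
            seq = "".join(rng.choice("ACDP") for _ in range(rng.randint(5, 60)))
            p = parse_pattern(random_pattern(rng), "r")
            got = {(m.start, m.end) for m in scan(p, seq)}
            assert got == substring_spans(p, seq), (p.source_text, seq)

    def test_anchor_assignments_match_naive_enumeration(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice("ACP") for _ in range(rng.randint(4, 25)))
            p = parse_pattern(random_pattern(rng, max_literals=3, max_gap=4), "r")
            got = {(m.start, m.end, m.anchor_positions) for m in scan(p, seq)}
            assert got == enumerate_anchor_matches(p, seq)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACP", min_size=3, max_size=40),
           seed=st.integers(0, 10_000))
    def test_spans_match_regex_oracle_hypothesis(self, seq, seed):
        p = parse_pattern(random_pattern(random.Random(seed)), "r")
        got = {(m.start, m.end) for m in scan(p, seq)}
        assert got == substring_spans(p, seq)


class TestMonotonicity:
    def test_widening_wildcards_never_removes_matches(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice("ACP") for _ in range(rng.randint(10, 60)))
            text = random_pattern(rng)
            p = parse_pattern(text, "narrow")
            wide_elements = []
            for e in p.elements:
                if e.kind == "wildcard":
                    wide_elements.append(
                        type(e)("wildcard", max(0, e.repeat_min - 1), e.repeat_max + 2))
                else:
                    wide_elements.append(e)
            wide = type(p)(name="wide", elements=tuple(wide_elements), source_text="")
            narrow_spans = {(m.start, m.end) for m in scan(p, seq)}
            wide_spans = {(m.start, m.end) for m in scan(wide, seq)}
            assert narrow_spans <= wide_spans

    def test_planted_gap_cysteines_do_not_break_match(self, rng):
        p = parse_pattern(CLASSIC_MOTIF, "classic")
        base = make_classic(gaps=(20, 3, 30, 9, 8))
        spans = {(m.start, m.end) for m in scan(p, base)}
        # plant a C inside the first wildcard gap
        mutated = base[:10] + "C" + base[11:]
        assert spans <= {(m.start, m.end) for m in scan(p, mutated)}
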