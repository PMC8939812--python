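"""Format readers and writers."""

from __future__ import annotations

import pytest

from obpscan import seqio
from obpscan.seqio import SeqIOError, SequenceRecord, GeneLocus, CatalogEntry


class TestFasta:
    def test_basic_parse(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">a\nMKC\n>b desc here\nCCC\n")
        recs = seqio.read_fasta(f)
        assert [r.id for r in recs] == ["a", "b"]
        assert recs[0].residues == "MKC"
        assert recs[1].description == "desc here"

    def test_multiline_body_concatenated(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">a\nMK\nCD\nEF\n")
        assert seqio.read_fasta(f)[0].residues == "MKCDEF"

    def test_lowercase_and_gaps_normalized(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">a\nmk-cd\n")
        assert seqio.read_fasta(f)[0].residues == "MKCD"

    def test_duplicate_id_error(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">a\nMK\n>a\nCD\n")
        with pytest.raises(SeqIOError, match="duplicate"):
            seqio.read_fasta(f)

    def test_illegal_character_names_record_and_position(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">rec1\nMKJ\n")
        with pytest.raises(SeqIOError, match=r"rec1.*position 3"):
            seqio.read_fasta(f)

    def test_dna_alphabet(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">a\nACGTN\n")
        assert seqio.read_fasta(f, alphabet="dna")[0].residues == "ACGTN"
        f.write_text(">a\nACGU\n")
        with pytest.raises(SeqIOError):
            seqio.read_fasta(f, alphabet="dna")

    def test_empty_file_warns(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text("")
        with pytest.warns(UserWarning):
            assert seqio.read_fasta(f) == []

    def test_round_trip(self, tmp_path):
        records = [SequenceRecord("a", "MKCDEF" * 25, "some desc"),
                   SequenceRecord("b", "CCC")]
        out = tmp_path / "out.fasta"
        seqio.write_fasta(records, out)
        back = seqio.read_fasta(out)
        assert [(r.id, r.residues, r.description) for r in back] == \
               [(r.id, r.residues, r.description) for r in records]


class TestBlastTab:
    LINE = "q1\ts1\t98.5\t120\t2\t0\t1\t120\t5\t124\t1e-50\t200\n"

    def test_parse_line(self, tmp_path):
        f = tmp_path / "h.tsv"
        f.write_text(self.LINE)
        (hit,) = seqio.read_blast_tab(f)
        assert hit.query_id == "q1" and hit.subject_id == "s1"
        assert hit.evalue == pytest.approx(1e-50)
        assert hit.percent_identity == pytest.approx(98.5)

    def test_comments_skipped_and_extra_columns_tolerated(self, tmp_path):
        f = tmp_path / "h.tsv"
        f.write_text("# header\n" + self.LINE + self.LINE.rstrip("\n") + "\textra\n")
        assert len(seqio.read_blast_tab(f)) == 2

    def test_empty_file(self, tmp_path):
        f = tmp_path / "h.tsv"
        f.write_text("")
        assert seqio.read_blast_tab(f) == []

    def test_wrong_column_count_names_line(self, tmp_path):
        f = tmp_path / "h.tsv"
        f.write_text(self.LINE + "q1\ts1\t98.5\n")
        with pytest.raises(SeqIOError, match=":2:"):
            seqio.read_blast_tab(f)


class TestDomainHits:
    def test_parse_and_flagging(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("AsteOR1\t7tm_6\tPF02949\t50\t380\t1e-40\n"
                     "weak\t7tm_6\tPF02949\t10\t40\t0.5\n")
        hits = seqio.read_domain_hits(f)
        assert hits[0].domain_accession == "PF02949" and not hits[0].flagged
        assert hits[1].flagged  # above threshold: flagged, not dropped

    def test_start_after_end_is_error(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("a\td\tPF1\t40\t10\t1e-5\n")
        with pytest.raises(SeqIOError):
            seqio.read_domain_hits(f)

    def test_non_numeric_coordinates_error(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("a\td\tPF1\tten\t20\t1e-5\n")
        with pytest.raises(SeqIOError, match="non-numeric"):
            seqio.read_domain_hits(f)

    def test_empty_file(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("")
        assert seqio.read_domain_hits(f) == []


class TestGff:
    GFF = ("##gff-version 3\n"
           "2\tsrc\tgene\t100\t900\t.\t+\t.\tID=g1\n"
           "2\tsrc\tmRNA\t100\t900\t.\t+\t.\tID=t1;Parent=g1\n")

    def test_gene_features_extracted(self, tmp_path):
        f = tmp_path / "a.gff3"
        f.write_text(self.GFF)
        (locus,) = seqio.read_gff_loci(f, feature_type="gene")
        assert (locus.chromosome, locus.start, locus.end, locus.strand) == ("2", 100, 900, "+")
        assert locus.sequence_id == "g1"

    def test_non_matching_feature_types_skipped(self, tmp_path):
        f = tmp_path / "a.gff3"
        f.write_text(self.GFF)
        assert seqio.read_gff_loci(f, feature_type="exon") == []

    def test_missing_attribute_key_is_error(self, tmp_path):
        f = tmp_path / "a.gff3"
        f.write_text(self.GFF)
        with pytest.raises(SeqIOError, match="Name"):
            seqio.read_gff_loci(f, feature_type="gene", id_attribute="Name")

    def test_write_read_round_trip(self, tmp_path):
        loci = [GeneLocus("g1", "X", 10, 500, "+"), GeneLocus("g2", "2", 7, 9, "-")]
        f = tmp_path / "o.gff3"
        seqio.write_gff3(loci, f)
        assert sorted(seqio.read_gff_loci(f), key=lambda l: l.sequence_id) == \
               sorted(loci, key=lambda l: l.sequence_id)


class TestCatalogWriter:
    def test_rows_sorted_by_name_numerically(self, tmp_path):
        entries = [CatalogEntry(name="AsteOBP10", source_id="p10", mw_da=15000.4, pi=5.04),
                   CatalogEntry(name="AsteOBP2", source_id="p2", mw_da=16500.6, pi=8.25,
                                class_label="classic", chromosome="X")]
        out = tmp_path / "cat.tsv"
        seqio.write_catalog(entries, out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == list(seqio.CATALOG_COLUMNS)
        assert lines[1].startswith("AsteOBP2\t") and lines[2].startswith("AsteOBP10\t")
        assert lines[1].split("\t")[5:] == ["16501", "8.3"]  # obp display style

    def test_empty_catalog_is_header_only(self, tmp_path):
        out = tmp_path / "cat.tsv"
        seqio.write_catalog([], out)
        assert out.read_text().splitlines() == ["\t".join(seqio.CATALOG_COLUMNS)]

    def test_invariants_of_types(self):
        with pytest.raises(SeqIOError):
            GeneLocus("g", "2", 10, 5)
        with pytest.raises(SeqIOError):
            seqio.HitRecord("q", "s", 150.0, 10, 1e-5, 50.0)
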