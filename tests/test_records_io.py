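"""Sequence/coordinate conventions and file round trips."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from canemir.io import (
    read_fasta,
    read_fastq,
    read_tag_table,
    write_gff3,
    write_tag_table,
)
from canemir.preprocess import TagTable, collapse_tags
from canemir.records import (
    GenomicInterval,
    LibraryMeta,
    ParseError,
    SequenceRecord,
    as_rna,
    revcomp,
)

rna = st.text(alphabet="ACGU", min_size=1, max_size=40)


class TestRecords:
    def test_normalization_converts_dna_and_case(self):
        assert as_rna("acgT") == "ACGU"
        assert as_rna("ACGTN") == "ACGUN"
        with pytest.raises(ValueError):
            as_rna("ACGX")

    @given(rna)
    def test_revcomp_is_an_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq

    def test_interval_serializes_one_based_inclusive(self):
        iv = GenomicInterval("chr1", 9, 259)
        assert (iv.start1, iv.end1) == (10, 259)
        assert len(iv) == 250

    def test_interval_rejects_degenerate_bounds(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_library_condition_vocabulary(self):
        with pytest.raises(ValueError):
            LibraryMeta("X", condition="watered")


class TestFasta:
    def test_read_converts_t_to_u_and_keeps_order(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nACGT\n>a\nUUGACAGAAGAGAGUGAGCAC\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["x", "a"]
        assert recs[0].sequence == "ACGU"
        assert len(recs[1]) == 21

    def test_empty_body_is_a_parse_error(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">a\n")
        with pytest.raises(ParseError):
            read_fasta(p)

    def test_headerless_file_is_a_parse_error(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACGU\n")
        with pytest.raises(ParseError):
            read_fasta(p)

    @given(st.lists(rna, min_size=1, max_size=8))
    def test_write_read_round_trip(self, tmp_path_factory, seqs):
        tmp = tmp_path_factory.mktemp("fasta") / "rt.fa"
        from canemir.io import write_fasta

        recs = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        write_fasta(recs, tmp)
        back = read_fasta(tmp)
        assert [(r.id, r.sequence) for r in back] == [(r.id, r.sequence) for r in recs]


class TestFastq:
    def test_well_formed_record(self, tmp_path):
        p = tmp_path / "x.fq"
        p.write_text("@r1\nACGTN\n+\nIIIII\n")
        recs = list(read_fastq(p))
        assert len(recs) == 1
        assert recs[0].sequence == "ACGUN"  # N preserved, T converted

    def test_truncated_tail_is_a_parse_error(self, tmp_path):
        p = tmp_path / "x.fq"
        p.write_text("@r1\nACGT\n+\nIIII\n@r2\n")
        with pytest.raises(ParseError):
            list(read_fastq(p))


class TestTagTableIO:
    def _table(self):
        libs = [LibraryMeta("L1", "HT", "irrigated"), LibraryMeta("L2", "HT", "drought")]
        return collapse_tags(
            {"L1": ["ACGUACGUACGUACGUACG"] * 2 + ["UGCAUGCAUGCAUGCAUGC"],
             "L2": ["ACGUACGUACGUACGUACG"]},
            libs,
        )

    def test_round_trip_identity(self, tmp_path):
        table = self._table()
        path = tmp_path / "tags.tsv"
        write_tag_table(table, path)
        back = read_tag_table(path)
        assert back.equals(table)
        assert back.totals == table.totals
        assert [m.condition for m in back.libraries] == ["irrigated", "drought"]

    def test_file_shape(self, tmp_path):
        path = tmp_path / "tags.tsv"
        write_tag_table(self._table(), path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 3  # header + 2 tags

    def test_duplicate_tag_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("tag\tL1\nACG\t1\nACG\t2\n")
        with pytest.raises(ParseError):
            read_tag_table(path)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("tag\tL1\nACG\t-1\n")
        with pytest.raises(ParseError):
            read_tag_table(path)


class TestGff3:
    def _candidate(self, start=9, end=259, strand="+"):
        from canemir.fold import fold
        from canemir.precursor import HairpinCandidate

        seq = "GGGGGAAAACCCCC"
        res = fold(seq)
        return HairpinCandidate(
            interval=GenomicInterval("chr1", start, end, strand),
            window_seq=seq,
            fold=res,
            mature_tag="GGGGG",
            mature_pos=(0, 5),
            star_pos=(9, 14),
            duplex_mismatches=0,
            gc=50.0,
            verdicts={k: True for k in
                      ("hairpin", "mature_in_arm", "star_mm_le6", "mfe_negative", "gc_in_range")},
            accepted=True,
        )

    def test_coordinates_and_strands(self, tmp_path):
        path = tmp_path / "p.gff3"
        write_gff3([self._candidate(), self._candidate(strand="-")], path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        cols = lines[1].split("\t")
        assert (cols[3], cols[4]) == ("10", "259")
        assert [l.split("\t")[6] for l in lines[1:]] == ["+", "-"]

    def test_empty_list_gives_header_only(self, tmp_path):
        path = tmp_path / "e.gff3"
        write_gff3([], path)
        assert path.read_text() == "##gff-version 3\n"

    def test_interval_outside_reference_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_gff3([self._candidate()], tmp_path / "x.gff3", ref_lengths={"chr1": 100})
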