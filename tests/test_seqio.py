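"""FASTA / SAM / extended-BED dialect behaviour."""

import pytest

from micromask import (
    BedRow,
    SequenceRecord,
    read_bed,
    read_fasta,
    read_sam,
    write_bed,
    write_fasta,
    write_sam,
)
from micromask.records import AlignmentRecord


class TestFasta:
    def test_wrapped_lines_concatenate(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">c1\nACGT\nACGT\n")
        (rec,) = read_fasta(path)
        assert rec.contig_id == "c1" and rec.length == 8

    def test_multiple_records_in_order(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">c1\nAC\n>c2\nGGGG\n")
        records = read_fasta(path)
        assert [(r.contig_id, r.length) for r in records] == [("c1", 2), ("c2", 4)]

    def test_headerless_input_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text("ACGT\n")
        with pytest.raises(ValueError):
            read_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="no sequences"):
            read_fasta(path)

    def test_bad_alphabet_names_contig(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">weird\nACGX\n")
        with pytest.raises(ValueError, match="weird"):
            read_fasta(path)

    def test_u_normalized_to_t(self, tmp_path):
        path = tmp_path / "rna.fasta"
        path.write_text(">r\nACGU\nacgu\n")
        (rec,) = read_fasta(path)
        assert rec.sequence == "ACGTacgt"

    def test_round_trip_preserves_ids_case_order(self, tmp_path):
        records = [
            SequenceRecord("c2", "acgtACGTnN" * 13),
            SequenceRecord("c1", "TTTT"),
        ]
        path = tmp_path / "rt.fasta"
        write_fasta(records, path)
        back = read_fasta(path)
        assert [(r.contig_id, r.sequence) for r in back] == [
            (r.contig_id, r.sequence) for r in records
        ]


TABLE_ROW = BedRow(
    organism="Arctocephalus gazella",
    ref_id="GCA_900500725.1",
    contig_id="UIRR01000886.1",
    start=127,
    end=246,
    length=119,
    n_reads=49387,
    taxon_fields=[
        (56, "Moritella_sp018219455"),
        (52, "Moritella_sp018219155"),
        (47, "Moritella_marina"),
    ],
)


class TestBed:
    def test_extended_row_fields(self, tmp_path):
        path = tmp_path / "r.bed"
        write_bed([TABLE_ROW], path)
        fields = path.read_text().strip().split("\t")
        assert fields[3:6] == ["127", "246", "119"]
        assert fields[6] == "49387"  # no thousands separator
        assert fields[7] == "56_reads_Moritella_sp018219455"

    def test_round_trip_including_taxon_counts(self, tmp_path):
        path = tmp_path / "r.bed"
        write_bed([TABLE_ROW], path)
        (back,) = read_bed(path)
        assert back == TABLE_ROW

    def test_empty_collection_gives_empty_file(self, tmp_path):
        path = tmp_path / "e.bed"
        write_bed([], path)
        assert path.read_text() == ""

    def test_inverted_coordinates_rejected(self, tmp_path):
        bad = BedRow("o", "r", "c", 10, 5, -5, 0)
        with pytest.raises(ValueError):
            write_bed([bad], tmp_path / "x.bed")

    def test_length_mismatch_rejected(self, tmp_path):
        bad = BedRow("o", "r", "c", 0, 10, 9, 0)
        with pytest.raises(ValueError, match="length"):
            write_bed([bad], tmp_path / "x.bed")

    def test_unsorted_rows_rejected(self, tmp_path):
        rows = [
            BedRow("o", "r", "c", 50, 60, 10, 1),
            BedRow("o", "r", "c", 0, 10, 10, 1),
        ]
        with pytest.raises(ValueError, match="sorted"):
            write_bed(rows, tmp_path / "x.bed")

    def test_plain_three_column_bed_accepted(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("c1\t0\t100\nc1\t150\t200\n")
        rows = read_bed(path)
        assert [(r.start, r.end, r.length) for r in rows] == [
            (0, 100, 100), (150, 200, 50)
        ]


SAM_TEXT = (
    "@HD\tVN:1.6\tSO:unsorted\n"
    "@SQ\tSN:c1\tLN:1000\n"
    "r1\t0\tc1\t128\t42\t4M\t*\t0\t0\tACGT\t*\tNM:i:1\n"
    "r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n"
    "r3\t16\tc1\t1\t42\t4M\t*\t0\t0\tACGT\t*\n"
)


class TestSam:
    def test_pos_conversion_strand_and_unmapped(self, tmp_path):
        path = tmp_path / "a.sam"
        path.write_text(SAM_TEXT)
        records = read_sam(path)
        assert [r.read_id for r in records] == ["r1", "r3"]  # r2 unmapped
        r1, r3 = records
        assert (r1.start, r1.strand, r1.mismatches) == (127, "+", 1)
        assert (r3.start, r3.strand, r3.mismatches) == (0, "-", 0)

    def test_unknown_reference_rejected_against_target(self, tmp_path):
        path = tmp_path / "a.sam"
        path.write_text(SAM_TEXT)
        with pytest.raises(ValueError, match="c1"):
            read_sam(path, target=[SequenceRecord("other", "ACGT")])

    def test_sam_round_trip(self, tmp_path):
        target = [SequenceRecord("c1", "A" * 500)]
        alignments = [
            AlignmentRecord("r1", "c1", 10, 70, "+", mismatches=2, rank=1),
            AlignmentRecord("r1", "c1", 100, 160, "-", mismatches=3, rank=2),
        ]
        path = tmp_path / "rt.sam"
        write_sam(alignments, target, path)
        back = read_sam(path, target=target)
        assert [(a.start, a.end, a.strand, a.mismatches, a.rank) for a in back] == [
            (10, 70, "+", 2, 1), (100, 160, "-", 3, 2)
        ]
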