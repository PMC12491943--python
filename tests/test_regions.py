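"""Region calling, annotation and coverage statistics."""

import numpy as np
import pytest

from micromask import (
    AlignmentRecord,
    Region,
    SequenceRecord,
    annotate_region,
    breadth_of_coverage,
    call_regions,
    contig_fraction_distribution,
    genome_taxon_table,
)

CONTIG = SequenceRecord("c1", "A" * 1_000)


def _aln(start, read_id="t|s|0", contig="c1", length=60):
    return AlignmentRecord(read_id, contig, start, start + length, "+")


class TestCallRegions:
    def test_overlapping_alignments_merge(self):
        regions = call_regions([_aln(5), _aln(50)], [CONTIG])
        (r,) = regions
        assert (r.start, r.end, r.n_reads) == (5, 110, 2)

    def test_gap_separates_regions(self):
        regions = call_regions([_aln(0), _aln(70)], [CONTIG])
        assert [(r.start, r.end) for r in regions] == [(0, 60), (70, 130)]

    def test_bookended_alignments_merge(self):
        regions = call_regions([_aln(0), _aln(60)], [CONTIG])
        assert [(r.start, r.end) for r in regions] == [(0, 120)]

    def test_flanking_depth_is_zero(self):
        (r,) = call_regions([_aln(100)], [CONTIG])
        assert (r.start, r.end) == (100, 160)  # depth 0 at 99 and 160

    def test_taxon_counts_and_sample_read_exclusion(self):
        alignments = [
            _aln(10, "taxA|s|0"),
            _aln(20, "taxA|s|10"),
            _aln(30, "taxB|s|0"),
            _aln(40, "sample_0001"),  # unlabelled: depth only
        ]
        (r,) = call_regions(alignments, [CONTIG])
        assert r.taxon_counts == {"taxA": 2, "taxB": 1}
        assert r.n_reads == 3 == sum(r.taxon_counts.values())

    def test_out_of_bounds_alignment_names_record(self):
        with pytest.raises(ValueError, match="bad_read"):
            call_regions(
                [AlignmentRecord("bad_read", "c1", 990, 1050, "+")], [CONTIG]
            )

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            call_regions([_aln(0, contig="nope")], [CONTIG])

    def test_adding_alignments_never_decreases_breadth(self):
        starts = [0, 200, 400, 405, 800]
        previous = 0.0
        for n in range(1, len(starts) + 1):
            regions = call_regions([_aln(s) for s in starts[:n]], [CONTIG])
            breadth, _ = breadth_of_coverage(regions, [CONTIG])
            assert breadth >= previous
            previous = breadth


class TestAnnotate:
    def test_top_k_and_published_row_shape(self):
        region = Region(
            "UIRR01000886.1", 127, 246,
            n_reads=49_387,
            taxon_counts={
                "Moritella_sp018219455": 56,
                "Moritella_sp018219155": 52,
                "Moritella_marina": 47,
                "Vibrio_echinoideorum": 30,
                "Photobacterium_toruni": 20,
                "Kosakonia_sp000410515": 10,
            },
        )
        row = annotate_region(region, k=5)
        assert row.length == 119 == row.end - row.start
        assert row.taxon_fields[0] == (56, "Moritella_sp018219455")
        assert len(row.taxon_fields) == 5  # only top 5 recorded

    def test_ties_break_lexicographically(self):
        region = Region("c", 0, 10, n_reads=6, taxon_counts={"B": 3, "A": 3})
        row = annotate_region(region, k=5)
        assert row.taxon_fields == [(3, "A"), (3, "B")]

    def test_fewer_taxa_than_k(self):
        region = Region("c", 0, 10, n_reads=7, taxon_counts={"X": 7})
        assert annotate_region(region, k=5).taxon_fields == [(7, "X")]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            annotate_region(Region("c", 0, 10, taxon_counts={"X": 1}), k=0)


class TestBreadth:
    def test_simple_ratio(self):
        breadth, per = breadth_of_coverage([Region("c1", 127, 246)], [CONTIG])
        assert breadth == pytest.approx(0.119)
        assert per["c1"] == pytest.approx(0.119)

    def test_no_regions_zero(self):
        assert breadth_of_coverage([], [CONTIG])[0] == 0.0

    def test_full_tiling_gives_one(self):
        breadth, per = breadth_of_coverage([Region("c1", 0, 1_000)], [CONTIG])
        assert per["c1"] == 1.0

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            breadth_of_coverage(
                [Region("c1", 0, 100), Region("c1", 50, 150)], [CONTIG]
            )


class TestContigFractions:
    def test_constructed_bimodality(self):
        target = [SequenceRecord(f"c{i}", "A" * 100) for i in range(100)]
        regions = [Region(f"c{i}", 0, 100) for i in range(50)]
        summary = contig_fraction_distribution(regions, target)
        assert summary.n_one_mode == 50 and summary.n_zero_mode == 50

    def test_half_covered_single_contig(self):
        summary = contig_fraction_distribution(
            [Region("c1", 0, 500)], [CONTIG], bins=10
        )
        assert summary.fractions["c1"] == 0.5
        assert summary.hist_counts[5] == 1

    def test_restriction_to_mapped_contigs(self):
        target = [SequenceRecord("c1", "A" * 100), SequenceRecord("c2", "A" * 100)]
        summary = contig_fraction_distribution(
            [Region("c1", 0, 100)], target, restrict_to={"c1"}
        )
        assert set(summary.fractions) == {"c1"}


class TestTaxonTable:
    def test_single_assembly_constant_columns_map_to_zero(self):
        table = genome_taxon_table({"g1": {"A": 10, "B": 5}})
        assert (table.loc["g1"] == 0.0).all()

    def test_min_max_scaling(self):
        table = genome_taxon_table({"g1": {"A": 0}, "g2": {"A": 10}})
        assert table.loc["g1", "A"] == 0.0 and table.loc["g2", "A"] == 1.0

    def test_values_within_unit_interval(self):
        rng = np.random.default_rng(3)
        counts = {
            f"g{i}": {f"t{j}": int(rng.integers(0, 100)) for j in range(5)}
            for i in range(4)
        }
        table = genome_taxon_table(counts)
        assert ((table.values >= 0) & (table.values <= 1)).all()

    def test_missing_taxa_filled_with_zero_raw(self):
        table = genome_taxon_table({"g1": {"A": 4}, "g2": {"B": 2}}, normalize=False)
        assert table.loc["g2", "A"] == 0.0

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            genome_taxon_table({"g1": {}})
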