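"""Interval I/O, overlap algebra and TSS-relative classification."""

import pytest
from hypothesis import given, settings, strategies as st

from motifarch.intervals import (
    ColocalizationPartition,
    GeneModel,
    GenomicInterval,
    RegionClass,
    build_union_groups,
    classify_region,
    classify_regions,
    merge_blocks,
    overlap_fraction_report,
    partition_by_overlap,
    read_narrowpeak,
    subtract_overlapping,
)


def iv(start, end, chrom="chr1", name=""):
    return GenomicInterval(chrom, start, end, name)


PLUS_GENE = GeneModel(
    "chr1", "+", 5000, 30000,
    exon_starts=(5000, 12000, 25000), exon_ends=(5400, 12300, 30000),
    symbol="plus_gene",
)
MINUS_GENE = GeneModel(
    "chr1", "-", 50000, 70000,
    exon_starts=(50000, 69000), exon_ends=(50500, 70000), symbol="minus_gene",
)


class TestNarrowPeakIO:
    def test_field_mapping(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t600\tpeak1\t0\t.\t5.5\t-1\t-1\t250\n")
        (peak,) = read_narrowpeak(path)
        assert (peak.chrom, peak.start, peak.end) == ("chr1", 100, 600)
        assert peak.name == "peak1"
        assert peak.summit_offset == 250

    def test_empty_file_and_header_skipping(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("")
        assert read_narrowpeak(path) == []
        path.write_text("track name=x\n# comment\nchr2\t5\t10\n")
        assert len(read_narrowpeak(path)) == 1

    @pytest.mark.parametrize(
        "line", ["chr1\t600\t100", "chr1\tx\t100", "chr1\t-5\t100"]
    )
    def test_malformed_coordinates_name_the_line(self, tmp_path, line):
        path = tmp_path / "bad.bed"
        path.write_text(line + "\n")
        with pytest.raises(ValueError, match="line 1"):
            read_narrowpeak(path)

    def test_interval_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, summit_offset=10)


class TestClassifyRegion:
    def test_upstream_window_is_proximal(self):
        assert classify_region(iv(4200, 4400), [PLUS_GENE]) is RegionClass.PROXIMAL

    def test_first_exon_is_proximal(self):
        assert classify_region(iv(5300, 5350), [PLUS_GENE]) is RegionClass.PROXIMAL

    def test_internal_intron_is_excluded(self):
        assert classify_region(iv(20000, 20100), [PLUS_GENE]) is RegionClass.EXCLUDED

    def test_far_interval_is_distal(self):
        assert classify_region(iv(100000, 100200), [PLUS_GENE]) is RegionClass.DISTAL

    def test_minus_strand_window_is_downstream_in_coordinates(self):
        # minus-strand TSS at tx_end: window [70000, 71000)
        assert classify_region(iv(70500, 70600), [MINUS_GENE]) is RegionClass.PROXIMAL
        assert classify_region(iv(49100, 49200), [MINUS_GENE]) is RegionClass.DISTAL

    def test_unknown_chromosome_falls_back_to_distal(self):
        assert classify_region(iv(100, 200, chrom="chrUn"), [PLUS_GENE]) is RegionClass.DISTAL

    def test_strand_mirror_symmetry(self):
        """Reversing coordinates and strands preserves every class."""
        genome_size = 200000
        genes = [PLUS_GENE, MINUS_GENE]
        mirrored_genes = []
        for g in genes:
            starts = tuple(genome_size - e for e in reversed(g.exon_ends))
            ends = tuple(genome_size - s for s in reversed(g.exon_starts))
            mirrored_genes.append(
                GeneModel(
                    g.chrom, "-" if g.strand == "+" else "+",
                    genome_size - g.tx_end, genome_size - g.tx_start,
                    starts, ends, g.symbol,
                )
            )
        probes = [iv(a, a + 150) for a in range(0, genome_size - 150, 997)]
        for p in probes:
            mirrored = iv(genome_size - p.end, genome_size - p.start)
            assert classify_region(p, genes) is classify_region(mirrored, mirrored_genes)

    def test_classify_regions_partitions_input(self):
        probes = [iv(4200, 4400), iv(20000, 20100), iv(100000, 100100)]
        groups = classify_regions(probes, [PLUS_GENE])
        assert sum(len(v) for v in groups.values()) == len(probes)


class TestPartitionByOverlap:
    def test_basic_three_way_split(self):
        A = [iv(0, 10), iv(20, 30)]
        B = [iv(5, 15), iv(100, 110)]
        part = partition_by_overlap(A, B)
        assert (part.a_only, part.both, part.b_only) == (1, 1, 1)

    def test_identical_sets_are_all_shared(self):
        A = [iv(0, 10), iv(50, 60)]
        part = partition_by_overlap(A, list(A))
        assert (part.a_only, part.b_only) == (0, 0)
        assert part.pct_both == pytest.approx(100.0)

    def test_printed_style_percentages(self):
        # proportions of a 2197-block union: 7.6 / 22.3 / 70.1
        part = ColocalizationPartition(166, 491, 1540)
        assert round(part.pct_a_only, 1) == 7.6
        assert round(part.pct_both, 1) == 22.3
        assert round(part.pct_b_only, 1) == 70.1
        assert part.pct_a_only + part.pct_both + part.pct_b_only == pytest.approx(100.0, abs=0.2)

    def test_record_counting_mode(self):
        A = [iv(0, 10), iv(2, 8)]
        B = [iv(5, 15)]
        assert partition_by_overlap(A, B, count="records").both == 3
        assert partition_by_overlap(A, B, count="blocks").both == 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_conservation_against_merged_blocks(self, data):
        def draw_set(tag):
            n = data.draw(st.integers(0, 15))
            out = []
            for i in range(n):
                s = data.draw(st.integers(0, 300))
                length = data.draw(st.integers(1, 40))
                out.append(iv(s, s + length, name=f"{tag}{i}"))
            return out

        A, B = draw_set("a"), draw_set("b")
        part = partition_by_overlap(A, B)
        assert part.total == len(merge_blocks(list(A) + list(B)))


class TestSubtractOverlapping:
    def test_examples(self):
        A = [iv(0, 10), iv(50, 60)]
        assert subtract_overlapping(A, [iv(5, 8)]) == [iv(50, 60)]
        assert subtract_overlapping(A, []) == A

    def test_touching_is_not_overlap(self):
        assert subtract_overlapping([iv(0, 10)], [iv(10, 20)]) == [iv(0, 10)]

    def test_matches_all_pairs_brute_force(self, random_intervals):
        A = random_intervals(200)
        B = random_intervals(200)
        expected = [a for a in A if not any(a.overlaps(b) for b in B)]
        assert subtract_overlapping(A, B) == expected


class TestUnionGroups:
    def test_single_line_overlap_is_inter(self):
        groups = build_union_groups({"l1": [iv(0, 10)]}, {"l1": [iv(5, 15)]})
        assert groups.inter == [iv(0, 15)]
        assert groups.fos_only == [] and groups.nfyb_only == []

    def test_colocalization_in_any_line_counts(self):
        groups = build_union_groups(
            {"l1": [iv(0, 10)], "l2": [iv(100, 110)]},
            {"l1": [iv(50, 60)], "l2": [iv(105, 115)]},
        )
        assert iv(100, 115) in groups.inter
        assert groups.fos_only == [iv(0, 10)]
        assert groups.nfyb_only == [iv(50, 60)]

    def test_outputs_disjoint_and_cover_inputs(self, random_intervals):
        fos = {"l1": random_intervals(40), "l2": random_intervals(40)}
        nfyb = {"l1": random_intervals(40), "l2": random_intervals(40)}
        groups = build_union_groups(fos, nfyb)
        blocks = groups.fos_only + groups.inter + groups.nfyb_only
        for i, a in enumerate(blocks):
            for b in blocks[i + 1 :]:
                assert not a.overlaps(b)
        every = [x for s in (*fos.values(), *nfyb.values()) for x in s]
        for x in every:
            assert any(b.chrom == x.chrom and b.start <= x.start and x.end <= b.end for b in blocks)


class TestOverlapFractionReport:
    def test_printed_style_percentages(self):
        A = [iv(i * 10, i * 10 + 5) for i in range(5099)]
        B = [iv(i * 10, i * 10 + 5) for i in range(4436)]
        assert overlap_fraction_report(A, B) == (4436, 87)

    def test_rounding_to_integer_percent(self):
        A = [iv(i * 10, i * 10 + 5) for i in range(1724)]
        B = [iv(i * 10, i * 10 + 5) for i in range(1535)]
        assert overlap_fraction_report(A, B) == (1535, 89)

    def test_disjoint_sets_and_empty_input(self):
        assert overlap_fraction_report([iv(0, 5)], [iv(10, 15)]) == (0, 0)
        assert overlap_fraction_report([], [iv(0, 5)]) == (0, None)
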