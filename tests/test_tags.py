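"""PSL parsing, quality filtering, boundary assignment and count-table I/O."""

import pytest

from cnc4c import (
    AlignedTag,
    FilterConfig,
    LibraryCounts,
    RestrictionFragment,
    assign_tags,
    filter_tags,
    parse_psl,
    read_counts_table,
    write_counts_table,
)
from cnc4c.tags import CountsFormatError, PslFormatError


def psl_line(read_id, chrom, start, end, matches, *, strand="+", gap=0, q_start=0):
    qsize = matches + gap
    if gap:
        b1 = matches // 2
        b2 = matches - b1
        blocks = (2, f"{b1},{b2},", f"{q_start},{q_start + b1},",
                  f"{start},{start + b1 + gap},")
        t_ins = gap
    else:
        blocks = (1, f"{matches},", f"{q_start},", f"{start},")
        t_ins = 0
    fields = [matches, 0, 0, 0, 0, 0, 1 if gap else 0, t_ins, strand, read_id,
              qsize, q_start, q_start + matches, chrom, 10_000, start, end, *blocks]
    return "\t".join(str(x) for x in fields)


def make_tag(**kw):
    base = dict(read_id="r", chrom="c1", start=8, end=14, strand="+",
                match_length=36, max_gap=0, hit_count=1, leading_seq="GATC")
    base.update(kw)
    return AlignedTag(**base)


class TestParsePsl:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "a.psl"
        p.write_text(psl_line("r1", "chr1", 100, 136, 36) + "\n")
        (tag,) = parse_psl(p)
        assert (tag.chrom, tag.start, tag.end) == ("chr1", 100, 136)
        assert tag.match_length == 36 and tag.max_gap == 0 and tag.hit_count == 1

    def test_multi_mapper_hit_count(self, tmp_path):
        p = tmp_path / "a.psl"
        p.write_text(
            psl_line("r1", "chr1", 100, 136, 36) + "\n"
            + psl_line("r1", "chr2", 500, 536, 36) + "\n"
        )
        tags = parse_psl(p)
        assert [t.hit_count for t in tags] == [2, 2]

    def test_header_only_file_yields_no_tags(self, tmp_path):
        p = tmp_path / "a.psl"
        p.write_text("psLayout version 3\n\nmatch\tmis-\n----\n----\n")
        assert parse_psl(p) == []

    def test_per_gap_size_from_blocks(self, tmp_path):
        # a single 2 nt gap between two blocks
        p = tmp_path / "a.psl"
        p.write_text(psl_line("r1", "chr1", 100, 138, 36, gap=2) + "\n")
        (tag,) = parse_psl(p)
        assert tag.max_gap == 2

    def test_malformed_column_count_rejected(self, tmp_path):
        p = tmp_path / "a.psl"
        p.write_text("only\tthree\tcolumns\n")
        with pytest.raises(PslFormatError, match="line 1"):
            parse_psl(p)

    def test_prefix_inferred_from_query_start(self, tmp_path):
        p = tmp_path / "a.psl"
        p.write_text(
            psl_line("r1", "chr1", 100, 136, 36, q_start=0) + "\n"
            + psl_line("r2", "chr1", 100, 133, 33, q_start=3) + "\n"
        )
        t1, t2 = parse_psl(p)
        assert t1.leading_seq == "GATC" and t2.leading_seq != "GATC"


class TestFilterTags:
    @pytest.mark.parametrize(
        "tag,kept",
        [
            (make_tag(match_length=28), False),  # below 29 nt minimum
            (make_tag(match_length=29), True),
            (make_tag(max_gap=2), False),  # gap larger than 1 nt
            (make_tag(max_gap=1), True),
            (make_tag(hit_count=2), False),  # multi-mapper
            (make_tag(leading_seq="AATC"), False),  # no GATC start
            (make_tag(), True),
        ],
    )
    def test_criteria(self, tag, kept):
        assert (filter_tags([tag]) == [tag]) is kept

    def test_idempotent_subset_order_preserved(self):
        tags = [make_tag(read_id=f"r{i}", match_length=20 + i) for i in range(20)]
        once = filter_tags(tags)
        assert filter_tags(once) == once
        assert all(t in tags for t in once)
        assert [t.read_id for t in once] == [t.read_id for t in tags if t in once]


class TestAssignTags:
    def test_plus_strand_anchors_at_fragment_start(self, toy_index):
        lib = assign_tags([make_tag(start=8, end=14)], toy_index)
        assert lib.counts == {toy_index.fragments["c1"][2]: 1}

    def test_minus_strand_anchors_at_fragment_end(self, toy_index):
        lib = assign_tags([make_tag(strand="-", start=2, end=8)], toy_index)
        assert lib.counts == {toy_index.fragments["c1"][1]: 1}

    def test_off_boundary_tag_dropped_at_zero_tolerance(self, toy_index):
        lib = assign_tags([make_tag(start=9, end=14)], toy_index)
        assert lib.counts == {} and lib.n_unassigned == 1

    def test_tolerance_snaps_to_nearest_boundary(self, toy_index):
        lib = assign_tags([make_tag(start=9, end=14)], toy_index, tolerance=1)
        assert lib.counts == {toy_index.fragments["c1"][2]: 1}

    def test_unknown_chromosome_dropped(self, toy_index):
        lib = assign_tags([make_tag(chrom="cX")], toy_index)
        assert lib.total_tags == 0 and lib.n_unassigned == 1

    def test_tag_conservation(self, toy_index):
        tags = [make_tag(start=s, end=s + 4) for s in (0, 2, 8, 9, 11)]
        lib = assign_tags(tags, toy_index)
        assert lib.total_tags + lib.n_unassigned == len(tags)


class TestCountsTable:
    def make_lib(self, bait="CNC1"):
        return LibraryCounts(
            bait_id=bait,
            counts={
                RestrictionFragment("chr1", 100, 300): 60,
                RestrictionFragment("chr2", 0, 50): 7,
            },
        )

    def test_roundtrip(self, tmp_path):
        path = tmp_path / "counts.tsv"
        libs = [self.make_lib("CNC1"), self.make_lib("CNC2")]
        write_counts_table(libs, path)
        back = read_counts_table(path)
        assert [lib.bait_id for lib in back] == ["CNC1", "CNC2"]
        assert back[0].counts == libs[0].counts
        assert back[1].counts == libs[1].counts

    def test_rows_grouped_by_bait(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "BaitID\tChr\tDpnIIStart\tDpnIIEnd\tNumbReads\n"
            "CNC1\tchr1\t101\t300\t60\n"
            "CNC1\tchr2\t1\t50\t7\n"
            "CNC2\tchr1\t101\t300\t5\n"
        )
        libs = read_counts_table(path)
        assert len(libs) == 2
        assert len(libs[0].counts) == 2 and libs[0].total_tags == 67

    def test_dialect_conversion(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("CNC1\tchr1\t101\t300\t60\n")
        (one_based,) = read_counts_table(path, dialect="one-based-inclusive")
        (zero_based,) = read_counts_table(path, dialect="zero-based-half-open")
        assert list(one_based.counts)[0].start == 100
        assert list(zero_based.counts)[0].start == 101

    def test_negative_reads_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("CNC1\tchr1\t101\t300\t-5\n")
        with pytest.raises(CountsFormatError, match="line 1"):
            read_counts_table(path)

    def test_duplicate_bait_across_libraries_is_error(self, tmp_path):
        with pytest.raises(ValueError, match="CNC1"):
            write_counts_table([self.make_lib(), self.make_lib()], tmp_path / "x.tsv")
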