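import numpy as np
import pysam
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tnmap.samfilter import (
    FilterConfig,
    InsertionTable,
    call_insertions,
    collapse,
    count_mismatches,
    coverage_filter,
    insertion_position,
    parameter_sweep,
    passes_filters,
    reference_span,
)

from conftest import write_sam


def table_of(sites: dict[int, int], ref="chr1") -> InsertionTable:
    return InsertionTable({(ref, pos): depth for pos, depth in sites.items()})


class TestCountMismatches:
    @pytest.mark.parametrize(
        "md,expected",
        [
            ("50", 0),
            ("10A5C3", 2),
            ("3^AC10T5", 1),
            ("0A0C0", 2),
            ("5^ACGT5", 0),
        ],
    )
    def test_examples(self, md, expected):
        assert count_mismatches(md) == expected

    def test_deletion_letters_not_counted_against_brute_force(self):
        # alignment implied by MD "3^AC10T5" with CIGAR 3M2D16M:
        # 3 matches, 2-base deletion, 10 matches, 1 substitution, 5 matches
        ref_ = "AAA" + "AC" + "GGGGGGGGGG" + "T" + "CCCCC"
        read = "AAA" + "GGGGGGGGGG" + "G" + "CCCCC"
        # brute force: walk the alignment columns and count substitutions
        subs = 0
        ri = qi = 0
        for n, op in [(3, "M"), (2, "D"), (16, "M")]:
            if op == "M":
                for _ in range(n):
                    subs += ref_[ri] != read[qi]
                    ri += 1
                    qi += 1
            else:
                ri += n
        assert subs == 1
        assert count_mismatches("3^AC10T5") == subs

    @pytest.mark.parametrize("bad", ["", "10A5X!", "A^", "^"])
    def test_malformed_md_raises(self, bad):
        with pytest.raises(ValueError, match="MD"):
            count_mismatches(bad, read_id="r9")

    @given(
        st.lists(
            st.one_of(
                st.integers(min_value=0, max_value=30),  # match run
                st.sampled_from(list("ACGT")),  # substitution
                st.tuples(st.sampled_from(list("ACGT"))),  # deletion of 1 base
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_counts_substitution_letters_only(self, tokens):
        md = ""
        expected = 0
        last_was_letterish = True
        for tok in tokens:
            if isinstance(tok, int):
                md += str(tok)
                last_was_letterish = False
            elif isinstance(tok, tuple):
                if last_was_letterish:
                    md += "0"
                md += "^" + tok[0]
                last_was_letterish = True
            else:
                if last_was_letterish:
                    md += "0"
                md += tok
                expected += 1
                last_was_letterish = True
        if last_was_letterish:
            md += "0"
        assert count_mismatches(md) == expected


class TestPassesFilters:
    def test_recommended_strict_filters(self):
        cfg = FilterConfig(max_mismatch=0, min_align_score=50)
        assert passes_filters(0, 50, cfg, read_len=30)
        assert not passes_filters(1, 50, cfg, read_len=30)
        assert not passes_filters(0, 49, cfg, read_len=30)

    def test_fractional_mismatch_uses_floor_of_read_length(self):
        cfg = FilterConfig(max_mismatch=0.1, min_align_score=0)
        assert cfg.mismatch_threshold(30) == 3
        assert passes_filters(3, 0, cfg, read_len=30)
        assert not passes_filters(4, 0, cfg, read_len=30)

    def test_missing_alignment_score_fails(self):
        cfg = FilterConfig(max_mismatch=5, min_align_score=-100)
        assert not passes_filters(0, None, cfg, read_len=30)

    def test_negative_scores_expressible(self):
        cfg = FilterConfig(max_mismatch=0, min_align_score=-10)
        assert passes_filters(0, -5, cfg, read_len=30)
        assert not passes_filters(0, -11, cfg, read_len=30)

    @pytest.mark.parametrize("bad", [-1, 1.5])
    def test_invalid_mismatch_config_rejected(self, bad):
        with pytest.raises(ValueError):
            FilterConfig(max_mismatch=bad)


class TestInsertionPosition:
    def test_forward_strand_uses_leftmost_base(self):
        assert insertion_position("c", 100, "30M", "+") == ("c", 100)

    def test_reverse_strand_uses_rightmost_base(self):
        assert insertion_position("c", 100, "30M", "-") == ("c", 129)

    def test_deletions_extend_reference_span(self):
        assert insertion_position("c", 100, "10M2D20M", "-") == ("c", 131)

    def test_soft_clips_do_not_consume_reference(self):
        assert insertion_position("c", 100, "5S25M", "-") == ("c", 124)

    @pytest.mark.parametrize(
        "cigar", ["30M", "10M2D20M", "5S25M3S", "10M2I18M", "4M100N6M"]
    )
    def test_reference_span_matches_pysam(self, cigar):
        header = pysam.AlignmentHeader.from_dict(
            {"SQ": [{"SN": "c", "LN": 10_000}]}
        )
        rec = pysam.AlignedSegment(header)
        rec.query_name = "r"
        rec.reference_id = 0
        rec.reference_start = 99
        rec.cigarstring = cigar
        qlen = sum(n for n, op in rec.cigartuples if op in (0, 1, 4, 7, 8))
        rec.query_sequence = "A" * qlen
        assert reference_span(cigar) == rec.reference_end - rec.reference_start


class TestCollapse:
    def test_pair_exactly_d_apart_merges_to_lower(self):
        out = collapse(table_of({100: 5, 108: 3}), 8)
        assert out.sites == {("chr1", 100): 8}

    def test_single_pass_no_rechaining(self):
        out = collapse(table_of({100: 5, 108: 3, 116: 2}), 8)
        assert out.sites == {("chr1", 100): 8, ("chr1", 116): 2}

    def test_inexact_distance_untouched(self):
        out = collapse(table_of({100: 5, 107: 3}), 8)
        assert out.sites == {("chr1", 100): 5, ("chr1", 107): 3}

    def test_d_zero_is_identity(self):
        t = table_of({100: 5, 108: 3})
        assert collapse(t, 0).sites == t.sites

    def test_references_do_not_interact(self):
        t = InsertionTable({("a", 100): 1, ("b", 108): 1})
        assert collapse(t, 8).sites == t.sites

    @given(
        st.dictionaries(
            st.integers(min_value=1, max_value=300),
            st.integers(min_value=1, max_value=9),
            min_size=1,
            max_size=40,
        ),
        st.integers(min_value=1, max_value=12),
    )
    def test_depth_conserved_and_positions_decrease(self, sites, d):
        before = table_of(sites)
        after = collapse(before, d)
        assert after.total_mapped_reads == before.total_mapped_reads
        assert after.total_unique_positions <= before.total_unique_positions
        assert set(after.sites) <= set(before.sites)


class TestCoverageFilter:
    def test_removes_single_read_sites(self):
        out = coverage_filter(table_of({100: 1, 200: 5}), 2)
        assert out.sites == {("chr1", 200): 5}
        assert out.total_mapped_reads == 5

    def test_min_depth_one_is_identity(self):
        t = table_of({100: 1, 200: 5})
        assert coverage_filter(t, 1).sites == t.sites

    def test_all_sites_removed_gives_empty_table(self):
        out = coverage_filter(table_of({1: 1, 2: 1}), 2)
        assert out.sites == {}


class TestInsertionTable:
    def test_totals_are_consistent(self):
        t = table_of({100: 2, 200: 3})
        assert t.total_mapped_reads == 5
        assert t.total_unique_positions == 2

    def test_tsv_round_trip(self, tmp_path):
        t = table_of({100: 2, 200: 3})
        t.to_tsv(tmp_path / "positions.tsv")
        assert InsertionTable.from_tsv(tmp_path / "positions.tsv").sites == t.sites

    def test_missing_columns_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError, match="columns"):
            InsertionTable.from_tsv(tmp_path / "bad.tsv")


class TestCallInsertions:
    def test_conservation_of_sam_records(self, tmp_path):
        sam = write_sam(
            tmp_path / "t.sam",
            [
                ("pass", 99, "30M", False, "30", 50),
                ("mis", 99, "30M", False, "15A14", 50),
                ("low", 99, "30M", False, "30", 10),
                ("unmapped", None, None, False, None, None),
                ("nomd", 99, "30M", False, None, 50),
            ],
        )
        table, stats = call_insertions(sam, FilterConfig(0, 50))
        assert stats.total_records == 5
        assert stats.total_records == (
            stats.unmapped
            + stats.secondary
            + stats.passed
            + stats.failed_mismatch
            + stats.failed_score
        )
        assert stats.missing_md == 1
        assert table.sites == {("chr1", 100): 1}

    def test_strand_aware_positions(self, tmp_path):
        sam = write_sam(
            tmp_path / "t.sam",
            [
                ("f", 99, "30M", False, "30", 50),
                ("r", 99, "30M", True, "30", 50),
            ],
        )
        table, _ = call_insertions(sam, FilterConfig(0, 50))
        assert table.sites == {("chr1", 100): 1, ("chr1", 129): 1}

    def test_roundtrip_against_truth(self, small_pipeline):
        """Truth sites are recovered exactly at strict filters (oracle SAM)."""
        assert small_pipeline["table"].sites == small_pipeline["expected"].sites


def noisy_sam(path):
    """10 true sites (depth 5, AS 50, 0 mismatches) + 20 noise sites
    (depth 1, AS 10, 1-5 mismatches)."""
    records = []
    for i in range(10):
        pos0 = 1000 + 100 * i
        for j in range(5):
            records.append((f"true{i}_{j}", pos0, "30M", False, "30", 50))
    for i in range(20):
        pos0 = 10_000 + 100 * i
        n_mis = 1 + i % 5
        md = "A".join(["5"] * (n_mis + 1))
        records.append((f"noise{i}", pos0, "30M", False, md, 10))
    return write_sam(path, records)


class TestParameterSweep:
    @pytest.fixture()
    def sweep_table(self, tmp_path):
        sam = noisy_sam(tmp_path / "noisy.sam")
        return parameter_sweep(sam, [0, 3, 5], [0, 10, 30, 50])

    def test_lenient_recovers_all_strict_recovers_true(self, sweep_table):
        cell = lambda m, s: int(
            sweep_table.query(
                "max_mismatch == @m and min_align_score == @s"
            )["unique_positions"].iloc[0]
        )
        assert cell(5, 0) == 30
        assert cell(0, 50) == 10

    def test_monotone_in_both_thresholds(self, sweep_table):
        for m in (0, 3, 5):
            col = sweep_table.query("max_mismatch == @m").sort_values(
                "min_align_score"
            )["unique_positions"]
            assert (col.diff().dropna() <= 0).all()
        for s in (0, 10, 30, 50):
            row = sweep_table.query("min_align_score == @s").sort_values(
                "max_mismatch"
            )["unique_positions"]
            assert (row.diff().dropna() >= 0).all()

    def test_mismatch_inactive_at_top_score_stringency(self, sweep_table):
        top = sweep_table.query("min_align_score == 50")["unique_positions"]
        assert top.nunique() == 1
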