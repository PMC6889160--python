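"""Read ingest: window tiling, SAM/TSV parsing, mate stitching."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methsector.ingest import (
    ReadCallsFormatError,
    SequencedFragment,
    Window,
    enumerate_windows,
    find_cpg_positions,
    parse_alignment_file,
    parse_readcalls_tsv,
    stitch_mates,
    write_readcalls_tsv,
)

from conftest import write_sam


class TestEnumerateWindows:
    def test_tiling_with_trailing_partial_window(self):
        ref = {"chr1": "T" * 250}
        wins = enumerate_windows(ref, 100)
        assert [(w.start, w.end) for w in wins] == [(0, 100), (100, 200), (200, 250)]

    def test_cpg_detected_at_c_coordinate(self):
        wins = enumerate_windows({"chr1": "TTCGTT"}, 100)
        assert len(wins) == 1
        assert wins[0].cpg_positions == (2,)

    def test_boundary_straddling_cpg_belongs_to_c_window(self):
        # C at 99, G at 100: the CpG belongs to [0, 100)
        seq = "A" * 99 + "CG" + "A" * 99
        wins = enumerate_windows({"chr1": seq}, 100)
        assert 99 in wins[0].cpg_positions
        assert 99 not in wins[1].cpg_positions

    def test_windows_tile_disjointly_and_cover_chromosome(self):
        wins = enumerate_windows({"chr1": "ACGT" * 60}, 100)
        assert wins[0].start == 0
        for prev, cur in zip(wins, wins[1:]):
            assert prev.end == cur.start
        assert wins[-1].end == 240

    def test_explicit_cpg_positions(self):
        wins = enumerate_windows(
            None, 100, cpg_positions={"chrX": [5, 150]}, chrom_lengths={"chrX": 220}
        )
        assert wins[0].cpg_positions == (5,)
        assert wins[1].cpg_positions == (150,)

    def test_empty_reference_gives_empty_list(self):
        assert enumerate_windows({}, 100) == []

    def test_window_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            enumerate_windows({"chr1": "ACGT"}, 1)

    def test_lowercase_sequence_handled(self):
        assert find_cpg_positions("ttcgtt") == [2]


class TestStitchMates:
    def test_mate1_wins_at_overlap(self):
        merged, conflicts = stitch_mates({100: 1, 120: 0}, {120: 1, 140: 1})
        assert merged == {100: 1, 120: 0, 140: 1}
        assert conflicts == 1

    def test_disjoint_union(self):
        merged, conflicts = stitch_mates({100: 1}, {140: 0})
        assert merged == {100: 1, 140: 0}
        assert conflicts == 0

    def test_single_end_identity(self):
        assert stitch_mates({100: 1}, None) == ({100: 1}, 0)
        assert stitch_mates(None, {100: 1}) == ({100: 1}, 0)

    @given(
        st.dictionaries(st.integers(0, 50), st.integers(0, 1), max_size=8),
        st.dictionaries(st.integers(0, 50), st.integers(0, 1), max_size=8),
    )
    @settings(derandomize=True, max_examples=50)
    def test_stitching_idempotent_and_single_call_per_position(self, m1, m2):
        merged, _ = stitch_mates(m1, m2)
        again, conflicts = stitch_mates(merged, merged)
        assert again == merged and conflicts == 0
        # mate-1 precedence everywhere
        for pos, state in m1.items():
            assert merged[pos] == state


class TestReadcallsTsv:
    def test_round_trip(self, tmp_path):
        frags = [
            SequencedFragment("f1", "A", "chr1", {12: 1, 48: 0}),
            SequencedFragment("f2", "B", "chr2", {7: 0}),
        ]
        path = tmp_path / "calls.tsv"
        assert write_readcalls_tsv(frags, path) == 2
        back = list(parse_readcalls_tsv(path))
        assert [(f.fragment_id, f.condition, f.chrom, f.calls) for f in back] == [
            (f.fragment_id, f.condition, f.chrom, f.calls) for f in frags
        ]

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["A", "B"]),
                st.dictionaries(st.integers(0, 500), st.integers(0, 1), min_size=1, max_size=6),
            ),
            max_size=10,
        )
    )
    @settings(derandomize=True, max_examples=30)
    def test_round_trip_property(self, tmp_path_factory, entries):
        frags = [
            SequencedFragment(f"f{i}", cond, "chr1", calls)
            for i, (cond, calls) in enumerate(entries)
        ]
        path = tmp_path_factory.mktemp("rt") / "calls.tsv"
        write_readcalls_tsv(frags, path)
        back = list(parse_readcalls_tsv(path))
        assert [(f.fragment_id, f.condition, f.calls) for f in back] == [
            (f.fragment_id, f.condition, f.calls) for f in frags
        ]

    def test_duplicate_position_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "fragment_id\tcondition\tchrom\tcalls\nf1\tA\tchr1\t12:1,12:0\n"
        )
        with pytest.raises(ReadCallsFormatError, match="line 2"):
            list(parse_readcalls_tsv(path))

    def test_state_outside_binary_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("fragment_id\tcondition\tchrom\tcalls\nf1\tA\tchr1\t12:2\n")
        with pytest.raises(ReadCallsFormatError):
            list(parse_readcalls_tsv(path))

    def test_empty_file_yields_empty_stream(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert list(parse_readcalls_tsv(path)) == []


class TestAlignmentParsing:
    def test_forward_strand_z_offset(self, tmp_path):
        # 0-based pos 10, Z at query offset 2 -> call at 12, methylated
        sam = write_sam(
            tmp_path / "fwd.sam",
            ["r1\t0\tchr1\t11\t40\t5M\t*\t0\t0\tTTCGT\tIIIII\tXM:Z:..Z..\tXG:Z:CT"],
        )
        frags = list(parse_alignment_file(sam, "A"))
        assert len(frags) == 1
        assert frags[0].calls == {12: 1}

    def test_reverse_strand_g_position_shifted_to_c(self, tmp_path):
        # reverse-informative read (XG:GA): z over the G at forward pos 13
        # reports the CpG's C at 12, unmethylated
        sam = write_sam(
            tmp_path / "rev.sam",
            ["r1\t16\tchr1\t11\t40\t5M\t*\t0\t0\tTTCAT\tIIIII\tXM:Z:...z.\tXG:Z:GA"],
        )
        frags = list(parse_alignment_file(sam, "A"))
        assert frags[0].calls == {12: 0}

    def test_non_cpg_symbols_emit_no_calls(self, tmp_path):
        sam = write_sam(
            tmp_path / "noncpg.sam",
            ["r1\t0\tchr1\t11\t40\t5M\t*\t0\t0\tTTTTT\tIIIII\tXM:Z:.xh..\tXG:Z:CT"],
        )
        assert list(parse_alignment_file(sam, "A")) == []

    def test_duplicate_and_secondary_records_skipped(self, tmp_path):
        sam = write_sam(
            tmp_path / "dup.sam",
            [
                "r1\t1024\tchr1\t11\t40\t5M\t*\t0\t0\tTTCGT\tIIIII\tXM:Z:..Z..\tXG:Z:CT",
                "r2\t256\tchr1\t11\t40\t5M\t*\t0\t0\tTTCGT\tIIIII\tXM:Z:..Z..\tXG:Z:CT",
            ],
        )
        assert list(parse_alignment_file(sam, "A")) == []

    def test_missing_xm_tag_skipped_and_counted(self, tmp_path):
        from methsector.ingest import ParseStats

        sam = write_sam(
            tmp_path / "notag.sam",
            ["r1\t0\tchr1\t11\t40\t5M\t*\t0\t0\tTTCGT\tIIIII"],
        )
        stats = ParseStats()
        assert list(parse_alignment_file(sam, "A", stats=stats)) == []
        assert stats.skipped_no_tag == 1

    def test_mate_pair_stitched_with_first_read_precedence(self, tmp_path):
        # mates overlap at pos 12; read1 says methylated, read2 unmethylated
        sam = write_sam(
            tmp_path / "pair.sam",
            [
                "p1\t99\tchr1\t11\t40\t5M\t=\t13\t7\tTTCGT\tIIIII\tXM:Z:..Z..\tXG:Z:CT",
                "p1\t147\tchr1\t13\t40\t5M\t=\t11\t-7\tCGTCG\tIIIII\tXM:Z:z..Z.\tXG:Z:CT",
            ],
        )
        from methsector.ingest import ParseStats

        stats = ParseStats()
        frags = list(parse_alignment_file(sam, "A", stats=stats))
        assert len(frags) == 1
        assert frags[0].calls == {12: 1, 15: 1}
        assert stats.overlap_conflicts == 1
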