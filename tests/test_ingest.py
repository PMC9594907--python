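"""Alignment filtering, UMI deduplication, window assignment, counting."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from readzs.ingest import (
    AlignmentRecord,
    FilteredRead,
    IngestStats,
    WindowSpec,
    assign_window,
    build_counts,
    counts_from_alignments,
    deduplicate,
    filter_alignment,
)
from readzs.simulate import SimSpec, simulate_celltype_dataset


def rec(cigar="98M", seq_len=98, mapq=255, **kw):
    defaults = dict(chrom="chr1", pos=100, strand="+", cell="c1", umi="u1", sample="s")
    defaults.update(kw)
    return AlignmentRecord(cigar=cigar, seq_len=seq_len, mapq=mapq, **defaults)


class TestFilterAlignment:
    @pytest.mark.parametrize(
        "cigar,seq_len,mapq,expected",
        [
            ("98M", 98, 255, True),      # unique full-length match
            ("50M10S", 60, 255, False),  # clipped
            ("98M", 98, 60, False),      # non-unique mapping
            ("49M1000N49M", 98, 255, False),  # spliced
            ("98M", 99, 255, False),     # length mismatch
        ],
    )
    def test_examples(self, cigar, seq_len, mapq, expected):
        assert filter_alignment(rec(cigar=cigar, seq_len=seq_len, mapq=mapq)) is expected

    def test_configurable_mapq_for_other_aligners(self):
        assert filter_alignment(rec(mapq=60), min_mapq=60)

    def test_invalid_record_rejected_at_construction(self):
        with pytest.raises(ValueError):
            rec(pos=-1)
        with pytest.raises(ValueError):
            rec(strand="*")


class TestDeduplicate:
    def test_umi_collapse_keeps_one_read(self):
        reads = [("A", "u1", "chr1", "+", 100)] * 3
        out = deduplicate(reads)
        assert out == [FilteredRead("chr1", "+", 100, "A", "sample")]

    def test_multi_position_umi_discarded(self):
        reads = [("A", "u2", "chr1", "+", 100), ("A", "u2", "chr1", "+", 900)]
        stats = IngestStats()
        assert deduplicate(reads, stats=stats) == []
        assert stats.umi_multi_position == 1

    def test_umi_scope_is_per_cell(self):
        reads = [("A", "u1", "chr1", "+", 100), ("B", "u1", "chr1", "+", 100)]
        out = deduplicate(reads)
        assert sorted(r.cell for r in out) == ["A", "B"]

    def test_ten_read_toy_set_against_exhaustive_grouping(self):
        reads = [
            ("A", "u1", "chr1", "+", 100),
            ("A", "u1", "chr1", "+", 100),
            ("A", "u1", "chr1", "+", 100),
            ("A", "u2", "chr1", "+", 100),
            ("A", "u2", "chr1", "+", 900),
            ("B", "u1", "chr1", "+", 100),
            ("B", "u3", "chr1", "-", 250),
            ("B", "u3", "chr1", "-", 250),
            ("C", "u4", "chr2", "+", 7),
            ("A", "u5", "chr1", "+", 4999),
        ]
        # oracle: exhaustive grouping by (cell, umi)
        groups = {}
        for cell, umi, chrom, strand, pos in reads:
            groups.setdefault((cell, umi), set()).add((chrom, strand, pos))
        expected = {
            (k[0], *next(iter(v))) for k, v in groups.items() if len(v) == 1
        }
        out = deduplicate(reads)
        assert {(r.cell, r.chrom, r.strand, r.pos) for r in out} == expected

    def test_idempotence(self):
        reads = [
            ("A", "u1", "chr1", "+", 100),
            ("A", "u1", "chr1", "+", 100),
            ("B", "u2", "chr1", "-", 30),
        ]
        once = deduplicate(reads)
        tuples = [(r.cell, f"u{i}", r.chrom, r.strand, r.pos) for i, r in enumerate(once)]
        twice = deduplicate(tuples)
        assert sorted((r.cell, r.chrom, r.strand, r.pos) for r in once) == sorted(
            (r.cell, r.chrom, r.strand, r.pos) for r in twice
        )

    def test_missing_umi_skipped_and_counted(self):
        stats = IngestStats()
        assert deduplicate([("A", None, "chr1", "+", 5)], stats=stats) == []
        assert stats.missing_umi == 1

    def test_plate_mode_passthrough(self):
        reads = [("A", None, "chr1", "+", 5), ("A", None, "chr1", "+", 5)]
        assert len(deduplicate(reads, use_umi=False)) == 2


class TestAssignWindow:
    def test_fixed_mode_floor(self):
        spec = WindowSpec(size_bp=5000)
        assert assign_window("chr1", "+", 12345, spec) == "chr1:+:2"
        assert spec.interval_of("chr1:+:2") == ("chr1", "+", 10000, 15000)

    def test_zero_boundary(self):
        assert assign_window("chr1", "-", 0, WindowSpec(size_bp=5000)) == "chr1:-:0"

    def test_gene_mode(self):
        spec = WindowSpec(mode="gene", gene_intervals=[("chr1", 100, 500, "+", "g1")])
        assert assign_window("chr1", "+", 150, spec) == "g1"
        assert assign_window("chr1", "-", 150, spec) is None  # wrong strand
        assert assign_window("chr1", "+", 600, spec) is None  # intergenic

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(pos=st.integers(min_value=0, max_value=10**9),
           size=st.integers(min_value=1, max_value=10**6))
    def test_every_position_in_exactly_one_window_per_strand(self, pos, size):
        spec = WindowSpec(size_bp=size)
        wid = assign_window("chr1", "+", pos, spec)
        _, _, start, end = spec.interval_of(wid)
        assert start <= pos < end


class TestBuildCounts:
    def test_same_cell_same_pos_aggregates(self):
        reads = [FilteredRead("chr1", "+", 100, "A", "s")] * 2
        counts = build_counts(reads, WindowSpec(size_bp=5000))
        assert len(counts) == 1 and counts["count"].iloc[0] == 2

    def test_opposite_strands_distinct_windows(self):
        reads = [
            FilteredRead("chr1", "+", 100, "A", "s"),
            FilteredRead("chr1", "-", 100, "A", "s"),
        ]
        counts = build_counts(reads, WindowSpec(size_bp=5000))
        assert counts["window_id"].nunique() == 2

    def test_count_conservation(self, rng):
        reads = [
            FilteredRead("chr1", "+", int(rng.integers(0, 20000)), f"c{rng.integers(3)}", "s")
            for _ in range(10)
        ]
        counts = build_counts(reads, WindowSpec(size_bp=5000))
        assert counts["count"].sum() == 10

    def test_empty_input_gives_empty_table(self):
        assert build_counts([], WindowSpec()).empty


class TestSamRoundTrip:
    def test_simulated_sam_parses_and_dedups_to_truth(self, tmp_path):
        spec = SimSpec(n_cells=10, umi_dup_rate=0.5, rng_seed=11)
        sam, meta, _ = simulate_celltype_dataset(spec)
        path = tmp_path / "reads.sam"
        path.write_text(sam)
        with pysam.AlignmentFile(str(path), "r") as fh:
            raw = sum(1 for _ in fh)
        stats = IngestStats()
        counts = counts_from_alignments(
            [path], WindowSpec(size_bp=5000), stats=stats
        )
        # post-dedup molecule count equals unique UMI count (< raw records)
        assert counts["count"].sum() < raw
        assert counts["count"].sum() == stats.passed - stats.umi_duplicates_collapsed
        assert set(counts["cell"]).issubset(set(meta["cell"]))
        assert (counts["strand"] == spec.strand).all()

    def test_whitelist_restricts_cells(self, tmp_path):
        spec = SimSpec(n_cells=5, rng_seed=3)
        sam, meta, _ = simulate_celltype_dataset(spec)
        path = tmp_path / "reads.sam"
        path.write_text(sam)
        keep = set(meta["cell"][:3])
        counts = counts_from_alignments(
            [path], WindowSpec(size_bp=5000), cell_whitelist=keep
        )
        assert set(counts["cell"]).issubset(keep)
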