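"""Window/peak annotation: overlap fractions, shifted counts, UTR distances."""

import numpy as np
import pandas as pd
import pytest

from readzs.annotate import (
    Feature,
    annotate_peaks,
    annotate_windows,
    count_downstream_utr_ends,
    distance_summary,
    load_annotations,
    nearest_utr_distances,
)
from readzs.simulate import write_annotation_fixture


def windows_df(rows):
    return pd.DataFrame(rows, columns=["window_id", "chrom", "strand", "start", "end"])


class TestLoadAnnotations:
    def test_gff3_coordinates_converted(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1;gene_name=G1\n"
            "chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=t1\n"
            "chr1\tsrc\tthree_prime_UTR\t151\t200\t.\t+\t.\tID=u1\n"
        )
        feats = load_annotations(gff)
        assert len(feats) == 2  # mRNA dropped
        gene = next(f for f in feats if f.kind == "gene")
        assert (gene.start, gene.end, gene.id) == (100, 200, "G1")
        utr = next(f for f in feats if f.kind == "three_prime_UTR")
        assert (utr.start, utr.end, utr.id) == (150, 200, "u1")

    def test_duplicate_ids_kept_as_distinct_intervals(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tgene_name=G\n"
            "chr1\tsrc\tgene\t201\t300\t.\t+\t.\tgene_name=G\n"
        )
        assert len(load_annotations(gff)) == 2

    def test_round_trip_through_fixture_writer(self, tmp_path):
        text = write_annotation_fixture(
            genes=[("chr1", 500, 3000, "+", "g1")],
            utrs=[("chr1", 2000, 2786, "+", "g1.utr")],
        )
        p = tmp_path / "fix.gff3"
        p.write_text(text)
        feats = {f.kind: f for f in load_annotations(p)}
        assert (feats["gene"].start, feats["gene"].end) == (500, 3000)
        assert (feats["three_prime_UTR"].start, feats["three_prime_UTR"].end) == (2000, 2786)


class TestAnnotateWindows:
    W = windows_df([("w0", "chr1", "+", 0, 5000)])

    def test_exactly_25_percent_overlap_assigned(self):
        feats = [Feature("chr1", 3750, 6000, "+", "gene", "g")]
        out = annotate_windows(self.W, feats)  # overlap 1250 = 25% of 5000
        assert out["genes"].iloc[0] == "g"

    def test_one_bp_below_threshold_not_assigned(self):
        feats = [Feature("chr1", 3751, 6000, "+", "gene", "g")]  # overlap 1249
        out = annotate_windows(self.W, feats)
        assert out["genes"].iloc[0] == ""
        assert out["window_has_gene"].iloc[0]  # any overlap still counts here

    def test_no_overlap_means_no_gene(self):
        feats = [Feature("chr1", 9000, 9500, "+", "gene", "g")]
        out = annotate_windows(self.W, feats)
        assert not out["window_has_gene"].iloc[0]

    def test_feature_fraction_mode(self):
        feats = [Feature("chr1", 4900, 5100, "+", "gene", "g")]  # 50% of feature inside
        assert annotate_windows(self.W, feats, frac_of="feature")["genes"].iloc[0] == "g"
        assert annotate_windows(self.W, feats, frac_of="window")["genes"].iloc[0] == ""


class TestDownstreamUTRCount:
    def test_plus_strand_shifted_interval(self):
        utr = Feature("chr1", 5800, 6200, "+", "three_prime_UTR", "u")
        n = count_downstream_utr_ends(("chr1", "+", 1000, 6000), [utr], shift=300)
        assert n == 1  # end 6200 inside shifted [1300, 6300)

    def test_boundary_excluded_half_open(self):
        utr = Feature("chr1", 900, 1299, "+", "three_prime_UTR", "u")
        n = count_downstream_utr_ends(("chr1", "+", 1000, 6000), [utr], shift=300)
        assert n == 0  # end 1299 < shifted start 1300

    def test_opposite_strand_ignored(self):
        utr = Feature("chr1", 5800, 6200, "-", "three_prime_UTR", "u")
        assert count_downstream_utr_ends(("chr1", "+", 1000, 6000), [utr]) == 0

    def test_minus_strand_shift_and_clamp(self):
        utr = Feature("chr1", 50, 400, "-", "three_prime_UTR", "u")  # end coord 50
        assert count_downstream_utr_ends(("chr1", "-", 100, 600), [utr], shift=300) == 1
        # clamped window [0, 300) still half-open
        utr2 = Feature("chr1", 300, 700, "-", "three_prime_UTR", "u2")
        assert count_downstream_utr_ends(("chr1", "-", 100, 600), [utr2], shift=300) == 0


class TestNearestDistances:
    def test_plus_strand_orientation(self):
        up, down = nearest_utr_distances(5000, "+", np.array([4800, 5350]))
        assert (up, down) == (200.0, 350.0)

    def test_minus_strand_orientation_flips(self):
        up, down = nearest_utr_distances(5000, "-", np.array([4800, 5350]))
        assert (up, down) == (350.0, 200.0)

    def test_missing_side_is_nan(self):
        up, down = nearest_utr_distances(5000, "+", np.array([4000]))
        assert up == 200.0 * 5 and np.isnan(down)

    def test_agrees_with_naive_scan_on_random_fixtures(self, rng):
        for _ in range(50):
            peak = int(rng.integers(0, 10000))
            ends = rng.choice(np.arange(0, 10000), size=int(rng.integers(1, 8)), replace=False)
            strand = rng.choice(["+", "-"])
            up, down = nearest_utr_distances(peak, strand, ends)
            # oracle: O(n) linear scan
            ups = [abs(e - peak) for e in ends
                   if (e < peak if strand == "+" else e > peak)]
            downs = [abs(e - peak) for e in ends
                     if (e > peak if strand == "+" else e < peak)]
            assert (np.isnan(up) and not ups) or up == min(ups)
            assert (np.isnan(down) and not downs) or down == min(downs)

    def test_strand_antisymmetry_under_coordinate_mirror(self, rng):
        L = 100000
        for _ in range(20):
            peak = int(rng.integers(0, L))
            ends = rng.integers(0, L, size=5)
            a = nearest_utr_distances(peak, "+", ends)
            b = nearest_utr_distances(L - peak, "-", L - ends)
            assert a == b or (np.isnan(a[0]) == np.isnan(b[0]) and np.isnan(a[1]) == np.isnan(b[1]))


class TestPeakAnnotation:
    def test_constructed_distance_recovered_exactly(self):
        feats = [
            Feature("chr1", 500, 3000, "+", "gene", "g"),
            Feature("chr1", 2000, 2786, "+", "three_prime_UTR", "u"),
        ]
        peaks = pd.DataFrame(
            [{"window_id": "w0", "chrom": "chr1", "strand": "+", "mean": 2500.0}]
        )
        out = annotate_peaks(peaks, feats)
        assert out["downstream_3UTR_dist"].iloc[0] == 286.0
        assert out["peak_has_600bp_downstream_gene"].iloc[0]

    def test_downstream_gene_flag_strand_aware(self):
        feats = [Feature("chr1", 3000, 4000, "+", "gene", "g")]
        plus = pd.DataFrame([{"window_id": "w", "chrom": "chr1", "strand": "+", "mean": 2500.0}])
        minus = plus.assign(strand="-")
        assert annotate_peaks(plus, feats)["peak_has_600bp_downstream_gene"].iloc[0]
        assert not annotate_peaks(minus, feats)["peak_has_600bp_downstream_gene"].iloc[0]


class TestDistanceSummary:
    def _pann(self, dists, flag=True):
        return pd.DataFrame(
            {"window_id": [f"w{i}" for i in range(len(dists))],
             "mean": 0.0,
             "upstream_3UTR_dist": np.nan,
             "downstream_3UTR_dist": dists,
             "peak_has_600bp_downstream_gene": flag}
        )

    def test_median_of_four(self):
        q, _ = distance_summary(self._pann([100, 200, 300, 400]))
        assert q.loc[0.5] == 250.0

    def test_all_beyond_cap_gives_empty(self):
        q, hist = distance_summary(self._pann([2000, 3000]))
        assert q.empty and hist.empty

    def test_histogram_cdf_reaches_one(self):
        q, hist = distance_summary(self._pann(list(range(100, 1100, 100))), max_dist=2000)
        assert hist["cdf"].iloc[-1] == pytest.approx(1.0)
        assert hist["count"].sum() == 10
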