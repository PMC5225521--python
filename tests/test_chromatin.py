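"""DHS filtering, merging, annotation, ΔDHS and TSS openness."""

import numpy as np
import pandas as pd
import pytest

from chromreg.annotation import GeneModel, Transcript
from chromreg.chromatin import (
    annotate_dhs,
    classify_tss,
    delta_dhs,
    feature_distribution,
    filter_dhs,
    merge_adjacent,
    peak_overlap_fraction,
    select_differential,
    tss_openness,
    window_coverage,
)


def peaks_df(intervals, **cols) -> pd.DataFrame:
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    for k, v in cols.items():
        df[k] = v
    return df


class TestFilter:
    def test_boundary_inclusive_and_undercovered_removed(self, simple_peaks):
        out = filter_dhs(simple_peaks, min_reads=20)
        # 25/30 kept, 19/100 out (sample), 40/19 out (input), 100/60 kept
        assert list(out["start"]) == [100, 5000]

    def test_exact_boundary_kept(self):
        p = peaks_df([("chr1", 0, 100)], reads=20, input_reads=20)
        assert len(filter_dhs(p)) == 1

    def test_single_bp_blacklist_overlap_removes(self):
        p = peaks_df([("chr1", 100, 200)], reads=50, input_reads=50)
        bl = peaks_df([("chr1", 199, 300)])
        assert len(filter_dhs(p, blacklist=bl)) == 0
        bl_touch = peaks_df([("chr1", 200, 300)])  # half-open: no shared base
        assert len(filter_dhs(p, blacklist=bl_touch)) == 1

    def test_unsorted_input_auto_sorted(self, caplog):
        p = peaks_df([("chr1", 500, 600), ("chr1", 0, 100)], reads=50, input_reads=50)
        with caplog.at_level("INFO"):
            out = filter_dhs(p)
        assert list(out["start"]) == [0, 500]
        assert "sorting" in caplog.text

    def test_monotone_in_min_reads(self, simple_peaks):
        loose = filter_dhs(simple_peaks, min_reads=10)
        strict = filter_dhs(simple_peaks, min_reads=20)
        kept = set(map(tuple, strict[["start", "end"]].to_numpy()))
        assert kept <= set(map(tuple, loose[["start", "end"]].to_numpy()))


class TestMerge:
    def test_gap_boundary_inclusive(self):
        p = peaks_df([("chr1", 100, 200), ("chr1", 300, 400)], reads=1)
        out = merge_adjacent(p, max_gap=100)
        assert list(out[["start", "end"]].iloc[0]) == [100, 400]
        assert out["reads"].iloc[0] == 2

    def test_gap_over_boundary_unmerged(self):
        p = peaks_df([("chr1", 100, 200), ("chr1", 301, 400)], reads=1)
        assert len(merge_adjacent(p, max_gap=100)) == 2

    def test_transitive_chain_collapses_with_summed_counts(self):
        p = peaks_df(
            [("chr1", 0, 100), ("chr1", 150, 250), ("chr1", 330, 400)], reads=[3, 5, 7]
        )
        out = merge_adjacent(p, max_gap=100)
        assert len(out) == 1
        assert out["reads"].iloc[0] == 15
        assert list(out[["start", "end"]].iloc[0]) == [0, 400]

    def test_idempotent(self, rng):
        starts = np.sort(rng.integers(0, 10_000, 50))
        p = peaks_df([("chr1", s, s + 80) for s in starts], reads=1)
        once = merge_adjacent(p, 100)
        twice = merge_adjacent(once, 100)
        pd.testing.assert_frame_equal(once, twice)

    def test_source_labels_unioned(self):
        p = peaks_df([("chr1", 0, 100), ("chr1", 150, 250)], reads=1)
        p["source"] = ["vehicle", "treated"]
        out = merge_adjacent(p, 100, source_col="source")
        assert out["source"].iloc[0] == "treated,vehicle"


class TestAnnotate:
    @pytest.fixture
    def genes(self, two_tx_gene, minus_gene):
        return [two_tx_gene, minus_gene]

    def test_promoter_beats_intron(self, genes):
        # gA promoter is [8000, 10000); gA intron is (10400, 11000)
        inside_promoter = peaks_df([("chr1", 9000, 9100)])
        assert annotate_dhs(inside_promoter, genes)["feature"].iloc[0] == "promoter"

    def test_nothing_overlapping_is_intergenic(self, genes):
        out = annotate_dhs(peaks_df([("chr1", 500_000, 500_100)]), genes)
        assert out["feature"].iloc[0] == "intergenic"

    def test_exon_intron_boundary_labels_exon(self, genes):
        out = annotate_dhs(peaks_df([("chr1", 10_380, 10_450)]), genes)
        assert out["feature"].iloc[0] == "exon"

    def test_pure_intron(self, genes):
        out = annotate_dhs(peaks_df([("chr1", 10_500, 10_600)]), genes)
        assert out["feature"].iloc[0] == "intron"

    def test_unknown_chromosome_warns_intergenic(self, genes, caplog):
        with caplog.at_level("WARNING"):
            out = annotate_dhs(peaks_df([("chrX", 0, 100)]), genes)
        assert out["feature"].iloc[0] == "intergenic"
        assert "absent" in caplog.text

    def test_distribution_sums_to_one(self, genes):
        p = peaks_df([("chr1", 9000, 9100), ("chr1", 500_000, 500_100)])
        dist = feature_distribution(annotate_dhs(p, genes))
        assert dist.sum() == pytest.approx(1.0)


class TestDeltaDHS:
    def test_equal_counts_give_zero_everywhere(self):
        p = peaks_df([("chr1", i * 100, i * 100 + 50) for i in range(5)])
        p["reads_treated"] = p["reads_vehicle"] = [10, 20, 30, 40, 50]
        assert np.allclose(delta_dhs(p)["delta"], 0.0)

    def test_worked_four_peak_example(self):
        p = peaks_df([("chr1", i * 100, i * 100 + 50) for i in range(4)])
        p["reads_treated"] = [400, 0, 0, 0]
        p["reads_vehicle"] = [100, 100, 100, 100]
        out = delta_dhs(p)
        assert out["delta"].iloc[0] == pytest.approx(1.0)
        assert out["delta"].iloc[0] == out["delta"].max()

    def test_antisymmetric_under_condition_swap(self, rng):
        p = peaks_df([("chr1", i * 100, i * 100 + 50) for i in range(30)])
        p["reads_treated"] = rng.integers(0, 500, 30)
        p["reads_vehicle"] = rng.integers(0, 500, 30)
        fwd = delta_dhs(p)["delta"]
        swapped = p.rename(
            columns={"reads_treated": "reads_vehicle", "reads_vehicle": "reads_treated"}
        )
        assert np.allclose(delta_dhs(swapped)["delta"], -fwd)

    def test_mean_squared_condition_term_is_one(self, rng):
        # sum_i n_i / (total/m) = m, so the mean squared term is exactly 1
        p = peaks_df([("chr1", i * 100, i * 100 + 50) for i in range(64)])
        p["reads_treated"] = rng.integers(1, 900, 64)
        p["reads_vehicle"] = rng.integers(1, 900, 64)
        m = len(p)
        term = np.sqrt(p["reads_treated"] / (p["reads_treated"].sum() / m))
        assert np.mean(term**2) == pytest.approx(1.0)

    def test_zero_total_condition_warns_and_zeroes_term(self, caplog):
        p = peaks_df([("chr1", 0, 50), ("chr1", 100, 150)])
        p["reads_treated"] = [10, 30]
        p["reads_vehicle"] = [0, 0]
        with caplog.at_level("WARNING"):
            out = delta_dhs(p)
        assert np.allclose(out["delta"], np.sqrt(p["reads_treated"] / 20))

    @pytest.mark.parametrize(
        "delta, selected", [(0.20, True), (0.19, False), (-0.25, False)]
    )
    def test_selection_boundary(self, delta, selected):
        scores = pd.DataFrame({"delta": [delta]})
        assert (len(select_differential(scores)) == 1) is selected

    def test_closing_direction(self):
        scores = pd.DataFrame({"delta": [0.3, -0.3, 0.1]})
        assert len(select_differential(scores, direction="closing")) == 1
        assert len(select_differential(scores, direction="both")) == 2


class TestTSSOpenness:
    def _reads_at(self, chrom, positions):
        return pd.DataFrame(
            [(chrom, p, p + 50) for p in positions], columns=["chrom", "start", "end"]
        )

    def test_expression_weighted_combination(self):
        # two TSSs far apart; coverages 40 and 80; expression (30, 10)
        t1 = Transcript("g.t0", [(5_000, 5_500)])
        t2 = Transcript("g.t1", [(50_000, 50_500)])
        gene = GeneModel("g", "chr1", "+", [t1, t2])
        reads = pd.concat(
            [self._reads_at("chr1", [5_000] * 40), self._reads_at("chr1", [50_000] * 80)]
        )
        out = tss_openness([gene], reads, {"g.t0": 30, "g.t1": 10})
        assert out["weighted_coverage"].iloc[0] == pytest.approx(0.75 * 40 + 0.25 * 80)

    def test_single_transcript_passthrough(self):
        gene = GeneModel("g", "chr1", "+", [Transcript("g.t0", [(5_000, 5_500)])])
        reads = self._reads_at("chr1", [5_000] * 7)
        out = tss_openness([gene], reads, {"g.t0": 3.0})
        assert out["weighted_coverage"].iloc[0] == 7

    def test_fallback_to_other_condition_weights(self):
        t1 = Transcript("g.t0", [(5_000, 5_500)])
        t2 = Transcript("g.t1", [(50_000, 50_500)])
        gene = GeneModel("g", "chr1", "+", [t1, t2])
        reads = pd.concat(
            [self._reads_at("chr1", [5_000] * 40), self._reads_at("chr1", [50_000] * 80)]
        )
        out = tss_openness([gene], reads, {"g.t0": 0}, {"g.t0": 30, "g.t1": 10})
        assert out["fallback"].iloc[0] == "other_condition"
        assert out["weighted_coverage"].iloc[0] == pytest.approx(50.0)

    def test_unexpressed_in_both_uses_max_coverage(self):
        t1 = Transcript("g.t0", [(5_000, 5_500)])
        t2 = Transcript("g.t1", [(50_000, 50_500)])
        gene = GeneModel("g", "chr1", "+", [t1, t2])
        reads = pd.concat(
            [self._reads_at("chr1", [5_000] * 40), self._reads_at("chr1", [50_000] * 80)]
        )
        out = tss_openness([gene], reads, {}, {})
        assert out["fallback"].iloc[0] == "max_coverage"
        assert out["weighted_coverage"].iloc[0] == 80


class TestClassifyTSS:
    def test_first_quintile_order_statistic(self):
        cov = pd.Series(range(1, 11), index=[f"g{i}" for i in range(10)])
        out = classify_tss(cov)
        assert (out == "closed").sum() == 2
        assert set(cov[out == "closed"]) == {1, 2}

    def test_all_equal_is_all_closed_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = classify_tss(pd.Series([3.0] * 8))
        assert (out == "closed").all()
        assert "degenerate" in caplog.text

    def test_zero_among_large_is_closed(self):
        cov = pd.Series([0.0] + [100.0 + i for i in range(9)])
        assert classify_tss(cov).iloc[0] == "closed"

    def test_too_few_genes_all_open(self, caplog):
        with caplog.at_level("WARNING"):
            out = classify_tss(pd.Series([1.0, 2.0]))
        assert (out == "open").all()


class TestOverlapFraction:
    def test_self_overlap_is_one(self, simple_peaks):
        assert peak_overlap_fraction(simple_peaks, simple_peaks) == 1.0

    def test_disjoint_is_zero(self):
        a = peaks_df([("chr1", 0, 100)])
        b = peaks_df([("chr1", 200, 300)])
        assert peak_overlap_fraction(a, b) == 0.0

    def test_asymmetric_counting(self):
        a = peaks_df([("chr1", 0, 100), ("chr1", 200, 300)])
        b = peaks_df([("chr1", 250, 260)])
        assert peak_overlap_fraction(a, b) == 0.5
        assert peak_overlap_fraction(b, a) == 1.0

    def test_empty_a_is_an_error(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        b = peaks_df([("chr1", 0, 100)])
        with pytest.raises(ValueError):
            peak_overlap_fraction(empty, b)


def test_window_coverage_counts_each_read_once():
    reads = pd.DataFrame(
        {"chrom": ["chr1"] * 3, "start": [0, 50, 400], "end": [100, 150, 500]}
    )
    cov = window_coverage(reads, [("chr1", 40, 60), ("chr1", 300, 350)])
    assert list(cov) == [2, 0]
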