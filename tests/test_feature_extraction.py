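import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cagetss.feature_extraction import (
    build_feature_matrix,
    compute_conservation,
    compute_kmer_features,
    compute_kurtosis,
    compute_max_score_feature,
    compute_read_density,
    compute_rnaseq_difference,
    impute_missing_conservation,
    kmer_feature_names,
    make_flank_pair,
    peak_summit,
    reverse_complement,
)
from cagetss.genomic_io import GenomicInterval, ReadStartProfile, ScoreTrack
from cagetss.peak_calling import Peak

from _reference import kurtosis_brute, poisson_lower_tail_brute
from conftest import make_peak, make_profile


class TestPeakSummit:
    def test_unique_maximum(self):
        profile = make_profile(
            {"chr1": 1000},
            [("chr1", "+", 100, 3), ("chr1", "+", 105, 7), ("chr1", "+", 110, 2)],
        )
        peak = make_peak("chr1", 100, 111, "+", profile)
        assert peak_summit(peak, profile) == 105

    def test_tie_breaks_five_prime(self):
        for strand, expected in (("+", 100), ("-", 110)):
            profile = make_profile(
                {"chr1": 1000},
                [("chr1", strand, 100, 5), ("chr1", strand, 110, 5)],
            )
            peak = make_peak("chr1", 100, 111, strand, profile)
            assert peak_summit(peak, profile) == expected

    def test_single_base_peak(self):
        profile = make_profile({"chr1": 1000}, [("chr1", "+", 500, 9)])
        peak = make_peak("chr1", 500, 501, "+", profile)
        assert peak_summit(peak, profile) == 500


class TestKurtosis:
    def test_symmetric_two_point_attains_pearson_minimum(self):
        profile = make_profile(
            {"chr1": 1000}, [("chr1", "+", 0, 5), ("chr1", "+", 10, 5)]
        )
        peak = make_peak("chr1", 0, 11, "+", profile)
        assert compute_kurtosis(peak, profile) == pytest.approx(1.0)

    def test_matches_expanded_observation_oracle(self):
        profile = make_profile(
            {"chr1": 1000},
            [("chr1", "+", 0, 2), ("chr1", "+", 10, 2), ("chr1", "+", 5, 1)],
        )
        peak = make_peak("chr1", 0, 11, "+", profile)
        expected = kurtosis_brute([0, 0, 10, 10, 5])
        assert compute_kurtosis(peak, profile) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_single_base_is_nan(self):
        profile = make_profile({"chr1": 1000}, [("chr1", "+", 5, 12)])
        peak = make_peak("chr1", 5, 6, "+", profile)
        assert math.isnan(compute_kurtosis(peak, profile))

    def test_kurtosis_at_least_one_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            profile = ReadStartProfile({"chr1": 10_000})
            positions = rng.integers(100, 160, size=rng.integers(2, 50))
            if len(set(positions.tolist())) < 2:
                continue
            for pos in positions:
                profile.add("chr1", "+", int(pos))
            peak = make_peak("chr1", int(positions.min()), int(positions.max()) + 1, "+", profile)
            assert compute_kurtosis(peak, profile) >= 1.0 - 1e-12


class TestReadDensity:
    @pytest.mark.parametrize(
        "total,width,expected", [(100, 50, 2.0), (10, 1, 10.0), (10, 10, 1.0)]
    )
    def test_examples(self, total, width, expected):
        peak = Peak(GenomicInterval("chr1", 0, width, "+"), total_count=total, summit=0)
        assert compute_read_density(peak) == expected


class TestConservation:
    def _peak(self, start, end):
        return Peak(GenomicInterval("chr1", start, end, "+"), total_count=1, summit=start)

    def test_mean_over_scored_bases(self):
        track = ScoreTrack()
        track.add("chr1", 0, 1, 0.5)
        track.add("chr1", 1, 2, 1.5)
        assert compute_conservation(self._peak(0, 2), track) == pytest.approx(1.0)

    def test_unscored_peak_is_missing(self):
        assert math.isnan(compute_conservation(self._peak(0, 2), ScoreTrack()))

    def test_partial_coverage_uses_scored_bases_only(self):
        track = ScoreTrack()
        track.add("chr1", 0, 1, 2.0)
        track.add("chr1", 3, 4, 4.0)
        assert compute_conservation(self._peak(0, 4), track) == pytest.approx(3.0)


class TestImputeConservation:
    def _matrix(self, values, line="A"):
        return pd.DataFrame(
            {"cell_line": [line] * len(values), "conservation_mean": values}
        )

    def test_missing_takes_minimum(self):
        out = impute_missing_conservation(self._matrix([0.2, 0.8, np.nan]))
        assert out["conservation_mean"].tolist() == [0.2, 0.8, 0.2]

    def test_no_missing_is_identity(self):
        matrix = self._matrix([0.5, 0.7])
        pd.testing.assert_frame_equal(impute_missing_conservation(matrix), matrix)

    def test_minimum_may_be_negative(self):
        out = impute_missing_conservation(self._matrix([-1.5, 0.3, np.nan]))
        assert out["conservation_mean"].tolist() == [-1.5, 0.3, -1.5]

    def test_per_cell_line(self):
        matrix = pd.concat(
            [self._matrix([1.0, np.nan], "A"), self._matrix([5.0, np.nan], "B")],
            ignore_index=True,
        )
        out = impute_missing_conservation(matrix)
        assert out["conservation_mean"].tolist() == [1.0, 1.0, 5.0, 5.0]

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            impute_missing_conservation(self._matrix([np.nan, np.nan]))


class TestMaxScoreFeature:
    def _peak(self):
        return Peak(GenomicInterval("chr1", 1000, 1050, "+"), total_count=1, summit=1000)

    def test_extension_reaches_both_sides(self):
        track = ScoreTrack()
        track.add("chr1", 940, 960, 3.0)
        track.add("chr1", 1090, 1110, 7.0)
        assert compute_max_score_feature(self._peak(), track, 100) == 7.0

    def test_no_signal_in_reach_gives_zero(self):
        track = ScoreTrack()
        track.add("chr1", 5000, 5100, 9.0)
        assert compute_max_score_feature(self._peak(), track, 100) == 0.0

    def test_straddling_interval_counts(self):
        track = ScoreTrack()
        track.add("chr1", 880, 905, 4.0)  # overlaps [900, 1150) by 5 bases
        assert compute_max_score_feature(self._peak(), track, 100) == 4.0

    def test_monotone_in_extension(self):
        rng = np.random.default_rng(8)
        track = ScoreTrack()
        for _ in range(50):
            start = int(rng.integers(0, 5000))
            track.add("chr1", start, start + int(rng.integers(1, 100)), float(rng.random()))
        values = [compute_max_score_feature(self._peak(), track, ext)
                  for ext in (0, 10, 50, 100, 500, 2000)]
        assert values == sorted(values)


class TestKmerFeatures:
    def test_column_count_is_512(self):
        assert len(kmer_feature_names(4)) == 512
        assert len({c for c in kmer_feature_names(4)}) == 512
        assert sum(c.startswith("up_") for c in kmer_feature_names(4)) == 256

    def test_overlapping_occurrences_counted(self):
        # upstream window of 8 bases = "ACGTACGT": 5 scanned 4-mers, ACGT twice
        genome = {"chr1": "ACGTACGT" + "A" * 100}
        counts = compute_kmer_features(8, "+", genome, "chr1", k=4, window=8)
        names = kmer_feature_names(4)
        assert counts[names.index("up_ACGT")] == 2
        assert counts[: len(names) // 2].sum() == 5

    def test_poly_a_window(self):
        genome = {"chr1": "A" * 1200}
        counts = compute_kmer_features(600, "+", genome, "chr1")
        names = kmer_feature_names(4)
        up = counts[: 256]
        assert up[names.index("up_AAAA")] == 497
        assert up.sum() == 497

    def test_total_counts_conserve_positions(self, small_genome):
        counts = compute_kmer_features(2500, "+", small_genome, "chr1")
        assert counts[:256].sum() == 500 - 3
        assert counts[256:].sum() == 500 - 3

    def test_non_acgt_kmers_skipped(self):
        genome = {"chr1": "ACGTNACGT" + "C" * 100}
        counts = compute_kmer_features(9, "+", genome, "chr1", k=4, window=9)
        assert counts[:256].sum() == 2  # only the two N-free 4-mers

    def test_strand_mirror_invariance(self, small_genome):
        seq = small_genome["chr1"]
        mirrored = {"chr1": reverse_complement(seq)}
        summit = 2500
        mirrored_summit = len(seq) - 1 - summit
        fwd = compute_kmer_features(summit, "+", small_genome, "chr1")
        rev = compute_kmer_features(mirrored_summit, "-", mirrored, "chr1")
        assert (fwd == rev).all()

    def test_edge_truncation(self):
        genome = {"chr1": "A" * 1000}
        counts = compute_kmer_features(2, "+", genome, "chr1")
        assert counts[:256].sum() == 0  # upstream window has width 2 < k


class TestRnaseqDifference:
    def _peak(self, strand="+"):
        return Peak(GenomicInterval("chr1", 1000, 1050, strand), total_count=1, summit=1000)

    def test_empty_flanks_give_one(self):
        rnaseq = ReadStartProfile({"chr1": 5000})
        assert compute_rnaseq_difference(self._peak(), rnaseq) == 1.0

    def test_downstream_only_matches_single_term(self):
        rnaseq = make_profile({"chr1": 5000}, [("chr1", "+", 1060, 10)])
        value = compute_rnaseq_difference(self._peak(), rnaseq)
        assert value == pytest.approx(math.exp(-10), rel=1e-12)

    def test_balanced_flanks_match_partial_sum(self):
        rnaseq = make_profile(
            {"chr1": 5000}, [("chr1", "+", 950, 5), ("chr1", "+", 1060, 5)]
        )
        value = compute_rnaseq_difference(self._peak(), rnaseq)
        assert value == pytest.approx(poisson_lower_tail_brute(5, 5.0), rel=1e-12)

    def test_minus_strand_swaps_flanks(self):
        rnaseq = make_profile({"chr1": 5000}, [("chr1", "+", 950, 10)])
        plus = compute_rnaseq_difference(self._peak("+"), rnaseq)   # upstream-heavy
        minus = compute_rnaseq_difference(self._peak("-"), rnaseq)  # downstream-heavy
        assert plus == 1.0
        assert minus == pytest.approx(math.exp(-10), rel=1e-12)

    def test_counts_both_strands(self):
        rnaseq = make_profile(
            {"chr1": 5000}, [("chr1", "+", 1060, 3), ("chr1", "-", 1070, 4)]
        )
        value = compute_rnaseq_difference(self._peak(), rnaseq)
        assert value == pytest.approx(math.exp(-7), rel=1e-12)


class TestFlankPair:
    def test_plus_strand(self):
        peak = Peak(GenomicInterval("chr1", 1000, 1050, "+"), total_count=1, summit=1000)
        pair = make_flank_pair(peak)
        assert (pair.upstream.start, pair.upstream.end) == (900, 1000)
        assert (pair.downstream.start, pair.downstream.end) == (1050, 1150)

    def test_minus_strand(self):
        peak = Peak(GenomicInterval("chr1", 1000, 1050, "-"), total_count=1, summit=1000)
        pair = make_flank_pair(peak)
        assert (pair.upstream.start, pair.upstream.end) == (1050, 1150)
        assert (pair.downstream.start, pair.downstream.end) == (900, 1000)

    def test_edge_truncation(self):
        peak = Peak(GenomicInterval("chr1", 0, 50, "+"), total_count=1, summit=0)
        assert make_flank_pair(peak).upstream is None


class TestBuildFeatureMatrix:
    def _setup(self, small_genome):
        profile = make_profile(
            {"chr1": 5000},
            [("chr1", "+", 1000 + i, 3) for i in range(10)]
            + [("chr1", "-", 3000, 15)],
        )
        peaks = [
            make_peak("chr1", 1000, 1010, "+", profile),
            make_peak("chr1", 3000, 3001, "-", profile),
        ]
        return profile, peaks

    def test_internal_columns(self, small_genome):
        profile, peaks = self._setup(small_genome)
        matrix = build_feature_matrix(peaks, profile, small_genome, "lineA")
        assert list(matrix.columns) == ["cell_line", "kurtosis", "read_density"] + kmer_feature_names(4)
        assert len(matrix) == 2
        assert not matrix.drop(columns="cell_line").isna().any().any()

    def test_full_scenario_columns(self, small_genome):
        profile, peaks = self._setup(small_genome)
        tracks = {name: ScoreTrack() for name in ("tfbs", "dnase", "h3k4me3", "conservation")}
        tracks["conservation"].add("chr1", 0, 5000, 1.0)
        rnaseq = make_profile({"chr1": 5000}, [("chr1", "+", 1100, 2)])
        matrix = build_feature_matrix(
            peaks, profile, small_genome, "lineA", tracks=tracks, rnaseq_profile=rnaseq
        )
        expected_extra = ["tfbs_max", "dnase_max", "h3k4me3_max", "conservation_mean", "rnaseq_diff"]
        assert list(matrix.columns)[-5:] == expected_extra

    def test_zero_peaks_empty_matrix_with_header(self, small_genome):
        profile, _ = self._setup(small_genome)
        matrix = build_feature_matrix([], profile, small_genome, "lineA")
        assert len(matrix) == 0
        assert "kurtosis" in matrix.columns and "up_AAAA" in matrix.columns

    def test_degenerate_kurtosis_gets_cell_line_max(self, small_genome):
        profile, peaks = self._setup(small_genome)
        matrix = build_feature_matrix(peaks, profile, small_genome, "lineA")
        # second peak is single-base (degenerate) -> takes the max of the others
        assert matrix["kurtosis"].iloc[1] == matrix["kurtosis"].iloc[0]
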