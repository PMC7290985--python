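"""Sliding-window ROH detection against brute-force oracles, length
classes and the length-generation dating formula."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autozyg import (
    GenotypeMatrix,
    MISSING,
    ROHParams,
    classify_length,
    detect_roh,
    expected_length,
    generations_from_length,
    scan_windows,
    summarize_roh,
)
from autozyg.genotypes import MarkerMap
from autozyg.roh import segments_to_frame
from helpers import random_roh_chromosome, roh_intervals_oracle, toy_marker_map, window_proportions_oracle


def chromosome_fixture(calls, positions, chrom="chr1"):
    calls = np.asarray(calls, dtype=np.int8).reshape(1, -1)
    mmap = MarkerMap.from_arrays(
        [f"m{i}" for i in range(calls.shape[1])],
        [chrom] * calls.shape[1],
        list(positions),
    )
    return GenotypeMatrix(["ind"], calls, "pop"), mmap


class TestScanWindows:
    def test_all_homozygous_gives_one_everywhere(self):
        assert (scan_windows(np.zeros(120, dtype=np.int8)) == 1.0).all()

    def test_all_heterozygous_gives_zero_everywhere(self):
        assert (scan_windows(np.ones(120, dtype=np.int8)) == 0.0).all()

    def test_single_het_matches_quadratic_enumerator(self):
        calls = np.zeros(200, dtype=np.int8)
        calls[100] = 1
        params = ROHParams(max_het_in_window=0)
        expected = window_proportions_oracle(calls, params)
        np.testing.assert_allclose(scan_windows(calls, params), expected)

    @pytest.mark.parametrize("n_snp", [30, 49, 50, 73, 211])
    def test_matches_quadratic_enumerator_on_random_input(self, n_snp, rng):
        """Vectorised scan equals direct window enumeration, including the
        short-chromosome single-window case."""
        calls = rng.choice(
            np.array([0, 1, 2, MISSING], dtype=np.int8),
            size=n_snp,
            p=[0.5, 0.2, 0.25, 0.05],
        )
        params = ROHParams()
        np.testing.assert_allclose(
            scan_windows(calls, params),
            window_proportions_oracle(calls, params),
        )


class TestDetectROH:
    def test_homozygous_chromosome_single_segment(self):
        """60 evenly spaced SNPs over 2 Mb: one maximal run, class 2-4 Mb."""
        positions = np.linspace(1, 2_000_001, 60).astype(np.int64)
        g, mmap = chromosome_fixture(np.zeros(60), positions)
        segments = detect_roh(g, mmap)
        assert len(segments) == 1
        seg = segments[0]
        assert (seg.start_bp, seg.end_bp) == (1, 2_000_001)
        assert seg.n_snp == 60
        assert seg.length_class == "2-4"

    def test_oversized_gap_splits_and_kills_short_halves(self):
        """A 600 kb gap at the midpoint splits the run; each 30-SNP half
        fails the 50-SNP minimum."""
        spacing = np.full(59, (2_000_000 - 600_000) // 58)
        spacing[29] = 600_000
        positions = np.concatenate([[1], 1 + np.cumsum(spacing)])
        g, mmap = chromosome_fixture(np.zeros(60), positions)
        assert detect_roh(g, mmap) == []

    def test_equals_bruteforce_enumerator_on_random_chromosomes(self):
        """Window+run detection is identical to interval-wise brute force
        on random 300-SNP chromosomes (a small slice of the acceptance
        sweep)."""
        params = ROHParams()
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            calls, positions = random_roh_chromosome(300, rng)
            g, mmap = chromosome_fixture(calls, positions)
            got = {
                (s.start_bp, s.end_bp, s.n_snp) for s in detect_roh(g, mmap, params)
            }
            want = set(roh_intervals_oracle(calls, positions, params))
            assert got == want, f"seed {seed}"

    @pytest.mark.parametrize(
        "relax",
        [
            {"min_snp": 30},
            {"min_length_bp": 500_000},
            {"max_gap_bp": 1_000_000},
            {"min_density_bp_per_snp": 100_000},
            {"max_het_in_window": 2},
        ],
    )
    def test_relaxing_a_threshold_never_loses_segments(self, relax, rng):
        calls, positions = random_roh_chromosome(400, rng)
        g, mmap = chromosome_fixture(calls, positions)
        n_strict = len(detect_roh(g, mmap, ROHParams()))
        n_relaxed = len(detect_roh(g, mmap, ROHParams(**relax)))
        assert n_relaxed >= n_strict

    def test_total_roh_length_bounded_by_genome_span(self, study_design, study_segments):
        span = study_design.marker_map.l_auto_bp
        for segs in study_segments.values():
            frame = segments_to_frame(segs)
            per_ind = frame.groupby("individual_id")["length_bp"].sum()
            assert (per_ind <= span).all()

    def test_detects_implanted_autozygous_tract(self):
        """An individual built from founder haplotypes with one 10 Mb
        identical-by-descent tract yields a detected segment overlapping
        it >= 90% reciprocally."""
        from autozyg import GenomeSpec, simulate_founders

        founders = simulate_founders(
            5, GenomeSpec((30_000_000,), markers_per_mb=100.0), seed=5
        )
        lo, hi = 10_000_000, 20_000_000
        pos = founders.marker_map.positions
        hap_a = founders.haplotype_alleles[0]
        hap_b = np.where(
            (pos > lo) & (pos <= hi), hap_a, founders.haplotype_alleles[1]
        )
        g = GenotypeMatrix(
            ["x"], (hap_a + hap_b).astype(np.int8).reshape(1, -1), "sim"
        )
        segments = detect_roh(g, founders.marker_map)
        overlaps = [
            (min(s.end_bp, hi) - max(s.start_bp, lo)) for s in segments
        ]
        assert overlaps, "tract not detected at all"
        best = segments[int(np.argmax(overlaps))]
        ov = max(overlaps)
        assert ov / (hi - lo) >= 0.9
        assert ov / best.length_bp >= 0.9

    def test_correlates_with_true_autozygous_length(self, study_design, study_segments):
        """Detected total ROH length tracks true autozygous length with
        r > 0.9 when line breeding generates the F variance."""
        truth = study_design.truth
        totals, trues = [], []
        for name, g in study_design.populations.items():
            frame = segments_to_frame(study_segments[name])
            per_ind = frame.groupby("individual_id")["length_bp"].sum()
            for iid in g.individual_ids:
                totals.append(per_ind.get(iid, 0))
                trues.append(truth.true_autozygosity(iid))
        assert np.corrcoef(totals, trues)[0, 1] > 0.9


class TestLengthClasses:
    @pytest.mark.parametrize(
        "length_bp,label",
        [
            (1_000_000, "1-2"),
            (1_999_999, "1-2"),
            (2_000_000, "2-4"),
            (7_999_999, "4-8"),
            (8_000_000, "8-16"),
            (16_000_000, ">16"),   # boundary assigned upward
            (61_820_000, ">16"),   # longest run scale seen on real arrays
        ],
    )
    def test_half_open_bins(self, length_bp, label):
        assert classify_length(length_bp) == label

    def test_below_minimum_is_error(self):
        with pytest.raises(ValueError):
            classify_length(999_999)


class TestGenerationDating:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
    def test_property_exact_reciprocal_pair(self, length_mb):
        g = generations_from_length(length_mb)
        assert expected_length(g) == pytest.approx(length_mb, rel=1e-12)

    def test_known_lengths(self):
        assert generations_from_length(1.0) == pytest.approx(50.0)
        assert generations_from_length(4.0) == pytest.approx(12.5)
        assert expected_length(50.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("g", [0.5, 3, 6, 12.5, 20, 50])
    def test_reciprocal_pair(self, g):
        assert generations_from_length(expected_length(g)) == pytest.approx(g)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            generations_from_length(0)
        with pytest.raises(ValueError):
            expected_length(-1)


class TestSummaries:
    def test_zero_segments_reported_absent_not_zero(self):
        mmap = toy_marker_map(10)
        out = summarize_roh([], ["a", "b"], mmap)
        per_class = out["per_class"].set_index("length_class")
        assert per_class.loc[">16", "n_segments"] == 0
        assert np.isnan(per_class.loc[">16", "mean_length_mb"])
        assert (out["per_individual"]["n_segments"] == 0).all()

    def test_single_segment_summary(self):
        positions = np.linspace(1, 3_000_001, 80).astype(np.int64)
        g, mmap = chromosome_fixture(np.zeros(80), positions)
        segments = detect_roh(g, mmap)
        out = summarize_roh(segments, ["ind", "other"], mmap)
        per_class = out["per_class"].set_index("length_class")
        assert per_class.loc["ALL", "n_segments"] == 1
        assert per_class.loc["2-4", "mean_length_mb"] == pytest.approx(3.0)
        # both denominators exposed: all individuals vs carriers only
        assert per_class.loc["ALL", "mean_count_all"] == pytest.approx(0.5)
        assert per_class.loc["ALL", "mean_count_with_roh"] == pytest.approx(1.0)

    def test_aggregation_matches_independent_sums(self, study_design, study_segments):
        name = "POP_A"
        g = study_design.populations[name]
        out = summarize_roh(
            study_segments[name], g.individual_ids, study_design.marker_map
        )
        frame = segments_to_frame(study_segments[name])
        # independent aggregation: plain python sums per individual
        totals = {iid: 0 for iid in g.individual_ids}
        counts = {iid: 0 for iid in g.individual_ids}
        for row in frame.itertuples():
            totals[row.individual_id] += row.length_bp
            counts[row.individual_id] += 1
        per_ind = out["per_individual"].set_index("individual_id")
        for iid in g.individual_ids:
            assert per_ind.loc[iid, "total_length_bp"] == totals[iid]
            assert per_ind.loc[iid, "n_segments"] == counts[iid]
        assert out["per_class"].loc[0, "mean_count_all"] == pytest.approx(
            sum(counts.values()) / len(counts)
        )
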