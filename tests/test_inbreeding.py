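"""F_ROH / F_HOM / F_GRM identities, simulations with known truth, and
the estimator-comparison statistics."""

import numpy as np
import pandas as pd
import pytest

from autozyg import (
    DEFAULT_L_AUTO_BP,
    GenotypeMatrix,
    MISSING,
    build_grm,
    compare_estimators,
    f_grm,
    f_hom,
    f_roh,
    f_roh_table,
)
from autozyg.inbreeding import correlation_table, f_roh_per_chromosome, group_difference_table
from autozyg.roh import ROHSegment, classify_length, segments_to_frame


def make_segment(iid, chrom, start, length):
    return ROHSegment(
        individual_id=iid, chromosome=chrom, start_bp=start,
        end_bp=start + length, n_snp=max(50, length // 50_000),
        length_bp=length, length_class=classify_length(length),
    )


class TestFROH:
    def test_no_segments_gives_zero(self):
        assert f_roh(pd.DataFrame(columns=["individual_id", "chromosome",
                                           "start_bp", "end_bp", "length_bp"]),
                     DEFAULT_L_AUTO_BP) == 0.0

    def test_exact_ratio(self):
        seg = make_segment("x", "chr1", 1, 168_579_000)
        assert f_roh([seg], DEFAULT_L_AUTO_BP) == pytest.approx(0.1)

    def test_cohort_scale_ratio(self):
        """239.38 Mb of runs over a 1685.79 Mb genome is F_ROH = 0.142."""
        segs = [
            make_segment("x", "chr1", 1, 139_380_000),
            make_segment("x", "chr2", 1, 100_000_000),
        ]
        assert f_roh(segs, DEFAULT_L_AUTO_BP) == pytest.approx(0.142, abs=5e-4)

    def test_overlapping_segments_rejected(self):
        segs = [
            make_segment("x", "chr1", 1, 2_000_000),
            make_segment("x", "chr1", 1_500_000, 2_000_000),
        ]
        with pytest.raises(ValueError, match="overlap"):
            f_roh(segs, DEFAULT_L_AUTO_BP)

    def test_min_length_threshold_filters(self):
        segs = [
            make_segment("x", "chr1", 1, 1_500_000),
            make_segment("x", "chr2", 1, 5_000_000),
        ]
        assert f_roh(segs, 6_500_000, min_length_mb=4) == pytest.approx(
            5_000_000 / 6_500_000
        )

    def test_threshold_table_non_increasing_and_anchored(self, study_design, study_segments):
        """F_ROH at growing minimum lengths never increases, and the
        >=1 Mb column equals genome-wide F_ROH, for every simulated
        individual."""
        l_auto = study_design.marker_map.l_auto_bp
        for name, g in study_design.populations.items():
            table = f_roh_table(study_segments[name], g.individual_ids, l_auto)
            cols = [f"f_roh_ge_{t}mb" for t in (1, 2, 4, 8, 16)]
            values = table[cols].to_numpy()
            assert (np.diff(values, axis=1) <= 1e-15).all()
            np.testing.assert_allclose(table["f_roh_ge_1mb"], table["f_roh_all"])
            assert ((values >= 0) & (values <= 1)).all()

    def test_per_chromosome_sums_to_genome_wide(self, study_design, study_segments):
        mmap = study_design.marker_map
        g = study_design.populations["POP_A"]
        per_chrom = f_roh_per_chromosome(
            study_segments["POP_A"], g.individual_ids, mmap
        ).set_index("individual_id")
        spans = mmap.chrom_spans_bp()
        total_bp = sum(
            per_chrom[c] * spans[c] for c in mmap.chromosomes
        )
        frame = segments_to_frame(study_segments["POP_A"])
        expected = frame.groupby("individual_id")["length_bp"].sum()
        for iid in g.individual_ids:
            assert total_bp[iid] == pytest.approx(expected.get(iid, 0))


class TestFHOM:
    def test_fully_homozygous_individual_gives_one(self):
        calls = np.array([[0, 2, 0, 2], [0, 1, 1, 2]], dtype=np.int8)
        g = GenotypeMatrix(["hom", "het"], calls, "p")
        values = f_hom(g, np.full(4, 0.5))
        assert values["hom"] == pytest.approx(1.0)

    def test_observed_equals_expected_gives_zero(self):
        # p = 0.5 at 2 markers: E_hom per marker = 0.5; one hom + one het
        calls = np.array([[0, 1]], dtype=np.int8)
        g = GenotypeMatrix(["x"], calls, "p")
        assert f_hom(g, np.array([0.5, 0.5]))["x"] == pytest.approx(0.0)

    def test_three_marker_hand_arithmetic(self):
        """O=2, E=1.5, N=3 at p=0.5 everywhere: F = (2-1.5)/(3-1.5) = 1/3."""
        calls = np.array([[0, 2, 1]], dtype=np.int8)
        g = GenotypeMatrix(["x"], calls, "p")
        assert f_hom(g, np.full(3, 0.5))["x"] == pytest.approx(1 / 3)

    def test_missing_markers_excluded_from_O_and_E(self):
        calls = np.array([[0, 2, 1, MISSING]], dtype=np.int8)
        g = GenotypeMatrix(["x"], calls, "p")
        # marker 4 missing -> identical to the 3-marker case
        assert f_hom(g, np.full(4, 0.5))["x"] == pytest.approx(1 / 3)

    def test_all_fixed_markers_flagged_undefined(self):
        calls = np.array([[0, 0]], dtype=np.int8)
        g = GenotypeMatrix(["x"], calls, "p")
        assert np.isnan(f_hom(g, np.array([0.0, 0.0]))["x"])

    def test_in_sample_mean_is_near_zero_for_unrelated_cohort(self):
        """With in-sample frequencies the mean of F_HOM is ~0 by
        construction for an unstructured random-mating sample."""
        rng = np.random.default_rng(3)
        p = rng.uniform(0.05, 0.5, size=4000)
        dose = (
            (rng.random((150, 4000)) < p).astype(np.int8)
            + (rng.random((150, 4000)) < p).astype(np.int8)
        )
        g = GenotypeMatrix([f"i{k}" for k in range(150)], dose, "hwe")
        assert abs(f_hom(g).mean()) < 0.01

    def test_admixed_cohort_is_most_negative(self, study_design):
        """An F1 cross of two diverged lines shows excess heterozygosity
        relative to its own pooled frequencies, so its mean F_HOM sits
        well below both parental lines'."""
        means = {
            name: f_hom(g).mean()
            for name, g in study_design.populations.items()
        }
        assert means["POP_C"] < means["POP_A"]
        assert means["POP_C"] < means["POP_B"]
        assert means["POP_C"] < -0.05


class TestGRM:
    def test_single_het_individual_hand_value(self):
        g = GenotypeMatrix(["x"], np.array([[1]], dtype=np.int8), "p")
        grm = build_grm(g, np.array([0.5]))
        assert grm.matrix[0, 0] == pytest.approx(0.0)
        assert f_grm(grm)["x"] == pytest.approx(-1.0)

    def test_fully_homozygous_individual_hand_value(self):
        m = 10
        calls = np.array([[0, 2] * (m // 2)], dtype=np.int8)
        g = GenotypeMatrix(["x"], calls, "p")
        grm = build_grm(g, np.full(m, 0.5))
        # z = +-1 per marker -> G_jj = m / (2 m 0.25) = 2 -> F = 1
        assert grm.matrix[0, 0] == pytest.approx(2.0)
        assert f_grm(grm)["x"] == pytest.approx(1.0)
        assert f_grm(grm, mode="two_gjj_minus_1")["x"] == pytest.approx(3.0)

    def test_unrelated_hwe_cohort_centres_on_zero(self):
        """200 unrelated HWE individuals x 5000 markers: mean F_GRM and
        mean F_HOM both within their sampling tolerance of zero."""
        rng = np.random.default_rng(11)
        p = rng.uniform(0.05, 0.5, size=5000)
        dose = (
            (rng.random((200, 5000)) < p).astype(np.int8)
            + (rng.random((200, 5000)) < p).astype(np.int8)
        )
        g = GenotypeMatrix([f"i{k}" for k in range(200)], dose, "hwe")
        assert abs(f_grm(build_grm(g)).mean()) < 0.02
        assert abs(f_hom(g).mean()) < 0.01

    def test_marker_permutation_invariance_and_symmetry(self, rng):
        calls = rng.integers(0, 3, size=(12, 80)).astype(np.int8)
        g = GenotypeMatrix([f"i{k}" for k in range(12)], calls, "p")
        grm = build_grm(g)
        perm = rng.permutation(80)
        grm_perm = build_grm(g.subset_markers(perm))
        np.testing.assert_allclose(grm.matrix, grm_perm.matrix, atol=1e-12)
        np.testing.assert_allclose(grm.matrix, grm.matrix.T, atol=1e-12)

    def test_monomorphic_only_input_rejected(self):
        g = GenotypeMatrix(["a", "b"], np.zeros((2, 4), dtype=np.int8), "p")
        with pytest.raises(ValueError, match="polymorphic"):
            build_grm(g)


class TestComparison:
    @staticmethod
    def _table(rng):
        rows = []
        for pop, shift in (("A", 0.10), ("B", 0.12), ("C", 0.00)):
            f = np.clip(rng.normal(shift, 0.03, size=40), 0, 1)
            rows.append(
                pd.DataFrame(
                    {
                        "population": pop,
                        "f_roh_all": f,
                        "f_hom": 2.0 * f - 0.1,      # exact linear transform
                        "f_grm": f + rng.normal(0, 0.005, size=40),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_self_correlation_is_one(self, rng):
        table = self._table(rng)
        corr = correlation_table(table, ["f_roh_all", "f_hom"])
        self_rows = corr[corr.estimator_a == corr.estimator_b]
        np.testing.assert_allclose(self_rows["r"].dropna(), 1.0)

    def test_antimonotone_vectors_give_minus_one(self):
        table = pd.DataFrame(
            {"population": "A", "f_roh_all": [1, 2, 3], "f_hom": [3, 2, 1]}
        )
        corr = correlation_table(table, ["f_roh_all", "f_hom"]).set_index(
            ["group", "estimator_a", "estimator_b"]
        )
        assert corr.loc[("ALL", "f_roh_all", "f_hom"), "r"] == pytest.approx(-1.0)

    def test_linear_transform_recovers_high_correlation(self, rng):
        corr = correlation_table(self._table(rng), ["f_roh_all", "f_hom"])
        row = corr[(corr.estimator_a == "f_roh_all") & (corr.estimator_b == "f_hom")]
        assert (row["r"] > 0.99).all()

    def test_zero_variance_reported_absent(self):
        table = pd.DataFrame(
            {"population": "A", "f_roh_all": [0.1, 0.1, 0.1], "f_hom": [1, 2, 3.0]}
        )
        corr = correlation_table(table, ["f_roh_all", "f_hom"]).set_index(
            ["group", "estimator_a", "estimator_b"]
        )
        assert np.isnan(corr.loc[("A", "f_roh_all", "f_hom"), "r"])

    def test_letter_display_separates_distinct_groups(self, rng):
        table = self._table(rng)
        tests = group_difference_table(table, ["f_roh_all"]).set_index("population")
        # C is far below A and B -> shares no letter with either
        assert not set(tests.loc["C", "letters"]) & set(tests.loc["A", "letters"])
        assert not set(tests.loc["C", "letters"]) & set(tests.loc["B", "letters"])

    def test_letter_display_joins_equal_groups(self, rng):
        base = rng.normal(0.1, 0.03, size=50)
        table = pd.concat(
            [
                pd.DataFrame({"population": p, "f_roh_all": base})
                for p in ("A", "B")
            ],
            ignore_index=True,
        )
        tests = group_difference_table(table, ["f_roh_all"]).set_index("population")
        assert set(tests.loc["A", "letters"]) & set(tests.loc["B", "letters"])

    def test_bundle_contains_both_tables(self, rng):
        out = compare_estimators(self._table(rng))
        assert set(out) == {"correlations", "group_tests"}
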