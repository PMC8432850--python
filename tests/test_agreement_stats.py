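"""Equivalence testing, weighted kappa, binning, and report assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icd2iss import synthetic
from icd2iss.agreement_stats import (
    GROUP_BOUNDS,
    bonferroni,
    compare_report,
    crosstab,
    equivalence_verdict,
    group_abs_diff_summary,
    iss_group,
    kappa_band,
    nhst_wilcoxon,
    paired_tost,
    tost_power,
    tost_sample_size,
    weighted_kappa,
)


class TestIssGroup:
    @pytest.mark.parametrize(
        "iss, group",
        [(0, 1), (8, 1), (9, 2), (15, 2), (16, 3), (24, 3), (25, 4),
         (40, 4), (41, 5), (49, 5), (50, 6), (75, 6)],
    )
    def test_boundaries(self, iss, group):
        assert iss_group(iss) == group

    def test_partition_of_0_75(self):
        """Every integer score maps to exactly one group."""
        for iss in range(76):
            hits = [g for g, (lo, hi) in enumerate(GROUP_BOUNDS, 1)
                    if lo <= iss <= hi]
            assert len(hits) == 1
            assert iss_group(iss) == hits[0]

    @pytest.mark.parametrize("iss", [-1, 76])
    def test_out_of_range_rejected(self, iss):
        with pytest.raises(ValueError):
            iss_group(iss)


class TestCrosstab:
    def test_conservation(self):
        pairs = synthetic.generate_paired_scores(
            synthetic.GeneratorConfig(n_patients=640, seed=3)
        )
        tab = crosstab(pairs["manual_iss"], pairs["auto_iss"])
        assert tab.total == 640

    def test_identical_scores_are_diagonal(self):
        scores = [0, 9, 16, 25, 41, 50, 75]
        tab = crosstab(scores, scores)
        assert tab.counts.sum() == np.trace(tab.counts)


def _kappa_oracle(counts, weighting):
    """Brute-force double sum, coded independently of the implementation."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    k = counts.shape[0]
    rows = counts.sum(axis=1) / n
    cols = counts.sum(axis=0) / n
    po = pe = 0.0
    for i in range(k):
        for j in range(k):
            if weighting == "linear":
                w = 1 - abs(i - j) / (k - 1)
            else:
                w = 1 - (i - j) ** 2 / (k - 1) ** 2
            po += w * counts[i, j] / n
            pe += w * rows[i] * cols[j]
    return (po - pe) / (1 - pe)


class TestWeightedKappa:
    def test_published_crosstab_gives_moderate_047(self):
        res = weighted_kappa(synthetic.table3_counts(), "linear")
        assert round(res.kappa, 2) == 0.47
        assert res.band == "moderate"

    def test_diagonal_table_is_one(self):
        tab = np.diag([5, 1, 9, 2, 7, 3])
        assert weighted_kappa(tab).kappa == pytest.approx(1.0)

    def test_outer_product_table_is_zero(self):
        rows = np.array([10, 20, 5, 8, 3, 4], float)
        cols = np.array([7, 1, 12, 9, 2, 6], float)
        assert weighted_kappa(np.outer(rows, cols)).kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_sum_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            tab = rng.integers(0, 30, size=(6, 6))
            if tab.sum() == 0:
                continue
            for weighting in ("linear", "quadratic"):
                got = weighted_kappa(tab, weighting).kappa
                assert got == pytest.approx(_kappa_oracle(tab, weighting))

    def test_invariant_under_count_scaling(self):
        tab = synthetic.table3_counts().counts
        assert weighted_kappa(tab).kappa == pytest.approx(
            weighted_kappa(tab * 17).kappa
        )

    def test_degenerate_single_cell_rejected(self):
        tab = np.zeros((6, 6))
        tab[2, 2] = 50
        with pytest.raises(ValueError, match="degenerate"):
            weighted_kappa(tab)

    @pytest.mark.parametrize(
        "kappa, band",
        [(0.1, "poor"), (0.2, "poor"), (0.21, "fair"), (0.4, "fair"),
         (0.47, "moderate"), (0.61, "good"), (0.81, "excellent")],
    )
    def test_interpretation_bands(self, kappa, band):
        assert kappa_band(kappa) == band


class TestPairedTost:
    def test_mean_at_upper_bound_gives_half(self):
        diffs = np.array([2.0, 3.0, 4.0, 2.0, 4.0, 3.0])  # mean exactly 3
        res = paired_tost(diffs, -3, 3)
        assert res.p_upper == pytest.approx(0.5)

    def test_large_centered_sample_clearly_equivalent(self):
        rng = np.random.default_rng(0)
        res = paired_tost(rng.normal(0, 1, 1000), -3, 3)
        assert res.p_tost < 1e-6

    def test_p_tost_is_max_of_one_sided(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            res = paired_tost(rng.normal(rng.uniform(-4, 4), 2, 20), -3, 3)
            assert res.p_tost == max(res.p_lower, res.p_upper)
            assert res.ci_low <= res.mean_diff <= res.ci_high

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            paired_tost([1.0])

    def test_zero_variance_flagged_not_fatal(self):
        res = paired_tost([1.0, 1.0, 1.0])
        assert "zero_variance" in res.flags
        assert res.p_tost == 0.0  # constant 1 inside (-3, 3)
        outside = paired_tost([5.0, 5.0])
        assert outside.p_tost == 1.0

    def test_widening_bounds_never_flips_verdict_true_to_false(self):
        rng = np.random.default_rng(5)
        diffs = rng.normal(1.0, 2.0, 60)
        narrow = paired_tost(diffs, -3, 3)
        wide = paired_tost(diffs, -6, 6)
        if narrow.p_tost <= 0.05:
            assert wide.p_tost <= 0.05


class TestWilcoxon:
    def test_symmetric_differences_not_significant(self):
        diffs = [1, -1, 2, -2, 3, -3, 4, -4]
        assert nhst_wilcoxon(diffs) > 0.5

    def test_all_positive_ones_exact_tail(self):
        # one-sided exact tail is 2^-20; two-sided about 1.9e-6
        p = nhst_wilcoxon([1.0] * 20)
        assert p == pytest.approx(2 * 2 ** -20, rel=0.05)

    def test_all_zero_differences_convention(self):
        assert nhst_wilcoxon([0.0, 0.0, 0.0]) == 1.0


class TestVerdict:
    @pytest.mark.parametrize(
        "p_tost, p_nhst, expected",
        [(0.001, 0.286, True), (0.001, 0.005, False), (0.99, 0.001, False),
         (0.05, 0.051, True), (0.051, 0.5, False)],
    )
    def test_dual_criterion(self, p_tost, p_nhst, expected):
        assert equivalence_verdict(p_tost, p_nhst, 0.05) is expected

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            equivalence_verdict(1.5, 0.5)


class TestGroupAbsDiff:
    def test_equal_pairs_all_zero(self):
        pairs = pd.DataFrame({"manual_iss": [4, 20, 60], "auto_iss": [4, 20, 60]})
        out = group_abs_diff_summary(pairs)
        assert (out.loc[out["n"] > 0, "mean_abs_diff"] == 0).all()

    def test_hand_arithmetic(self):
        pairs = pd.DataFrame({"manual_iss": [10, 12], "auto_iss": [12, 16]})
        row = group_abs_diff_summary(pairs).iloc[1]  # group 2 (ISS 9-15)
        assert row["n"] == 2
        assert row["mean_abs_diff"] == pytest.approx(3.0)
        assert row["sd_abs_diff"] == pytest.approx(math.sqrt(2))

    def test_empty_group_reported_with_missing_moments(self):
        pairs = pd.DataFrame({"manual_iss": [1], "auto_iss": [2]})
        out = group_abs_diff_summary(pairs)
        g6 = out[out["group"] == 6].iloc[0]
        assert g6["n"] == 0 and np.isnan(g6["mean_abs_diff"])


class TestSampleSize:
    def test_tiny_sd_needs_minimum_n(self):
        assert tost_sample_size(1e-6) == 2

    def test_returned_n_is_smallest_reaching_power(self):
        n = tost_sample_size(8.0)
        assert tost_power(n, 8.0) >= 0.8 > tost_power(n - 1, 8.0)

    def test_doubling_sd_roughly_quadruples_n(self):
        n1 = tost_sample_size(4.0)
        n2 = tost_sample_size(8.0)
        assert abs(n2 - 4 * n1) <= 0.1 * 4 * n1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tost_sample_size(-1.0)
        with pytest.raises(ValueError):
            tost_sample_size(3.0, low=1.0, high=2.0)


class TestBonferroni:
    def test_examples_and_clamping(self):
        assert bonferroni([0.01]) == [0.01]
        assert bonferroni([0.01, 0.04]) == [0.02, 0.08]
        assert bonferroni([0.9, 0.9]) == [1.0, 1.0]

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_adjusted_values_stay_probabilities(self, pvals):
        adj = bonferroni(pvals)
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= p for a, p in zip(adj, pvals))


@pytest.fixture(scope="module")
def pairs():
    return synthetic.generate_paired_scores(
        synthetic.GeneratorConfig(n_patients=640, seed=11)
    )


class TestCompareReport:

    def test_shape_six_groups_plus_overall(self, pairs):
        report = compare_report(pairs)
        assert len(report["equivalence"]) == 7
        assert report["equivalence"][-1]["iss_range"] == "0-75"

    def test_group_level_reconstruction_prints_047(self):
        report = compare_report(synthetic.table3_pairs())
        assert round(report["kappa"]["kappa"], 2) == 0.47
        assert report["kappa"]["band"] == "moderate"

    def test_region_section_only_when_columns_present(self, pairs):
        assert "regions" not in compare_report(pairs)
        rng = np.random.default_rng(2)
        with_regions = pairs.copy()
        for name in ("head_neck", "face", "thorax", "abdomen",
                     "extremities", "external"):
            m = rng.integers(0, 6, len(pairs))
            with_regions[f"manual_ais_{name}"] = m
            with_regions[f"auto_ais_{name}"] = np.clip(
                m + rng.integers(-1, 2, len(pairs)), 0, 6
            )
        report = compare_report(with_regions)
        assert len(report["regions"]) == 6
        assert all("kappa" in r for r in report["regions"])

    def test_missing_column_schema_error(self):
        with pytest.raises(ValueError, match="manual_iss"):
            compare_report(pd.DataFrame({"auto_iss": [1, 2]}))

    def test_report_is_json_serialisable(self, pairs):
        import json

        json.dumps(compare_report(pairs))
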