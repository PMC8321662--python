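import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from pkdscreen import (
    FenceParams,
    classify_enrichment,
    compute_log2_ratios,
    filter_proteins,
    impute_missing,
    to_log_matrix,
    make_design,
)
from pkdscreen.enrichment import LOG10_2
from pkdscreen.errors import ConfigurationError, StateError
from tests.conftest import build_table


class TestFilterProteins:
    def test_boundary_at_two_peptides(self):
        table = build_table([[1e7] * 6, [1e7] * 6], peptides=[2, 1])
        kept = filter_proteins(table, min_razor_unique=2)
        assert kept.leading_accessions == ["P1"]

    def test_threshold_zero_is_identity(self):
        table = build_table([[1e7] * 6] * 3, peptides=[0, 1, 7])
        assert filter_proteins(table, 0).leading_accessions == table.leading_accessions

    def test_counts_below_threshold_excluded(self):
        table = build_table([[1e7] * 6] * 5, peptides=[0, 1, 2, 3, 7])
        assert len(filter_proteins(table, 2)) == 3

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=30),
           st.integers(0, 10))
    @settings(deadline=None, max_examples=50)
    def test_raising_threshold_never_adds_rows(self, counts, thresh):
        table = build_table([[1e7] * 6] * len(counts), peptides=counts)
        low = set(filter_proteins(table, thresh).leading_accessions)
        high = set(filter_proteins(table, thresh + 1).leading_accessions)
        assert high <= low


class TestLogMatrix:
    def test_log10_transform_and_missing_flags(self, design3):
        table = build_table([[1e7, 1e6, np.nan, 1e7, 1e7, 1e7]])
        m = to_log_matrix(table, design3)
        assert m.values[0, 0] == pytest.approx(7.0)
        assert m.values[0, 1] == pytest.approx(6.0)
        assert not m.observed[0, 2] and np.isnan(m.values[0, 2])
        assert not m.imputed

    def test_unpaired_design_rejected(self):
        with pytest.raises(ConfigurationError, match="unpaired"):
            make_design(["C1", "C2"], ["T1", "T2", "T3"])


class TestImputation:
    def test_no_missing_cells_returns_values_unchanged(self, toy_table, design3):
        m = to_log_matrix(toy_table, design3)
        for seed in (1, 99):
            out = impute_missing(m, seed=seed)
            assert out.imputed
            np.testing.assert_array_equal(out.values, m.values)

    def test_observed_cells_bitwise_unchanged(self, design3):
        table = build_table([[1e7, np.nan, 1e7, 1e7, np.nan, 1e7],
                             [1e6, 1e6, 1e6, np.nan, 2e6, 2e6]])
        m = to_log_matrix(table, design3)
        out = impute_missing(m, seed=3)
        assert (out.values[m.observed] == m.values[m.observed]).all()
        assert np.isfinite(out.values).all()
        np.testing.assert_array_equal(out.observed, m.observed)

    def test_seed_contract(self, design3):
        table = build_table([[1e7, np.nan, 1e7, np.nan, 1e7, 1e7]])
        m = to_log_matrix(table, design3)
        a = impute_missing(m, seed=1).values
        b = impute_missing(m, seed=1).values
        c = impute_missing(m, seed=2).values
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_imputed_values_follow_anchored_normal(self, design3):
        # many missing cells: empirical mean ~ pooled 5% quantile, SD ~ 0.1
        rng = np.random.default_rng(0)
        n = 4000
        lfq = 10.0 ** rng.normal(7, 0.7, size=(n, 6))
        missing = rng.random((n, 6)) < 0.5
        lfq[missing] = np.nan
        m = to_log_matrix(build_table(lfq), design3)
        q = np.quantile(m.values[m.observed], 0.05)
        out = impute_missing(m, quantile=0.05, sd=0.1, seed=5)
        imputed = out.values[~m.observed]
        assert imputed.size >= 10_000
        assert abs(imputed.mean() - q) < 0.01
        assert abs(imputed.std(ddof=1) - 0.1) < 0.01

    def test_all_missing_matrix_is_error(self, design3):
        m = to_log_matrix(build_table([[np.nan] * 6]), design3)
        with pytest.raises(StateError, match="no observed"):
            impute_missing(m, seed=1)


class TestLog2Ratios:
    def _matrix(self, rows, design):
        m = to_log_matrix(build_table(rows), design)
        return impute_missing(m, seed=0)

    def test_equal_conditions_give_zero(self, design3):
        df = compute_log2_ratios(self._matrix([[1e7, 1e6, 1e5, 1e7, 1e6, 1e5]], design3))
        assert df.loc["P1", "log2_ratio"] == pytest.approx(0.0)

    def test_doubled_treatment_gives_one(self, design3):
        df = compute_log2_ratios(self._matrix([[1e7, 1e6, 1e5, 2e7, 2e6, 2e5]], design3))
        assert df.loc["P1", "log2_ratio"] == pytest.approx(1.0)

    def test_hand_computed_paired_mean(self, design3):
        # log10 pairs (7.0, 6.5), (7.2, 6.6), (6.9, 6.8) as (T, C)
        rows = [[10 ** 6.5, 10 ** 6.6, 10 ** 6.8, 10 ** 7.0, 10 ** 7.2, 10 ** 6.9]]
        df = compute_log2_ratios(self._matrix(rows, design3))
        expected = np.mean([0.5, 0.6, 0.1]) / LOG10_2
        assert df.loc["P1", "log2_ratio"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1.3288, abs=5e-5)
        # mean log10 intensity pools all six values
        assert df.loc["P1", "mean_log10_intensity"] == pytest.approx(np.mean([6.5, 6.6, 6.8, 7.0, 7.2, 6.9]))

    def test_ratio_of_means_mode(self, design3):
        rows = [[10 ** 6.5, 10 ** 6.6, 10 ** 6.8, 10 ** 7.0, 10 ** 7.2, 10 ** 6.9]]
        df = compute_log2_ratios(self._matrix(rows, design3), mode="ratio-of-means")
        expected = (np.mean([7.0, 7.2, 6.9]) - np.mean([6.5, 6.6, 6.8])) / LOG10_2
        assert df.loc["P1", "log2_ratio"] == pytest.approx(expected)

    def test_unimputed_matrix_is_state_error(self, toy_table, design3):
        with pytest.raises(StateError, match="imputed"):
            compute_log2_ratios(to_log_matrix(toy_table, design3))


class TestClassifyEnrichment:
    def test_all_equal_ratios_are_class_zero(self):
        out = classify_enrichment(pd.Series([0.3] * 10, index=[f"P{i}" for i in range(10)]))
        assert (out["significance"] == 0).all()
        assert (out["direction"] == 0).all()

    def test_single_extreme_outlier(self):
        ratios = pd.Series([-0.2, -0.1, 0.0, 0.1, 0.2, 5.0],
                           index=[f"P{i}" for i in range(6)])
        out = classify_enrichment(ratios)
        # linear-interpolation quartiles: Q1 = -0.075, Q3 = 0.175, IQR = 0.25,
        # extreme upper fence 0.925
        assert out.loc["P5", "significance"] == 2
        assert out.loc["P5", "direction"] == 1
        assert (out.drop("P5")["significance"] == 0).all()

    def test_fewer_than_four_or_nonfinite_ratios_rejected(self):
        with pytest.raises(ConfigurationError, match=">= 4"):
            classify_enrichment({"P1": 0.0, "P2": 1.0, "P3": 2.0})
        with pytest.raises(ConfigurationError, match="non-finite"):
            classify_enrichment({"P1": 0.0, "P2": 1.0, "P3": 2.0, "P4": np.nan})

    def test_fence_parameter_validation(self):
        with pytest.raises(ConfigurationError):
            FenceParams(k_potential=3.0, k_extreme=1.5)

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=4, max_size=40),
           st.floats(-5, 5, allow_nan=False),
           st.floats(0.1, 10, allow_nan=False))
    @settings(deadline=None, max_examples=100)
    def test_classes_invariant_under_affine_positive_maps(self, ratios, shift, scale):
        # strict fence comparisons make exact fence ties rounding-dependent;
        # the invariant is asserted away from ties
        r = np.asarray(ratios)
        q1, q3 = np.quantile(r, [0.25, 0.75])
        iqr = q3 - q1
        fences = [q1 - 3 * iqr, q1 - 1.5 * iqr, q3 + 1.5 * iqr, q3 + 3 * iqr]
        assume(all(abs(x - f) > 1e-6 * max(1.0, abs(x)) for x in r for f in fences))
        idx = [f"P{i}" for i in range(len(ratios))]
        base = classify_enrichment(pd.Series(ratios, index=idx))
        shifted = classify_enrichment(pd.Series([r + shift for r in ratios], index=idx))
        scaled = classify_enrichment(pd.Series([r * scale for r in ratios], index=idx))
        assert (base["significance"] == shifted["significance"]).all()
        assert (base["significance"] == scaled["significance"]).all()
        assert (base["direction"] == scaled["direction"]).all()

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=4, max_size=40))
    @settings(deadline=None, max_examples=100)
    def test_extreme_class_nested_in_potential_fence(self, ratios):
        """Every class-2 protein would also be flagged by the 1.5x fence alone."""
        idx = [f"P{i}" for i in range(len(ratios))]
        out = classify_enrichment(pd.Series(ratios, index=idx))
        r = np.asarray(ratios)
        q1, q3 = np.quantile(r, [0.25, 0.75])
        iqr = q3 - q1
        flagged_15 = (r > q3 + 1.5 * iqr) | (r < q1 - 1.5 * iqr)
        assert all(flagged_15[i] for i in np.flatnonzero(out["significance"].to_numpy() == 2))
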