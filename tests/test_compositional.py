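"""Censoring policies, clr transform, summaries and distribution tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilpte import (
    clr_transform,
    distribution_diagnostics,
    impute_censored,
    summarize,
)
from soilpte.compositional import CensoringPolicyError
from tests.conftest import toy_table


class TestImputeCensored:
    def test_half_dl_substitution(self):
        table = toy_table(
            {"Cd": [0.10, 0.30], "As": [5.0, 6.0]},
            censored={"Cd": [True, False]},
        )
        matrix, record = impute_censored(table, "half_dl")
        assert matrix["Cd"].iloc[0] == pytest.approx(0.05)
        assert matrix["Cd"].iloc[1] == 0.30
        assert record.substitutions == [("T0", "Cd", 0.05)]

    def test_dl_policy_keeps_limit(self):
        table = toy_table({"Cd": [0.10, 0.30]}, censored={"Cd": [True, False]})
        matrix, _ = impute_censored(table, "dl")
        assert matrix["Cd"].iloc[0] == 0.10

    def test_exclude_drops_heavily_censored_element(self):
        table = toy_table(
            {"Sb": [0.5] * 4, "As": [5.0, 6.0, 7.0, 8.0]},
            censored={"Sb": [True, True, True, False]},  # 75% censored
        )
        matrix, record = impute_censored(table, "exclude")
        assert record.dropped_elements == ["Sb"]
        assert list(matrix.columns) == ["As"]

    def test_no_censoring_is_identity(self, default_survey):
        table = toy_table({"As": [5.0, 6.0, 7.0]})
        matrix, record = impute_censored(table)
        assert matrix["As"].tolist() == [5.0, 6.0, 7.0]
        assert record.substitutions == []

    def test_unknown_policy(self):
        table = toy_table({"As": [5.0]})
        with pytest.raises(CensoringPolicyError):
            impute_censored(table, "winsorize")


class TestClr:
    def test_equal_parts_map_to_zero(self):
        clr = clr_transform(pd.DataFrame([[5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(clr.to_numpy(), 0.0, atol=1e-12)

    def test_analytic_row(self):
        clr = clr_transform(pd.DataFrame([[1.0, 10.0, 100.0]]))
        np.testing.assert_allclose(
            clr.to_numpy()[0], [-2.302585, 0.0, 2.302585], atol=1e-6
        )

    def test_scale_invariance_and_zero_sum(self, clr_default, default_survey):
        survey, _ = default_survey
        matrix, _ = impute_censored(survey)
        scaled = clr_transform(matrix * 7.0)
        np.testing.assert_allclose(
            scaled.to_numpy(), clr_default.to_numpy(), atol=1e-10
        )
        np.testing.assert_allclose(
            clr_default.sum(axis=1).to_numpy(), 0.0, atol=1e-10
        )

    def test_matches_skbio_oracle(self):
        from skbio.stats.composition import clr as skbio_clr

        rng = np.random.default_rng(42)
        x = rng.lognormal(size=(30, 8))
        ours = clr_transform(pd.DataFrame(x)).to_numpy()
        np.testing.assert_allclose(ours, skbio_clr(x), atol=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="impute"):
            clr_transform(pd.DataFrame([[1.0, 0.0, 2.0]]))


class TestSummarize:
    def test_constant_column(self):
        panel = summarize(toy_table({"As": [5.0, 5.0, 5.0]}))
        row = panel.loc["As"]
        assert row["sd"] == 0 and row["cv_percent"] == 0
        assert row["p10"] == row["p90"] == row["median"] == 5.0

    def test_small_column_order_statistics(self):
        panel = summarize(toy_table({"As": [1.0, 2.0, 3.0, 4.0, 100.0]}))
        assert panel.loc["As", "median"] == 3.0
        assert panel.loc["As", "max"] == 100.0

    def test_censored_counted_separately(self):
        table = toy_table(
            {"Cd": [0.10, 0.30, 0.4]}, censored={"Cd": [True, False, False]}
        )
        assert summarize(table).loc["Cd", "n_gt_dl"] == 2

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=60
        )
    )
    def test_percentile_ordering_invariant(self, values):
        panel = summarize(toy_table({"X": values}))
        row = panel.loc["X"]
        keys = ["min", "p10", "p25", "median", "p75", "p90", "max"]
        ordered = [row[k] for k in keys]
        assert all(a <= b + 1e-12 for a, b in zip(ordered, ordered[1:]))
        assert row["cv_percent"] == pytest.approx(
            100 * row["sd"] / row["average"]
        )


class TestDistributionDiagnostics:
    def test_gaussian_rarely_rejected(self):
        hits = 0
        for seed in range(100):
            v = np.random.default_rng(seed).standard_normal(100)
            table = toy_table({"X": v - v.min() + 1.0})  # shift positive
            report = distribution_diagnostics(table)
            if report.loc["X", "normal"]:
                hits += 1
        assert hits >= 95

    def test_lognormal_rejected(self):
        v = np.random.default_rng(1).lognormal(mean=0.0, sigma=1.0, size=44)
        report = distribution_diagnostics(toy_table({"X": v}))
        assert not report.loc["X", "normal"]

    def test_levene_zero_for_identical_groups(self):
        table = toy_table(
            {"X": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
            land_use=["agricultural"] * 3 + ["urban"] * 3,
        )
        report = distribution_diagnostics(table)
        assert report.loc["X", "levene_stat"] == pytest.approx(0.0)

    def test_constant_sample_skipped(self):
        report = distribution_diagnostics(toy_table({"X": [2.0, 2.0, 2.0]}))
        assert "skipped" in report.columns
        assert isinstance(report.loc["X", "skipped"], str)
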