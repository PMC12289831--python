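"""Contamination/risk factors, classification, screening, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilpte import (
    SyntheticScenario,
    cohort_enrichment,
    default_references,
    enrichment_factor,
    generate_survey,
    landuse_risk_summary,
    risk_factors,
    screen_thresholds,
)
from soilpte.references import ELEMENTS
from soilpte.risk import RI_CLASSES, _classify, RI_BOUNDS, ER_BOUNDS, ER_CLASSES
from tests.conftest import toy_table


def _background_survey(n=3):
    refs = default_references()
    return toy_table({el: [refs.B[el]] * n for el in ELEMENTS})


class TestRiskFactors:
    def test_background_concentrations_give_ri_115(self):
        """C = B for all 14 elements: E = 1, Er = Tr, RI = sum(Tr) = 115."""
        risk = risk_factors(_background_survey())
        np.testing.assert_allclose(risk.E.to_numpy(), 1.0, atol=1e-12)
        refs = default_references()
        for el in ELEMENTS:
            assert risk.Er[el].iloc[0] == pytest.approx(refs.Tr[el])
        np.testing.assert_allclose(risk.ri.to_numpy(), 115.0, atol=1e-9)

    def test_site26_arsenic_worked_example(self):
        """Er for the printed As maximum: 211 / 8.85 * 10 = 238.4."""
        risk = risk_factors(toy_table({"As": [211.0, 10.0]}))
        assert risk.Er["As"].iloc[0] == pytest.approx(238.4, abs=0.05)

    def test_doubling_is_linear(self):
        base = risk_factors(toy_table({"As": [20.0], "Zn": [100.0]}))
        double = risk_factors(toy_table({"As": [40.0], "Zn": [100.0]}))
        assert double.Er["As"].iloc[0] == pytest.approx(
            2 * base.Er["As"].iloc[0]
        )
        increment = double.Er["As"].iloc[0] - base.Er["As"].iloc[0]
        assert double.ri.iloc[0] - base.ri.iloc[0] == pytest.approx(increment)

    def test_missing_reference_is_config_error(self):
        with pytest.raises(KeyError, match="Xx"):
            risk_factors(toy_table({"Xx": [1.0]}))

    def test_censored_cells_use_policy(self):
        table = toy_table({"Cd": [0.10, 0.4]}, censored={"Cd": [True, False]})
        half = risk_factors(table, censoring_policy="half_dl")
        at_dl = risk_factors(table, censoring_policy="dl")
        assert at_dl.Er["Cd"].iloc[0] == pytest.approx(
            2 * half.Er["Cd"].iloc[0]
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.001, max_value=1e4),
            min_size=14, max_size=14,
        )
    )
    def test_ri_additive_er_monotone(self, values):
        conc = dict(zip(ELEMENTS, ([v] for v in values)))
        risk = risk_factors(toy_table(conc))
        assert risk.ri.iloc[0] == pytest.approx(
            risk.Er.iloc[0].sum(), rel=1e-9
        )
        bumped = dict(conc)
        bumped["As"] = [values[0] * 2]
        assert (
            risk_factors(toy_table(bumped)).Er["As"].iloc[0]
            > risk.Er["As"].iloc[0]
        )

    def test_unit_parameters_reduce_to_row_sum(self):
        refs = default_references().replace(
            Tr={el: 1.0 for el in ELEMENTS}, B={el: 1.0 for el in ELEMENTS}
        )
        conc = {el: [float(i + 1)] for i, el in enumerate(ELEMENTS)}
        risk = risk_factors(toy_table(conc), refs)
        assert risk.ri.iloc[0] == pytest.approx(sum(range(1, 15)))


class TestClassification:
    @pytest.mark.parametrize(
        "ri, expected",
        [
            (149.9, "low"),
            (150.0, "moderate"),   # boundary joins the higher class
            (299.9, "moderate"),
            (300.0, "considerable"),
            (601.0, "high"),
        ],
    )
    def test_ri_classes(self, ri, expected):
        assert _classify(ri, RI_BOUNDS, RI_CLASSES) == expected

    @pytest.mark.parametrize(
        "er, expected",
        [(39.0, "low"), (40.0, "moderate"), (100.0, "considerable"),
         (200.0, "high"), (320.0, "very high")],
    )
    def test_er_classes(self, er, expected):
        assert _classify(er, ER_BOUNDS, ER_CLASSES) == expected


class TestScreening:
    def test_toy_arsenic_counts(self, four_site_as):
        report = screen_thresholds(four_site_as)
        assert report.table.loc["As", "csc_a_count"] == 2   # > 20
        assert report.table.loc["As", "csc_b_count"] == 1   # > 50
        assert report.table.loc["As", "csc_a_percent"] == pytest.approx(50.0)

    def test_strict_inequality_at_threshold(self):
        report = screen_thresholds(toy_table({"As": [20.0, 20.0]}))
        assert report.table.loc["As", "csc_a_count"] == 0
        assert report.table.loc["As", "csc_b_count"] == 0

    def test_element_without_csc_listed(self):
        report = screen_thresholds(toy_table({"Mn": [500.0, 700.0]}))
        assert report.skipped == ["Mn"]

    def test_synthetic_rank_order_as_over_zn(self):
        """Default plume gives more As than Zn screening exceedances."""
        hits = 0
        for seed in range(20):
            survey, _ = generate_survey(SyntheticScenario(seed=seed))
            tab = screen_thresholds(survey).table
            if tab.loc["As", "csc_a_count"] > tab.loc["Zn", "csc_a_count"]:
                hits += 1
        assert hits >= 16


class TestEnrichment:
    def test_value_equal_reference(self):
        assert enrichment_factor(5.0, 5.0) == 1.0

    def test_nonpositive_reference(self):
        with pytest.raises(ValueError):
            enrichment_factor(5.0, 0.0)

    def test_cohort_self_reference_is_unity(self, default_survey):
        survey, _ = default_survey
        medians = survey.concentrations().median().to_dict()
        ef = cohort_enrichment(survey, medians)
        np.testing.assert_allclose(ef.to_numpy(), 1.0, atol=1e-12)


class TestLandUseSummary:
    def test_single_class_equals_overall(self, four_site_as):
        risk = risk_factors(four_site_as)
        summary = landuse_risk_summary(risk)
        assert list(summary.index) == ["agricultural"]
        assert summary.loc["agricultural", "median_ri"] == pytest.approx(
            risk.ri.median()
        )

    def test_permutation_invariant(self):
        conc = {"As": [10.0, 50.0, 30.0, 20.0]}
        uses = ["urban", "industrial", "urban", "industrial"]
        a = landuse_risk_summary(risk_factors(toy_table(conc, land_use=uses)))
        perm = [3, 1, 0, 2]
        b = landuse_risk_summary(
            risk_factors(
                toy_table(
                    {"As": [conc["As"][i] for i in perm]},
                    land_use=[uses[i] for i in perm],
                )
            )
        )
        pd.testing.assert_frame_equal(a, b)

    def test_industrial_exceeds_agricultural_risk(self):
        hits = 0
        for seed in range(20):
            survey, _ = generate_survey(SyntheticScenario(seed=seed))
            summary = landuse_risk_summary(risk_factors(survey))
            if "industrial" not in summary.index:
                continue  # layout drew no site near the source: no evidence
            if (
                summary.loc["industrial", "median_ri"]
                > summary.loc["agricultural", "median_ri"]
            ):
                hits += 1
        assert hits >= 17
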