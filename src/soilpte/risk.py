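"""Enrichment factors, Hakanson ecological risk indices, and regulatory
screening.

For element *i* with measured concentration ``C_i`` and background ``B_i``:

* contamination factor       ``E_i  = C_i / B_i``
* ecological risk factor     ``Er_i = Tr_i * E_i``
* site risk index            ``RI   = sum_i Er_i``

``Tr_i`` is the element's toxic-response weight. RI classes follow
Hakanson's original boundaries (low < 150 <= moderate < 300 <=
considerable < 600 <= high; a value exactly on a boundary joins the
higher class). Er classes use the standard 40/80/160/320 cut-offs.

The enrichment factor here is a direct ratio to a background or baseline
median (no crustal normaliser element), matching common practice for
survey-versus-baseline comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compositional import impute_censored
from .references import ReferenceTables, default_references
from .survey import SurveyTable

RI_BOUNDS = (150.0, 300.0, 600.0)
RI_CLASSES = ("low", "moderate", "considerable", "high")
ER_BOUNDS = (40.0, 80.0, 160.0, 320.0)
ER_CLASSES = ("low", "moderate", "considerable", "high", "very high")


def enrichment_factor(value: float, reference: float) -> float:
    """EF = value / reference (reference must be positive)."""
    if reference <= 0:
        raise ValueError("reference concentration must be > 0")
    return float(value) / float(reference)


def cohort_enrichment(
    table: SurveyTable,
    reference: dict[str, float],
    statistic: str = "median",
) -> pd.Series:
    """Cohort EF: a survey summary statistic over each element's reference.

    ``statistic`` is ``median`` (default) or ``mean``; the choice is
    recorded in the series name.
    """
    conc = table.concentrations()
    if statistic == "median":
        summary = conc.median()
    elif statistic == "mean":
        summary = conc.mean()
    else:
        raise ValueError("statistic must be 'median' or 'mean'")
    out = {}
    for el in conc.columns:
        if el in reference:
            out[el] = enrichment_factor(summary[el], reference[el])
    return pd.Series(out, name=f"EF_{statistic}")


def _classify(value: float, bounds: tuple, classes: tuple) -> str:
    # boundary values join the higher class ("150 -> moderate")
    idx = int(np.searchsorted(bounds, value, side="right"))
    if value in bounds:
        idx = bounds.index(value) + 1
    return classes[idx]


@dataclass
class RiskTable:
    """Per-site/per-element risk quantities and site-level indices."""

    E: pd.DataFrame          # contamination factors, site x element
    Er: pd.DataFrame         # ecological risk factors
    ri: pd.Series            # site risk index
    land_use: pd.Series
    censoring_policy: str

    @property
    def ri_class(self) -> pd.Series:
        return self.ri.map(lambda v: _classify(v, RI_BOUNDS, RI_CLASSES))

    def er_class(self) -> pd.DataFrame:
        return self.Er.map(lambda v: _classify(v, ER_BOUNDS, ER_CLASSES))

    def to_frame(self) -> pd.DataFrame:
        out = self.Er.add_prefix("Er_")
        out["RI"] = self.ri
        out["RI_class"] = self.ri_class
        out["land_use"] = self.land_use.to_numpy()
        return out


def risk_factors(
    table: SurveyTable,
    refs: ReferenceTables | None = None,
    censoring_policy: str = "half_dl",
) -> RiskTable:
    """Compute E, Er and RI for every site over the survey's element panel.

    Censored cells contribute via the stated substitution policy (default
    half the detection limit), which is recorded on the result.
    """
    refs = refs or default_references()
    missing = [
        el for el in table.elements if el not in refs.Tr or el not in refs.B
    ]
    if missing:
        raise KeyError(f"missing Tr or background B for element(s): {missing}")
    conc, _ = impute_censored(table, policy=censoring_policy)
    e = conc / pd.Series({el: refs.B[el] for el in conc.columns})
    er = e * pd.Series({el: refs.Tr[el] for el in conc.columns})
    ri = er.sum(axis=1)
    land_use = table.data.set_index(conc.index)["land_use"]
    return RiskTable(e, er, ri, land_use, censoring_policy)


@dataclass
class ExceedanceReport:
    """Counts and percentages of sites above the screening concentrations."""

    table: pd.DataFrame      # per element: counts/percents vs CSC_A and CSC_B
    skipped: list[str]       # elements without a statutory value


def screen_thresholds(
    table: SurveyTable, refs: ReferenceTables | None = None
) -> ExceedanceReport:
    """Strict-greater comparison of reported values against CSC_A / CSC_B."""
    refs = refs or default_references()
    conc = table.concentrations()
    n = len(conc)
    rows, skipped = {}, []
    for el in conc.columns:
        if el not in refs.CSC_A and el not in refs.CSC_B:
            skipped.append(el)
            continue
        row = {}
        for name, csc in (("csc_a", refs.CSC_A), ("csc_b", refs.CSC_B)):
            if el in csc:
                count = int((conc[el] > csc[el]).sum())
                row[f"{name}_threshold"] = csc[el]
                row[f"{name}_count"] = count
                row[f"{name}_percent"] = 100.0 * count / n
        rows[el] = row
    return ExceedanceReport(pd.DataFrame(rows).T, skipped)


def landuse_risk_summary(risk: RiskTable) -> pd.DataFrame:
    """Per-land-use RI distribution: n, median, quartiles and class counts."""
    rows = []
    for use, ri in risk.ri.groupby(risk.land_use.to_numpy()):
        if len(ri) == 0:
            continue
        classes = ri.map(lambda v: _classify(v, RI_BOUNDS, RI_CLASSES))
        row = {
            "land_use": use,
            "n": len(ri),
            "median_ri": float(ri.median()),
            "q1_ri": float(ri.quantile(0.25)),
            "q3_ri": float(ri.quantile(0.75)),
        }
        for cls in RI_CLASSES:
            row[f"n_{cls}"] = int((classes == cls).sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("land_use")
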