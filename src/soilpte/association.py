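"""Classical and robust correlation structure among elements.

Two complementary views of the pairwise association between log-transformed
concentrations: ordinary Pearson coefficients (with two-sided p-values), and
correlations derived from the minimum covariance determinant (MCD) scatter
estimate, which is resistant to the gross outliers that industrial hotspots
produce. Elements whose censoring rate exceeds a threshold (default 30%)
carry too little quantified information and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet

from .compositional import DEFAULT_EXCLUSION_THRESHOLD, impute_censored, log_transform
from .survey import SurveyTable


@dataclass
class CorrelationResult:
    """Square correlation matrix plus bookkeeping.

    Attributes
    ----------
    matrix : pandas.DataFrame
        Symmetric correlation matrix with unit diagonal.
    p_values : pandas.DataFrame or None
        Two-sided p-values (Pearson only).
    excluded : list
        Elements dropped for excessive censoring.
    n : int
        Number of sites used.
    method : str
    """

    matrix: pd.DataFrame
    p_values: pd.DataFrame | None
    excluded: list[str]
    n: int
    method: str

    def pairs(self) -> pd.DataFrame:
        """Tidy upper-triangle pair list."""
        els = list(self.matrix.columns)
        rows = []
        for i, a in enumerate(els):
            for b in els[i + 1:]:
                row = {"element_a": a, "element_b": b, "r": self.matrix.loc[a, b]}
                if self.p_values is not None:
                    row["p"] = self.p_values.loc[a, b]
                rows.append(row)
        return pd.DataFrame(rows)


def _log_matrix(
    table: SurveyTable, exclusion_threshold: float
) -> tuple[pd.DataFrame, list[str]]:
    rates = table.censoring_rate()
    excluded = [el for el in table.elements if rates[el] > exclusion_threshold]
    kept = [el for el in table.elements if el not in excluded]
    matrix, _ = impute_censored(table.subset_elements(kept), policy="half_dl")
    return log_transform(matrix), excluded


def log_pearson_matrix(
    table: SurveyTable,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
) -> CorrelationResult:
    """Pearson correlations (and p-values) on log10 concentrations."""
    logm, excluded = _log_matrix(table, exclusion_threshold)
    els = list(logm.columns)
    p = len(els)
    r_mat = pd.DataFrame(np.eye(p), index=els, columns=els)
    p_mat = pd.DataFrame(np.zeros((p, p)), index=els, columns=els)
    for i, a in enumerate(els):
        for b in els[i + 1:]:
            xa, xb = logm[a].to_numpy(), logm[b].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                r, pv = np.nan, np.nan  # constant column: undefined pair
            else:
                r, pv = stats.pearsonr(xa, xb)
            r_mat.loc[a, b] = r_mat.loc[b, a] = r
            p_mat.loc[a, b] = p_mat.loc[b, a] = pv
    return CorrelationResult(r_mat, p_mat, excluded, len(logm), "pearson_log10")


def mcd_correlation_matrix(
    table: SurveyTable,
    support_fraction: float = 0.75,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    seed: int = 0,
) -> CorrelationResult:
    """Robust correlations from the MCD scatter estimate on log10 data.

    The MCD covariance is computed on the same log-transformed matrix as
    the Pearson stage (so the two are directly comparable) at the stated
    support fraction, then rescaled to a correlation matrix.
    """
    logm, excluded = _log_matrix(table, exclusion_threshold)
    n, p = logm.shape
    if n <= p:
        raise ValueError(
            f"MCD needs more sites than elements (n={n}, p={p}); subset elements"
        )
    mcd = MinCovDet(
        support_fraction=support_fraction, random_state=int(seed)
    ).fit(logm.to_numpy())
    cov = mcd.covariance_
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    mat = pd.DataFrame(corr, index=logm.columns, columns=logm.columns)
    return CorrelationResult(mat, None, excluded, n, "mcd_log10")
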