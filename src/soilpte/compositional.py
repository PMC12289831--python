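"""Censoring policy, log-ratio transforms, summary statistics and
distributional diagnostics.

Trace-element concentrations are compositional: they carry relative, not
absolute, information, and the constant-sum closure induces spurious
negative correlation among raw parts. The centred log-ratio (clr)
transform, ``clr_ij = ln(x_ij / g(x_i))`` with ``g`` the row geometric
mean, maps each composition onto a zero-sum hyperplane where ordinary
multivariate tools (PCA, clustering) behave sensibly.

Censored (below detection limit) cells must be replaced by a positive
value before any log transform; the substitution policy is explicit and
logged so results stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .references import default_references
from .survey import SurveyTable

#: Elements whose censoring rate exceeds this fraction are dropped by the
#: ``exclude`` policy (and from the correlation stage).
DEFAULT_EXCLUSION_THRESHOLD = 0.30


class CensoringPolicyError(ValueError):
    """Unknown censored-value substitution policy."""


@dataclass
class ImputationRecord:
    """Log of the substitutions a censoring policy performed."""

    policy: str
    substitutions: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_elements: list[str] = field(default_factory=list)


def impute_censored(
    table: SurveyTable,
    policy: str = "half_dl",
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
) -> tuple[pd.DataFrame, ImputationRecord]:
    """Produce a strictly positive site-by-element matrix.

    Policies
    --------
    ``half_dl`` (default)
        Replace each censored cell by half its detection limit.
    ``dl``
        Keep the detection limit itself.
    ``exclude``
        Drop any element whose censoring rate exceeds
        ``exclusion_threshold``; remaining censored cells get DL/2.

    Returns the matrix (indexed by site) and an :class:`ImputationRecord`.
    """
    if policy not in ("half_dl", "dl", "exclude"):
        raise CensoringPolicyError(f"unknown censoring policy {policy!r}")
    conc = table.concentrations()
    record = ImputationRecord(policy=policy)
    elements = list(conc.columns)
    if policy == "exclude":
        rates = table.censoring_rate()
        record.dropped_elements = [
            el for el in elements if rates[el] > exclusion_threshold
        ]
        elements = [el for el in elements if el not in record.dropped_elements]
        conc = conc[elements]
    factor = 1.0 if policy == "dl" else 0.5
    out = conc.copy()
    cens = table.censored
    for el in elements:
        mask = cens[el].to_numpy()
        if mask.any():
            new = conc[el].to_numpy() * np.where(mask, factor, 1.0)
            for site, flagged, v in zip(conc.index, mask, new):
                if flagged:
                    record.substitutions.append((str(site), el, float(v)))
            out[el] = new
    return out, record


def clr_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio coordinates of a strictly positive matrix.

    Each row is log-transformed and centred on its own geometric mean, so
    rows sum to zero and the result is invariant to rescaling any row by
    a positive constant.
    """
    x = np.asarray(matrix, dtype=float)
    if (x <= 0).any() or not np.isfinite(x).all():
        raise ValueError(
            "clr requires strictly positive entries; impute censored cells first"
        )
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=matrix.index, columns=matrix.columns)


def summarize(table: SurveyTable) -> pd.DataFrame:
    """Descriptive statistics per element, Table-1 style.

    Censored cells enter at their detection limit (as reported values) and
    are counted separately via ``n_gt_dl``. Percentiles use linear
    interpolation between order statistics. CV is 100*SD/mean with the
    sample (n-1) standard deviation.
    """
    conc = table.concentrations()
    out = {}
    for el in conc.columns:
        v = conc[el].to_numpy(float)
        mean = v.mean()
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        out[el] = {
            "average": mean,
            "sd": sd,
            "cv_percent": 100.0 * sd / mean if mean > 0 else np.nan,
            "median": np.median(v),
            "min": v.min(),
            "max": v.max(),
            "p10": np.percentile(v, 10),
            "p25": np.percentile(v, 25),
            "p75": np.percentile(v, 75),
            "p90": np.percentile(v, 90),
            "n_gt_dl": int((~table.censored[el]).sum()),
            "all_censored": bool(table.censored[el].all()),
        }
    return pd.DataFrame(out).T


def distribution_diagnostics(
    table: SurveyTable,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Normality (Kolmogorov-Smirnov and Lilliefors) and variance-homogeneity
    (Levene, median-centred) diagnostics per element.

    KS is run against a normal with the sample's fitted mean/SD; Lilliefors
    accounts for that estimation. Levene groups sites by land use. Constant
    samples are skipped with a reason. The ``normal`` flag requires both
    normality tests to be non-significant at ``alpha``.
    """
    conc = table.concentrations()
    groups = table.data["land_use"]
    rows = []
    for el in conc.columns:
        v = conc[el].to_numpy(float)
        row: dict = {"element": el}
        if len(v) < 3 or np.ptp(v) == 0:
            row["skipped"] = "constant or too-small sample"
            rows.append(row)
            continue
        ks_stat, ks_p = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
        lf_stat, lf_p = lilliefors(v, dist="norm")
        row.update(
            ks_stat=ks_stat, ks_p=ks_p,
            lilliefors_stat=lf_stat, lilliefors_p=lf_p,
            normal=bool(ks_p >= alpha and lf_p >= alpha),
        )
        by_group = [
            g.to_numpy(float)
            for _, g in conc[el].groupby(groups.to_numpy())
            if len(g) >= 2
        ]
        if len(by_group) >= 2:
            if all(np.ptp(g) == 0 for g in by_group) and len(
                {g[0] for g in by_group}
            ) == 1:
                row.update(levene_stat=0.0, levene_p=1.0)
            else:
                lev_stat, lev_p = stats.levene(*by_group, center="median")
                row.update(levene_stat=lev_stat, levene_p=lev_p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("element")


def log_transform(
    matrix: pd.DataFrame, base: float = 10.0
) -> pd.DataFrame:
    """Element-wise logarithm (default log10, used before correlations).

    The base only rescales columns, so Pearson correlations are identical
    in any base.
    """
    x = np.asarray(matrix, dtype=float)
    if (x <= 0).any():
        raise ValueError("log transform requires strictly positive entries")
    return pd.DataFrame(
        np.log(x) / np.log(base), index=matrix.index, columns=matrix.columns
    )


def default_detection_limits() -> dict[str, float]:
    return dict(default_references().DL)
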