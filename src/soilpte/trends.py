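"""Source-attribution validation: distance-decay statistics and land-use
contrasts.

A genuine point-source plume should leave three fingerprints: component
scores that fall off with distance from the source (Pearson r and a robust
Theil-Sen slope), higher enrichment of plume elements in the high-score
cluster, and significantly higher scores on industrial land. The functions
here compute each piece and bundle them into one validation report.

Sign convention: PC1 is oriented chalcophile-positive before the trend
tests, so a real plume yields a *negative* slope of score against distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .references import CHALCOPHILE, LITHOGENIC
from .risk import RiskTable


def distance_to_source(coords: np.ndarray, source_xy) -> np.ndarray:
    """Planar Euclidean distance from each site to the source, in km."""
    coords = np.asarray(coords, float)
    sx, sy = source_xy
    return np.hypot(coords[:, 0] - sx, coords[:, 1] - sy) / 1000.0


def theil_sen(x, y, alpha: float = 0.05):
    """Theil-Sen slope (median of pairwise slopes), intercept and CI.

    The intercept is ``median(y - slope * x)``; the confidence interval
    comes from the rank-based distribution of the pairwise slopes.
    Pairs with tied x are skipped; all-tied x is an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("slope undefined: all x identical")
    slope, intercept, lo, hi = stats.theilslopes(y, x, alpha=1 - alpha)
    return float(slope), float(intercept), (float(lo), float(hi))


def oneway_anova(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across group labels.

    Groups with fewer than two members are excluded.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    samples = [
        values[groups == g] for g in pd.unique(groups)
        if (groups == g).sum() >= 2
    ]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        return 0.0, 1.0
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


@dataclass
class TrendResult:
    """Distance-decay and land-use validation bundle for one component."""

    distance_km: np.ndarray
    pearson_r: float
    pearson_p: float
    sen_slope: float           # score units per km
    sen_intercept: float
    sen_ci: tuple[float, float]
    anova_f: float
    anova_p: float
    cluster_ef: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "pearson_r", "pearson_p", "theil_sen_slope_per_km",
                    "theil_sen_ci_low", "theil_sen_ci_high",
                    "anova_F", "anova_p",
                ],
                "value": [
                    self.pearson_r, self.pearson_p, self.sen_slope,
                    self.sen_ci[0], self.sen_ci[1],
                    self.anova_f, self.anova_p,
                ],
            }
        )


def decay_validation(
    scores,
    coords: np.ndarray,
    source_xy,
    land_use,
    risk: RiskTable | None = None,
    cluster_labels: np.ndarray | None = None,
) -> TrendResult:
    """Validate a source assignment for one component's site scores.

    Computes Pearson and Theil-Sen statistics of score vs distance to
    source, a one-way ANOVA of scores across land-use classes, and — when
    a risk table and cluster labels are supplied — per-cluster mean
    contamination factors (EF against local background) for the
    chalcophile and lithogenic element groups.
    """
    scores = np.asarray(scores, float)
    d = distance_to_source(coords, source_xy)
    r, p = stats.pearsonr(d, scores)
    slope, intercept, ci = theil_sen(d, scores)
    f, ap = oneway_anova(scores, land_use)

    cluster_ef = None
    if risk is not None and cluster_labels is not None:
        labels = np.asarray(cluster_labels)
        rows = []
        for lab in np.unique(labels):
            mask = labels == lab
            row = {"cluster": int(lab), "n": int(mask.sum())}
            for group, name in ((CHALCOPHILE, "chalcophile"), (LITHOGENIC, "lithogenic")):
                els = [el for el in group if el in risk.E.columns]
                row[f"mean_ef_{name}"] = float(
                    risk.E.loc[mask, els].to_numpy().mean()
                )
            for el in ("As", "Zn", "Cr", "Ni"):
                if el in risk.E.columns:
                    row[f"mean_ef_{el}"] = float(risk.E.loc[mask, el].mean())
            rows.append(row)
        cluster_ef = pd.DataFrame(rows).set_index("cluster")

    return TrendResult(
        distance_km=d,
        pearson_r=float(r),
        pearson_p=float(p),
        sen_slope=slope,
        sen_intercept=intercept,
        sen_ci=ci,
        anova_f=f,
        anova_p=ap,
        cluster_ef=cluster_ef,
    )
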