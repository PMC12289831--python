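"""k-means partitioning of PCA scores with objective k-selection.

The number of clusters is chosen as the silhouette-width argmax over a
candidate range, with the gap statistic (uniform-box references, one-SE
rule) and a four-index validity panel (silhouette, Calinski-Harabasz,
Davies-Bouldin, gap) recorded as supporting evidence. Clustering operates
on the retained principal-component scores, not the full clr space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_samples,
    silhouette_score,
)


def kmeans_scores(
    scores, k: int, seed: int = 0, n_restarts: int = 50
) -> np.ndarray:
    """k-means labels (1-based) on a sites-by-components score matrix.

    k-means++ initialisation, ``n_restarts`` restarts, best inertia kept;
    deterministic under ``seed``.
    """
    x = np.asarray(scores, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(x) < k:
        raise ValueError("need at least as many points as clusters")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_restarts, random_state=int(seed)
    ).fit(x)
    return km.labels_ + 1


@dataclass
class ClusterSolution:
    """k-selection report: chosen k, labels, and the validity panel."""

    k: int
    labels: np.ndarray
    silhouette_widths: np.ndarray
    mean_silhouette: float
    panel: pd.DataFrame  # per-candidate-k validity indices
    votes: dict[str, int]
    rationale: str
    invalid_k: list[int] = field(default_factory=list)

    def membership(self, site_ids=None) -> pd.DataFrame:
        idx = range(len(self.labels)) if site_ids is None else list(site_ids)
        return pd.DataFrame(
            {
                "site": idx,
                "cluster": self.labels,
                "silhouette": self.silhouette_widths,
            }
        )


def _gap_statistic(
    x: np.ndarray, k_values: list[int], seed: int, n_ref: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Gap(k) = E*[log W_k] - log W_k against uniform-box references."""
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)

    def log_wk(data: np.ndarray, k: int, rs: int) -> float:
        km = KMeans(n_clusters=k, n_init=10, random_state=rs).fit(data)
        return float(np.log(max(km.inertia_, 1e-300)))

    gaps, ses = [], []
    ref_logs = np.empty((n_ref, len(k_values)))
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=x.shape)
        for j, k in enumerate(k_values):
            ref_logs[b, j] = log_wk(ref, k, seed + b)
    for j, k in enumerate(k_values):
        obs = log_wk(x, k, seed)
        gaps.append(ref_logs[:, j].mean() - obs)
        ses.append(ref_logs[:, j].std(ddof=1) * np.sqrt(1.0 + 1.0 / n_ref))
    return np.asarray(gaps), np.asarray(ses)


def gap_supports_structure(
    scores, seed: int = 0, n_ref: int = 50
) -> bool:
    """One-SE comparison of k=1 vs k=2: True if Gap favours k >= 2."""
    x = np.asarray(scores, float)
    gaps, ses = _gap_statistic(x, [1, 2], seed, n_ref)
    return bool(gaps[0] < gaps[1] - ses[1])


def select_k(
    scores,
    k_range: range | list[int] = range(2, 7),
    seed: int = 0,
    n_restarts: int = 50,
    n_ref: int = 50,
) -> ClusterSolution:
    """Choose k by maximum mean silhouette width over ``k_range``.

    The panel records silhouette, Calinski-Harabasz, Davies-Bouldin and the
    gap statistic (with one-SE rule) per candidate k, plus each index's
    vote. A candidate k that forces every point into its own cluster
    (k >= n, silhouette undefined) is marked invalid; an isolated hotspot
    may legitimately form a singleton cluster, whose silhouette width is 0
    by the usual convention.
    """
    x = np.asarray(scores, float)
    k_values = [k for k in k_range if k >= 2]
    if not k_values:
        raise ValueError("empty candidate range")
    rows, labelings, invalid = [], {}, []
    for k in k_values:
        if k > len(x) - 1:
            invalid.append(k)  # silhouette undefined (singletons forced)
            continue
        labels = kmeans_scores(x, k, seed=seed, n_restarts=n_restarts)
        if len(np.unique(labels)) < 2:
            invalid.append(k)
            continue
        labelings[k] = labels
        rows.append(
            {
                "k": k,
                "silhouette": silhouette_score(x, labels),
                "calinski_harabasz": calinski_harabasz_score(x, labels),
                "davies_bouldin": davies_bouldin_score(x, labels),
            }
        )
    if not rows:
        raise ValueError("no valid k in candidate range (singleton clusters)")
    panel = pd.DataFrame(rows).set_index("k")
    gaps, ses = _gap_statistic(x, list(panel.index), seed, n_ref)
    panel["gap"] = gaps
    panel["gap_se"] = ses

    votes = {
        "silhouette": int(panel["silhouette"].idxmax()),
        "calinski_harabasz": int(panel["calinski_harabasz"].idxmax()),
        "davies_bouldin": int(panel["davies_bouldin"].idxmin()),
    }
    # gap one-SE rule: smallest k with Gap(k) >= Gap(k+1) - SE(k+1)
    ks = list(panel.index)
    gap_k = ks[-1]
    for j in range(len(ks) - 1):
        if gaps[j] >= gaps[j + 1] - ses[j + 1]:
            gap_k = ks[j]
            break
    votes["gap"] = int(gap_k)

    chosen = int(panel["silhouette"].idxmax())
    labels = labelings[chosen]
    widths = silhouette_samples(x, labels)
    return ClusterSolution(
        k=chosen,
        labels=labels,
        silhouette_widths=widths,
        mean_silhouette=float(widths.mean()),
        panel=panel,
        votes=votes,
        rationale="argmax of mean silhouette width; panel votes recorded",
        invalid_k=invalid,
    )
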