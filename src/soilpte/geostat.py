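"""Variogram estimation and ordinary kriging.

The contamination surface is interpolated from site-level principal
component scores by ordinary kriging: a best linear unbiased predictor
whose weights, constrained to sum to one, come from a fitted variogram.
At survey scale (tens to a few hundred sites) every observation sits in
the kriging neighbourhood and the dense system is solved directly.

Variogram families: spherical (default), exponential, gaussian, each
parameterised by nugget, partial sill and range. The empirical variogram
uses equal-width lag bins of the classical Matheron estimator, and the
model is fitted by weighted least squares with Cressie-style weights
(pair count / model value squared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull, Delaunay
from scipy.spatial.distance import cdist, pdist, squareform

FAMILIES = ("spherical", "exponential", "gaussian")


def _model_gamma(family: str, h, nugget: float, psill: float, range_: float):
    h = np.asarray(h, float)
    if family == "spherical":
        r = np.clip(h / range_, 0.0, 1.0)
        struct = 1.5 * r - 0.5 * r**3
    elif family == "exponential":
        struct = 1.0 - np.exp(-3.0 * h / range_)
    elif family == "gaussian":
        struct = 1.0 - np.exp(-3.0 * (h / range_) ** 2)
    else:
        raise ValueError(f"unknown variogram family {family!r}")
    gamma = nugget + psill * struct
    return np.where(h == 0, 0.0, gamma)


@dataclass
class VariogramModel:
    """Fitted variogram: family, nugget, partial sill and range (m)."""

    family: str
    nugget: float
    psill: float
    range_: float
    lags: np.ndarray | None = None
    gamma: np.ndarray | None = None
    pair_counts: np.ndarray | None = None
    fit_method: str = "wls"

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ValueError("nugget/psill must be >= 0 and range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def __call__(self, h) -> np.ndarray:
        """Model semivariance at lag distance(s) h."""
        return _model_gamma(self.family, h, self.nugget, self.psill, self.range_)


def empirical_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    n_lags: int = 12,
    max_dist: float | None = None,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Matheron empirical variogram on equal-width lag bins.

    Returns a frame with lag centre, semivariance, pair count and a
    ``reliable`` flag (pair count >= ``min_pairs``).
    """
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    if len(coords) < 2:
        raise ValueError("need at least 2 sites for an empirical variogram")
    # < ~10 sites gives too few pairs for stable bins; flagged, not fatal
    d = pdist(coords)
    if d.max() == 0:
        raise ValueError("all points coincident")
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    if max_dist is None:
        max_dist = d.max() / 2.0
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (d > lo) & (d <= hi)
        n_pairs = int(mask.sum())
        rows.append(
            {
                "lag": (lo + hi) / 2.0,
                "gamma": float(sq[mask].mean()) if n_pairs else np.nan,
                "n_pairs": n_pairs,
                "reliable": n_pairs >= min_pairs,
            }
        )
    return pd.DataFrame(rows)


def fit_variogram(
    lag_table: pd.DataFrame, family: str = "spherical"
) -> VariogramModel:
    """Weighted least-squares fit of a variogram family to a lag table.

    Weights are pair_count / gamma_model^2 (Cressie). Bounded optimisation
    from moment-based starting values; if the solver fails, a coarse grid
    search over the bounded space is used and flagged.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown variogram family {family!r}")
    tab = lag_table.dropna(subset=["gamma"])
    tab = tab[tab["n_pairs"] > 0]
    if len(tab) < 3:
        raise ValueError("need >= 3 non-empty lag bins")
    h = tab["lag"].to_numpy(float)
    g = tab["gamma"].to_numpy(float)
    npairs = tab["n_pairs"].to_numpy(float)

    sill0 = max(g.mean(), 1e-12)
    lo = np.array([0.0, 0.0, h.min() / 10.0])
    hi = np.array([2.0 * g.max() + 1e-9, 4.0 * g.max() + 1e-9, 3.0 * h.max()])

    def residuals(theta):
        nugget, psill, range_ = theta
        gm = _model_gamma(family, h, nugget, psill, range_)
        w = np.sqrt(npairs) / np.maximum(gm, 1e-12)
        return w * (gm - g)

    x0 = np.array([0.1 * sill0, 0.9 * sill0, h.max() / 2.0])
    fit_method = "wls"
    try:
        sol = least_squares(residuals, x0, bounds=(lo, hi))
        theta = sol.x
        if not sol.success:
            raise RuntimeError(sol.message)
    except Exception:
        fit_method = "grid"
        best, best_loss = x0, np.inf
        for nug in np.linspace(lo[0], g.max(), 8):
            for ps in np.linspace(1e-9, hi[1], 12):
                for rg in np.geomspace(lo[2], hi[2], 15):
                    loss = float(np.sum(residuals([nug, ps, rg]) ** 2))
                    if loss < best_loss:
                        best, best_loss = np.array([nug, ps, rg]), loss
        theta = best
    return VariogramModel(
        family=family,
        nugget=float(theta[0]),
        psill=float(theta[1]),
        range_=float(theta[2]),
        lags=h,
        gamma=g,
        pair_counts=npairs,
        fit_method=fit_method,
    )


@dataclass
class KrigedSurface:
    """Regular-grid kriging prediction with variance and hull mask."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    prediction: np.ndarray  # (ny, nx), NaN outside mask
    variance: np.ndarray
    mask: np.ndarray  # True where prediction is supported
    cell_size: float

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "value": self.prediction.ravel(),
                "variance": self.variance.ravel(),
                "inside": self.mask.ravel(),
            }
        )

    def peak_location(self) -> tuple[float, float]:
        """(x, y) of the masked-surface maximum."""
        masked = np.where(self.mask, self.prediction, -np.inf)
        iy, ix = np.unravel_index(np.nanargmax(masked), masked.shape)
        return float(self.grid_x[ix]), float(self.grid_y[iy])


def kriging_weights(
    model: VariogramModel, coords: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary kriging weights and Lagrange multipliers for target points.

    Returns ``(weights (m, n), mu (m,))``; each weight row sums to 1.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    gamma = model(squareform(pdist(coords)))
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma
    a[n, :] = 1.0
    a[:, n] = 1.0
    a[n, n] = 0.0
    b = np.empty((n + 1, len(targets)))
    b[:n, :] = model(cdist(coords, np.asarray(targets, float)))
    b[n, :] = 1.0
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular kriging system (duplicate sites?)"
        ) from exc
    return sol[:n].T, sol[n]


def ordinary_krige(
    model: VariogramModel,
    coords: np.ndarray,
    values: np.ndarray,
    cell_size: float = 100.0,
    buffer: float = 250.0,
) -> KrigedSurface:
    """Ordinary kriging of point values onto a regular grid.

    Predictions are masked beyond ``buffer`` metres of the sample convex
    hull to avoid unsupported extrapolation. Duplicate sites are averaged
    with a warning-free deduplication.
    """
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    if len(coords) < 5:
        raise ValueError("need >= 5 sites to krige")
    # deduplicate exact coordinate repeats (singular system otherwise)
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) < len(coords):
        agg = np.zeros(len(uniq))
        counts = np.bincount(inverse)
        np.add.at(agg, inverse, values)
        coords, values = uniq, agg / counts

    x0, y0 = coords.min(axis=0) - buffer
    x1, y1 = coords.max(axis=0) + buffer
    gx = np.arange(x0, x1 + cell_size, cell_size)
    gy = np.arange(y0, y1 + cell_size, cell_size)
    xx, yy = np.meshgrid(gx, gy)
    targets = np.column_stack([xx.ravel(), yy.ravel()])

    hull = Delaunay(coords[ConvexHull(coords).vertices])
    inside = hull.find_simplex(targets) >= 0
    near = cdist(targets, coords).min(axis=1) <= buffer
    mask = (inside | near).reshape(xx.shape)

    w, mu = kriging_weights(model, coords, targets)
    pred = w @ values
    gamma_t = model(cdist(coords, targets))
    var = np.maximum((w * gamma_t.T).sum(axis=1) + mu, 0.0)

    pred = np.where(mask.ravel(), pred, np.nan).reshape(xx.shape)
    var = np.where(mask.ravel(), var, np.nan).reshape(xx.shape)
    return KrigedSurface(gx, gy, pred, var, mask, cell_size)
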