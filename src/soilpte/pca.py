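"""Principal component analysis of clr coordinates, with diagnostics.

The model is fitted statsmodels-style::

    results = CompositionalPCA(clr).fit()
    results.summary()

clr variables are standardised to unit variance before the
eigendecomposition, so eigenvalues live on the correlation scale and the
Kaiser "eigenvalue > 1" retention rule is meaningful. The clr closure
constraint makes the correlation matrix rank-deficient by one; the null
direction simply appears as a ~0 trailing eigenvalue and is never retained.

Diagnostics follow standard chemometric practice: Kaiser-Meyer-Olkin
sampling adequacy, Bartlett's sphericity test, leave-one-out reconstruction
RMSE, and Hotelling T^2 / Q-residual outlier screening with F-based and
Jackson-Mudholkar 95% limits respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _correlation_matrix(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant column: correlation undefined")
    r = (xc / sd).T @ (xc / sd) / (len(x) - 1)
    return (r + r.T) / 2.0


def sampling_adequacy(
    clr: pd.DataFrame, rcond: float = 1e-8
) -> tuple[float, float, int, float]:
    """KMO index and Bartlett's sphericity test on the clr correlation matrix.

    Returns ``(kmo, chi2, df, p)``. The clr closure makes the correlation
    matrix exactly singular along one direction; that null direction is
    truncated (pseudo-inverse for the partial correlations, pseudo-
    determinant over the retained eigenvalues for Bartlett) rather than
    regularised, with a warning. ``df`` stays p(p-1)/2 as in the classical
    test.
    """
    x = np.asarray(clr, float)
    n, p = x.shape
    r = _correlation_matrix(x)
    evals = np.linalg.eigvalsh(r)
    singular = np.linalg.cond(r) > 1e10
    if singular:
        warnings.warn(
            "singular correlation matrix (clr closure); null direction "
            "truncated for partial correlations and log-determinant",
            stacklevel=2,
        )
    inv = np.linalg.pinv(r, rcond=rcond, hermitian=True)
    d = np.sqrt(np.diag(inv))
    partial = -inv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    kmo = float(np.sum(r[off] ** 2)
                / (np.sum(r[off] ** 2) + np.sum(partial[off] ** 2)))
    kept = evals[evals > rcond * evals.max()]
    logdet = float(np.sum(np.log(kept)))
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    p_value = float(stats.chi2.sf(chi2, df))
    return kmo, float(chi2), int(df), p_value


def bartlett_df(p: int) -> int:
    """Degrees of freedom of Bartlett's sphericity test for p variables."""
    return p * (p - 1) // 2


class CompositionalPCA:
    """PCA model for a clr-coordinate matrix (sites x elements)."""

    def __init__(self, clr: pd.DataFrame, standardize: bool = True):
        self.clr = pd.DataFrame(clr).astype(float)
        self.standardize = standardize
        n, p = self.clr.shape
        if n <= 2:
            raise ValueError("need at least 3 sites")
        if n < p:
            warnings.warn(
                f"fewer sites ({n}) than elements ({p}): rank-deficient fit",
                stacklevel=2,
            )

    def fit(self) -> "CompositionalPCAResults":
        x = self.clr.to_numpy()
        mean = x.mean(axis=0)
        xc = x - mean
        scale = xc.std(axis=0, ddof=1) if self.standardize else np.ones(x.shape[1])
        if (scale == 0).any():
            raise ValueError("constant clr column")
        z = xc / scale
        # eigendecomposition of the (co)rrelation matrix
        r = z.T @ z / (len(z) - 1)
        evals, evecs = np.linalg.eigh((r + r.T) / 2.0)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # sign convention: largest-|loading| entry of each component positive
        for k in range(evecs.shape[1]):
            j = np.argmax(np.abs(evecs[:, k]))
            if evecs[j, k] < 0:
                evecs[:, k] *= -1.0
        scores = z @ evecs
        comp = [f"PC{k + 1}" for k in range(evecs.shape[1])]
        return CompositionalPCAResults(
            model=self,
            loadings=pd.DataFrame(evecs, index=self.clr.columns, columns=comp),
            eigenvalues=evals,
            scores=pd.DataFrame(scores, index=self.clr.index, columns=comp),
            mean=mean,
            scale=scale,
        )


@dataclass
class CompositionalPCAResults:
    """Fitted clr-PCA: loadings, eigenvalues, scores and diagnostics."""

    model: CompositionalPCA
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    scores: pd.DataFrame
    mean: np.ndarray
    scale: np.ndarray

    @property
    def variance_fraction(self) -> np.ndarray:
        """Percent of total variance per component (sums to 100)."""
        return 100.0 * self.eigenvalues / self.eigenvalues.sum()

    @property
    def n_retained(self) -> int:
        """Kaiser criterion: eigenvalues strictly greater than one."""
        n = int((self.eigenvalues > 1.0).sum())
        if n == 0:
            warnings.warn("no eigenvalue exceeds 1; nothing retained", stacklevel=2)
        return n

    @property
    def squared_loadings(self) -> pd.DataFrame:
        return self.loadings**2

    def retained_scores(self, retained: int | None = None) -> pd.DataFrame:
        a = self.n_retained if retained is None else retained
        return self.scores.iloc[:, :a]

    def orient(self, elements: list[str]) -> "CompositionalPCAResults":
        """Flip components so the mean loading over ``elements`` is positive.

        Used to fix PC1 chalcophile-positive before trend analysis; flags
        and eigenvalues are invariant to the flip.
        """
        loadings = self.loadings.copy()
        scores = self.scores.copy()
        for comp in loadings.columns:
            if loadings.loc[list(elements), comp].mean() < 0:
                loadings[comp] *= -1.0
                scores[comp] *= -1.0
        return CompositionalPCAResults(
            self.model, loadings, self.eigenvalues.copy(), scores,
            self.mean.copy(), self.scale.copy(),
        )

    # -- diagnostics --------------------------------------------------------

    def sampling_adequacy(self) -> tuple[float, float, int, float]:
        return sampling_adequacy(self.model.clr)

    def loo_rmse(self, retained: int | None = None) -> float:
        """Leave-one-out reconstruction RMSE, % of total clr SD.

        Each site is held out, the PCA refitted on the rest, the held-out
        row projected onto the retained components and reconstructed; the
        RMSE of all reconstruction residuals (in clr units) is expressed
        as a percentage of the pooled clr standard deviation.
        """
        a = self.n_retained if retained is None else int(retained)
        if a <= 0:
            raise ValueError("retained components must be >= 1")
        x = self.model.clr.to_numpy()
        n = len(x)
        resid = np.empty_like(x)
        for i in range(n):
            train = np.delete(x, i, axis=0)
            mean = train.mean(axis=0)
            scale = (
                train.std(axis=0, ddof=1)
                if self.model.standardize
                else np.ones(x.shape[1])
            )
            z = (train - mean) / scale
            r = z.T @ z / (len(z) - 1)
            evals, evecs = np.linalg.eigh((r + r.T) / 2.0)
            v = evecs[:, np.argsort(evals)[::-1][:a]]
            zi = (x[i] - mean) / scale
            resid[i] = (zi - v @ (v.T @ zi)) * scale
        total_sd = np.std(x - x.mean(axis=0), ddof=1)
        return float(100.0 * np.sqrt(np.mean(resid**2)) / total_sd)

    def t2_q(self, retained: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
        """Hotelling T^2 and Q residual per site with (1-alpha) limits.

        T^2 sums squared retained scores over their eigenvalues, with the
        F-based limit A(n^2-1)/(n(n-A)) * F(A, n-A). Q is the squared
        reconstruction residual in standardised units, with the
        Jackson-Mudholkar limit from the discarded eigenvalues; if no
        variance is discarded the Q limit is skipped.
        """
        a = self.n_retained if retained is None else int(retained)
        if a < 1:
            raise ValueError("retained components must be >= 1")
        n, p = self.model.clr.shape
        t = self.scores.to_numpy()[:, :a]
        lam = self.eigenvalues[:a]
        t2 = (t**2 / lam).sum(axis=1)
        t2_lim = a * (n - 1) * (n + 1) / (n * (n - a)) * stats.f.ppf(1 - alpha, a, n - a)

        v = self.loadings.to_numpy()[:, :a]
        z = (self.model.clr.to_numpy() - self.mean) / self.scale
        resid = z - z @ v @ v.T
        q = (resid**2).sum(axis=1)
        rest = self.eigenvalues[a:]
        rest = rest[rest > 1e-12]
        if rest.size == 0:
            q_lim = np.nan  # all variance retained: Q identically ~0
        else:
            th1, th2, th3 = (float((rest**m).sum()) for m in (1, 2, 3))
            h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
            if h0 <= 0:
                h0 = 1e-3
            c = stats.norm.ppf(1 - alpha)
            q_lim = th1 * (
                c * np.sqrt(2.0 * th2 * h0**2) / th1
                + 1.0
                + th2 * h0 * (h0 - 1.0) / th1**2
            ) ** (1.0 / h0)
        outlier = t2 > t2_lim
        if np.isfinite(q_lim):
            outlier = outlier | (q > q_lim)
        return pd.DataFrame(
            {
                "t2": t2,
                "q": q,
                "t2_limit": t2_lim,
                "q_limit": q_lim,
                "outlier": outlier,
            },
            index=self.scores.index,
        )

    def outlier_sites(self, retained: int | None = None, alpha: float = 0.05):
        tq = self.t2_q(retained, alpha)
        return list(tq.index[tq["outlier"]])

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        lines = ["Compositional PCA (standardised clr coordinates)"]
        lines.append(f"  sites: {len(self.scores)}   elements: {len(self.loadings)}")
        kmo, chi2, df, p_val = self.sampling_adequacy()
        lines.append(f"  KMO = {kmo:.2f}   Bartlett chi2 = {chi2:.0f}, "
                     f"df = {df}, p = {p_val:.2g}")
        lines.append(f"  retained (Kaiser, eigenvalue > 1): {self.n_retained}")
        lines.append("  component  eigenvalue  %variance  cumulative%")
        cum = 0.0
        for k, (ev, vf) in enumerate(zip(self.eigenvalues, self.variance_fraction)):
            cum += vf
            lines.append(f"  PC{k + 1:<8d} {ev:10.3f} {vf:10.1f} {cum:12.1f}")
            if k >= max(self.n_retained, 4) - 1:
                break
        return "\n".join(lines)
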