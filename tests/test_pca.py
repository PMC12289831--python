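"""clr-PCA model, retention rule, adequacy diagnostics, outlier screening."""

import numpy as np
import pandas as pd
import pytest

from soilpte import CompositionalPCA, clr_transform, sampling_adequacy
from soilpte.pca import CompositionalPCAResults, bartlett_df
from soilpte.references import CHALCOPHILE


def _results_with_eigenvalues(evals):
    evals = np.asarray(evals, float)
    p = len(evals)
    dummy = pd.DataFrame(np.eye(p))
    model = CompositionalPCA.__new__(CompositionalPCA)
    model.clr = pd.DataFrame(np.zeros((3, p)))
    model.standardize = True
    return CompositionalPCAResults(
        model=model,
        loadings=dummy,
        eigenvalues=evals,
        scores=pd.DataFrame(np.zeros((3, p))),
        mean=np.zeros(p),
        scale=np.ones(p),
    )


class TestFit:
    def test_eigenvalue_sum_equals_trace(self, clr_default, pca_default):
        z = (clr_default - clr_default.mean()) / clr_default.std(ddof=1)
        trace = np.trace(np.cov(z.to_numpy().T, ddof=1))
        assert pca_default.eigenvalues.sum() == pytest.approx(trace, rel=1e-10)
        assert pca_default.variance_fraction.sum() == pytest.approx(100.0)

    def test_closure_null_eigenvalue(self, pca_default):
        assert pca_default.eigenvalues[-1] == pytest.approx(0.0, abs=1e-8)

    def test_dominant_trend_concentrates_variance(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal(60)
        x = np.outer(t, rng.uniform(1, 2, 6)) + 0.01 * rng.standard_normal((60, 6))
        res = CompositionalPCA(pd.DataFrame(x), standardize=False).fit()
        assert res.variance_fraction[0] > 90

    def test_orthonormal_loadings_and_uncorrelated_scores(self, pca_default):
        ld = pca_default.loadings.to_numpy()
        np.testing.assert_allclose(ld.T @ ld, np.eye(ld.shape[1]), atol=1e-8)
        s = pca_default.scores.to_numpy()[:, :4]
        c = np.corrcoef(s.T)
        np.testing.assert_allclose(c - np.diag(np.diag(c)), 0.0, atol=1e-8)

    def test_two_source_loading_contrast(self, pca_default):
        """Plume elements load with one sign on PC1, the mafic set opposite."""
        pc1 = pca_default.orient(list(CHALCOPHILE)).loadings["PC1"]
        assert (pc1[["As", "Cd", "Cu", "Pb", "Zn"]] > 0).all()
        assert (pc1[["Cr", "Ni", "V"]] < 0).all()


class TestKaiserRetention:
    def test_strictly_greater_than_one(self):
        assert _results_with_eigenvalues([5.2, 1.4, 1.14, 0.9]).n_retained == 3

    def test_boundary_eigenvalue_not_retained(self):
        assert _results_with_eigenvalues([2.0, 1.0, 0.5]).n_retained == 1

    def test_none_retained_warns(self):
        res = _results_with_eigenvalues([0.9, 0.8])
        with pytest.warns(UserWarning, match="nothing retained"):
            assert res.n_retained == 0


class TestSamplingAdequacy:
    def test_bartlett_df_formula(self):
        assert bartlett_df(14) == 91
        assert bartlett_df(3) == 3

    def test_independent_noise_not_spherical(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.standard_normal((500, 5)))
        _, chi2, df, p = sampling_adequacy(x)
        assert chi2 < 20 and p > 0.05

    def test_kmo_matches_textbook_three_variable_oracle(self):
        # build data whose sample correlation is exactly R, then compare
        # against the closed-form partial-correlation KMO
        r_ab, r_ac, r_bc = 0.6, 0.4, 0.5
        r = np.array([[1, r_ab, r_ac], [r_ab, 1, r_bc], [r_ac, r_bc, 1.0]])
        rng = np.random.default_rng(1)
        n = 40
        q, _ = np.linalg.qr(rng.standard_normal((n, 4)))
        basis = q[:, 1:4] - q[:, 1:4].mean(axis=0)
        basis, _ = np.linalg.qr(basis)
        x = basis @ np.linalg.cholesky(r).T * np.sqrt(n - 1)
        kmo, _, _, _ = sampling_adequacy(pd.DataFrame(x))

        def partial(rij, rik, rjk):
            return (rij - rik * rjk) / np.sqrt((1 - rik**2) * (1 - rjk**2))

        p_ab = partial(r_ab, r_ac, r_bc)
        p_ac = partial(r_ac, r_ab, r_bc)
        p_bc = partial(r_bc, r_ab, r_ac)
        ssr = 2 * (r_ab**2 + r_ac**2 + r_bc**2)
        ssp = 2 * (p_ab**2 + p_ac**2 + p_bc**2)
        assert kmo == pytest.approx(ssr / (ssr + ssp), abs=1e-8)


class TestLooRmse:
    def test_full_rank_reconstruction_near_zero(self, pca_default):
        full = len(pca_default.eigenvalues)
        assert pca_default.loo_rmse(retained=full) < 1.0  # closure tolerance

    def test_rank_one_structure_recovered(self):
        rng = np.random.default_rng(2)
        t = rng.standard_normal(40)
        comp = np.exp(np.outer(t, [1.0, -0.5, 0.3, -0.8]))
        comp += rng.uniform(0, 1e-3, comp.shape)
        clr = clr_transform(pd.DataFrame(comp / comp.sum(1, keepdims=True)))
        res = CompositionalPCA(clr, standardize=False).fit()
        assert res.loo_rmse(retained=1) < 5.0

    def test_monotone_in_retained(self, pca_default):
        vals = [pca_default.loo_rmse(retained=a) for a in (1, 3, 5, 13)]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_zero_retained_rejected(self, pca_default):
        with pytest.raises(ValueError):
            pca_default.loo_rmse(retained=0)


class TestOutlierScreening:
    def test_centroid_site_not_flagged(self):
        rng = np.random.default_rng(3)
        half = rng.standard_normal((15, 5))
        x = np.vstack([half, -half, np.zeros(5)])  # last row = exact centroid
        res = CompositionalPCA(pd.DataFrame(x), standardize=False).fit()
        tq = res.t2_q(retained=2)
        assert tq["t2"].iloc[-1] == pytest.approx(0.0, abs=1e-12)
        assert not tq["outlier"].iloc[-1]

    def test_flags_invariant_to_sign_convention(self, default_survey, pca_default):
        oriented = pca_default.orient(list(CHALCOPHILE))
        a = pca_default.t2_q(retained=2)
        b = oriented.t2_q(retained=2)
        np.testing.assert_allclose(a["t2"], b["t2"], atol=1e-10)
        np.testing.assert_allclose(a["q"], b["q"], atol=1e-10)
        assert (a["outlier"] == b["outlier"]).all()

    def test_all_retained_skips_q_limit(self, pca_default):
        full = int((pca_default.eigenvalues > 1e-12).sum())
        tq = pca_default.t2_q(retained=full)
        assert np.isnan(tq["q_limit"].iloc[0])
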