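"""Tests of standardization and correlation-matrix PCA against brute-force
eigendecomposition oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gipca.decomposition import fit_pca, project, standardize
from gipca.registry import FEATURES
from gipca.synthetic import default_cohort_spec, simulate_cohort


class TestStandardize:
    def test_moments_after_standardization(self, rng):
        X = rng.normal(5, 3, size=(40, 6)) * [1, 10, 100, 1e3, 1e-3, 1]
        Z, mu, sd = standardize(X)
        assert np.abs(Z.mean(0)).max() < 1e-12
        assert np.allclose(Z.std(0, ddof=1), 1.0)

    def test_unit_change_invariance(self, rng):
        X = rng.normal(size=(30, 3))
        Z1, *_ = standardize(X)
        Z2, *_ = standardize(X * 1000.0)  # e.g. m -> mm
        assert np.allclose(Z1, Z2)

    def test_round_trip(self, rng):
        X = rng.normal(2, 7, size=(25, 4))
        Z, mu, sd = standardize(X)
        assert np.abs(Z * sd + mu - X).max() < 1e-12

    def test_zero_variance_column_named(self):
        df = simulate_cohort(default_cohort_spec(seed=0))
        df["fz_peak"] = 800.0
        with pytest.raises(ValueError, match="fz_peak"):
            fit_pca(df)


class TestFitPca:
    def test_collinear_data_single_component(self, rng):
        u = rng.normal(size=50)
        X = np.column_stack([u, -2 * u])  # exactly on a line
        model = fit_pca(X)
        assert model.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)
        assert model.explained_fraction[1] == pytest.approx(0.0, abs=1e-12)
        # PC1 parallel to the (standardized) line direction
        assert abs(model.loadings[:, 0] @ [1, -1] / np.sqrt(2)) == \
            pytest.approx(1.0, abs=1e-10)

    def test_isotropic_sample_splits_variance(self, rng):
        X = rng.normal(size=(10_000, 2))
        model = fit_pca(X)
        assert 0.49 < model.explained_fraction[0] < 0.51

    @pytest.mark.parametrize("n", [5, 12, 50])
    def test_matches_eigh_oracle(self, n, rng):
        """Eigenvalues and eigenvectors agree with an independent
        eigendecomposition of the sample correlation matrix."""
        X = rng.normal(size=(n, 11)) @ rng.normal(size=(11, 11))
        model = fit_pca(X)
        R = np.corrcoef(X, rowvar=False) * (n - 1) / (n - 1)
        # oracle: direct symmetric eigendecomposition
        Z, *_ = standardize(X)
        S = Z.T @ Z / (n - 1)
        w, V = np.linalg.eigh(S)
        w, V = w[::-1], V[:, ::-1]
        assert np.abs(model.eigenvalues - np.clip(w, 0, None)).max() < 1e-8
        for j in range(11):
            near_next = j + 1 < 11 and w[j] - w[j + 1] < 1e-6
            near_prev = j > 0 and w[j - 1] - w[j] < 1e-6
            if near_next or near_prev:
                continue  # nearly degenerate: direction not identified
            assert abs(abs(model.loadings[:, j] @ V[:, j]) - 1) < 1e-8

    def test_orthonormal_loadings(self, cohort_table):
        model = fit_pca(cohort_table)
        p = len(FEATURES)
        assert np.abs(model.loadings.T @ model.loadings - np.eye(p)).max() \
            < 1e-10
        assert model.explained_fraction.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(model.explained_fraction) <= 1e-15)

    def test_sign_convention_deterministic(self, cohort_table):
        m1 = fit_pca(cohort_table)
        m2 = fit_pca(cohort_table.iloc[::-1].reset_index(drop=True))
        for j in range(3):
            assert np.allclose(m1.loadings[:, j], m2.loadings[:, j],
                               atol=1e-8)

    def test_three_factor_population_concentrates_variance(self):
        """On a large cohort from the three-factor population, three
        components carry ~99.9% of the variance."""
        df = simulate_cohort(default_cohort_spec(
            n_control=2000, n_pd=2000, effect_scale=0.0, seed=9))
        model = fit_pca(df)
        assert np.cumsum(model.explained_fraction)[2] >= 0.999 - 2e-3

    def test_leading_subspace_converges_to_population(self):
        """Principal angle between the estimated and population top-3
        subspaces shrinks below 2 degrees at n = 10,000."""
        from gipca.synthetic import default_correlation
        df = simulate_cohort(default_cohort_spec(
            n_control=5000, n_pd=5000, effect_scale=0.0, seed=11))
        model = fit_pca(df)
        w, V = np.linalg.eigh(default_correlation())
        pop = V[:, ::-1][:, :3]
        est = model.loadings[:, :3]
        sv = np.linalg.svd(pop.T @ est, compute_uv=False)
        angle = np.degrees(np.arccos(np.clip(sv.min(), -1, 1)))
        assert angle < 2.0


class TestProject:
    def test_full_projection_preserves_variance(self, cohort_table):
        model = fit_pca(cohort_table)
        scores = project(model, cohort_table)
        p = len(FEATURES)
        assert scores.var(axis=0, ddof=1).sum() == pytest.approx(p, rel=1e-10)

    def test_training_scores_uncorrelated(self, cohort_table):
        model = fit_pca(cohort_table)
        scores = project(model, cohort_table, 4)
        r = np.corrcoef(scores, rowvar=False)
        assert np.abs(r - np.eye(4)).max() < 1e-10

    def test_constructed_spectrum_k3_reaches_999(self, rng):
        """A covariance with three dominant eigenvalues leaves <0.1% for the
        rest; k = 3 captures it."""
        Q, _ = np.linalg.qr(rng.normal(size=(11, 11)))
        lam = np.array([5.0, 3.5, 2.49] + [1e-4] * 8)
        X = rng.multivariate_normal(np.zeros(11), (Q * lam) @ Q.T, size=4000)
        model = fit_pca(X)
        assert np.cumsum(model.explained_fraction)[2] >= 0.999
        assert model.n_components_for(0.999) == 3

    def test_column_mismatch_named(self, cohort_table):
        model = fit_pca(cohort_table)
        with pytest.raises(ValueError, match="missing columns"):
            project(model, cohort_table.drop(columns=["fz_peak"]))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_row_permutation_equivariance(self, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(15, 5))
        model = fit_pca(X)
        perm = r.permutation(15)
        assert np.allclose(project(model, X)[perm], project(model, X[perm]))

    def test_sklearn_cross_check(self, cohort_table):
        """Independent library implementation agrees on eigenvalues and
        score magnitudes."""
        from sklearn.decomposition import PCA

        model = fit_pca(cohort_table)
        Z, *_ = standardize(
            cohort_table.loc[:, list(FEATURES)].to_numpy(float))
        sk = PCA(n_components=5).fit(Z)
        assert np.allclose(sk.explained_variance_[:5],
                           model.eigenvalues[:5], atol=1e-10)
        ours = project(model, cohort_table, 5)
        theirs = sk.transform(Z)
        assert np.allclose(np.abs(ours), np.abs(theirs), atol=1e-8)
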