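"""PCA/PLS engines against SVD, scikit-learn and least-squares oracles."""

import numpy as np
import pandas as pd
import pytest

from glycosar.chemometrics import (
    dmodx,
    fit_pca,
    fit_pls,
    permutation_test,
    pls_coefficients,
    preprocess,
)


class TestPreprocess:
    def test_column_example(self):
        out = preprocess(pd.DataFrame({"c": [1.0, 2.0, 3.0]}))
        assert out.data["c"].tolist() == [-1.0, 0.0, 1.0]  # sd already 1 after centering

    def test_postconditions_on_random_matrix(self, rng):
        out = preprocess(rng.normal(2.0, 3.0, size=(10, 5)))
        assert np.allclose(out.data.mean(), 0, atol=1e-12)
        assert np.allclose(out.data.std(ddof=1), 1, atol=1e-12)

    def test_centering_idempotent(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 3)))
        once = preprocess(X, center=True, uv_scale=False)
        twice = preprocess(once.data, center=True, uv_scale=False)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_inverse_transform_round_trip(self, rng):
        X = pd.DataFrame(rng.normal(5, 2, size=(9, 4)))
        out = preprocess(X)
        pd.testing.assert_frame_equal(out.inverse_transform(), X)

    def test_constant_column_dropped_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=6), "b": np.ones(6)})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = preprocess(X)
        assert list(out.data.columns) == ["a"]

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            preprocess(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))


class TestPca:
    def test_rank_one_single_component(self, rng):
        u, v = rng.normal(size=10), rng.normal(size=4)
        m = fit_pca(pd.DataFrame(np.outer(u, v)), 1, cv=False)
        assert m.r2x_cum[-1] == pytest.approx(1.0)

    def test_matches_svd_oracle(self, rng):
        X = preprocess(rng.normal(size=(20, 8))).data
        m = fit_pca(X, 5, cv=False)
        U, s, Vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
        assert np.allclose(m.r2x, s[:5] ** 2 / np.sum(s**2), atol=1e-8)
        for a in range(5):  # loadings equal up to sign
            dot = abs(np.dot(m.loadings.iloc[:, a], Vt[a]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn_explained_variance(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = preprocess(rng.normal(size=(25, 6))).data
        m = fit_pca(X, 3, cv=False)
        sk = sklearn.PCA(n_components=3).fit(X.to_numpy())
        assert np.allclose(m.r2x, sk.explained_variance_ratio_, atol=1e-8)

    def test_loadings_orthonormal_scores_orthogonal(self, rng):
        X = preprocess(rng.normal(size=(15, 6))).data
        m = fit_pca(X, 4, cv=False)
        P = m.loadings.to_numpy()
        assert np.allclose(P.T @ P, np.eye(4), atol=1e-10)
        TT = m.scores.to_numpy().T @ m.scores.to_numpy()
        assert np.allclose(TT - np.diag(np.diag(TT)), 0, atol=1e-8)

    def test_r2x_cum_nondecreasing_bounded(self, rng):
        X = preprocess(rng.normal(size=(12, 7))).data
        m = fit_pca(X, 6, cv=False)
        assert (np.diff(m.r2x_cum) >= -1e-12).all() and m.r2x_cum[-1] <= 1 + 1e-12

    def test_latent_factor_structure_recovered(self, rng):
        W, H = rng.normal(size=(30, 3)), rng.normal(size=(3, 12))
        X = preprocess(W @ H + 0.05 * rng.normal(size=(30, 12)))
        m = fit_pca(X, 3, cv=False)
        assert m.r2x_cum[-1] > 0.95

    def test_cv_q2_high_for_structured_low_for_noise(self, rng):
        W, H = rng.normal(size=(30, 3)), rng.normal(size=(3, 10))
        structured = preprocess(W @ H + 0.05 * rng.normal(size=(30, 10)))
        assert fit_pca(structured, 3).q2_cum > 0.9
        noise = preprocess(rng.normal(size=(30, 10)))
        assert fit_pca(noise, 3).q2_cum < 0.3

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            fit_pca(pd.DataFrame(rng.normal(size=(5, 3))), 5)


class TestDmodx:
    def test_in_plane_observation_zero(self, rng):
        # exactly rank-2 cohort: every observation sits in the model plane
        basis = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        T = rng.normal(size=(20, 2))
        X = pd.DataFrame(T @ basis.T)
        m = fit_pca(X, 2, cv=False)
        assert m.dmodx.max() < 1e-8

    def test_planar_observation_in_noisy_cohort_near_zero(self, rng):
        X = rng.normal(size=(20, 6))
        m = fit_pca(pd.DataFrame(X), 2, cv=False)
        # an observation constructed inside the model plane
        planar = (m.loadings.to_numpy() @ np.array([1.5, -0.7]))[None, :]
        d = dmodx(m, pd.DataFrame(planar))
        assert d.iloc[0] < 1e-10

    def test_orthogonal_outlier_maximal(self, rng):
        basis = np.linalg.qr(rng.normal(size=(6, 3)))[0]
        X = rng.normal(size=(20, 2)) @ basis[:, :2].T + 0.01 * rng.normal(size=(20, 6))
        m = fit_pca(pd.DataFrame(X), 2, cv=False)  # fit on the clean cohort
        X_test = X.copy()
        X_test[7] += 5.0 * basis[:, 2]  # displace one observation off-plane
        d = dmodx(m, pd.DataFrame(X_test))
        assert d.idxmax() == 7

    def test_mean_near_one_for_random_data(self, rng):
        vals = []
        for rep in range(10):
            X = preprocess(np.random.default_rng(rep).normal(size=(40, 10))).data
            vals.append(fit_pca(X, 2, cv=False).dmodx.mean())
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)


class TestPls:
    def test_perfect_proportionality(self, rng):
        x = rng.normal(size=(15, 1))
        m = fit_pls(pd.DataFrame(x), 2.0 * x[:, 0], 1)
        assert m.r2y == pytest.approx(1.0)
        assert m.b.iloc[0] > 0

    def test_full_rank_equals_least_squares(self, rng):
        X = rng.normal(size=(20, 5))
        y = X @ rng.normal(size=5) + 0.3 * rng.normal(size=20)
        m = fit_pls(pd.DataFrame(X), y, 5, loo=False)
        Xc = np.column_stack([np.ones(20), X])
        beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
        assert np.allclose(m.predict(pd.DataFrame(X)), Xc @ beta, atol=1e-8)

    def test_matches_sklearn_predictions(self, rng):
        skpls = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(20, 8))
        y = X @ rng.normal(size=8) + 0.5 * rng.normal(size=20)
        m = fit_pls(pd.DataFrame(X), y, 3, loo=False)
        sk = skpls.PLSRegression(n_components=3, scale=True).fit(X, y)
        assert np.allclose(m.predict(pd.DataFrame(X)), sk.predict(X).ravel(), atol=1e-8)

    def test_loo_q2_matches_explicit_refit_oracle(self, rng):
        skpls = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(15, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=15)
        m = fit_pls(pd.DataFrame(X), y, 2)
        press = ss = 0.0
        for i in range(15):
            keep = np.arange(15) != i
            sk = skpls.PLSRegression(n_components=2, scale=True).fit(X[keep], y[keep])
            press += float((y[i] - sk.predict(X[i : i + 1]).ravel()[0]) ** 2)
            ss += float((y[i] - y[keep].mean()) ** 2)
        assert m.q2_cum == pytest.approx(1 - press / ss, abs=1e-8)

    def test_null_response_negative_q2_in_expectation(self):
        q2s = []
        for rep in range(20):
            r = np.random.default_rng(rep)
            X = r.normal(size=(20, 8))
            y = r.normal(size=20)  # independent of X
            q2s.append(fit_pls(pd.DataFrame(X), y, 2).q2_cum)
        assert np.mean(q2s) <= 0

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_pls(pd.DataFrame(rng.normal(size=(10, 3))), np.ones(10), 1)

    def test_excess_latent_variables_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="n_lv"):
            fit_pls(pd.DataFrame(X), rng.normal(size=10), 7)

    def test_coefficients_named_and_ordered(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        m = fit_pls(X, rng.normal(size=12), 2, loo=False)
        assert list(pls_coefficients(m).index) == list("abcd")


class TestPermutation:
    def test_first_entry_is_unpermuted_baseline(self, rng):
        X = rng.normal(size=(15, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=15)
        rep = permutation_test(X, y, 2, n_perm=15, seed=0)
        assert rep.table.iloc[0]["correlation"] == 1.0

    def test_seed_fixed_bit_reproducible(self, rng):
        X = rng.normal(size=(15, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=15)
        a = permutation_test(X, y, 2, n_perm=12, seed=7)
        b = permutation_test(X, y, 2, n_perm=12, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_strong_signal_beats_all_permutations(self):
        r = np.random.default_rng(1)
        X = r.normal(size=(20, 6))
        y = X @ np.array([5.0, -4.0, 3.0, 0.0, 0.0, 2.0]) + 0.2 * r.normal(size=20)
        rep = permutation_test(X, y, 3, n_perm=100, seed=2)
        base = rep.table.iloc[0]
        perms = rep.table.iloc[1:]
        assert (perms["r2y"] < base["r2y"]).all()
        assert (perms["q2"] < base["q2"]).all()

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            permutation_test(rng.normal(size=(10, 3)), np.zeros(10), 1)

    def test_few_permutations_warns(self, rng):
        X = rng.normal(size=(12, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=12)
        with pytest.warns(UserWarning, match="10 permutations"):
            permutation_test(X, y, 1, n_perm=5, seed=0)
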