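"""Adequacy statistics, varimax rotation, and the PCA procedure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from biomon.apportionment import (PcaSolution, anti_image_msa, apportion,
                                  bartlett_sphericity, communalities_from_loadings,
                                  kmo, msa_eliminate, pca_varimax, spearman_screen,
                                  varimax, varimax_criterion)


def _exact_corr_data(R, n=400, seed=0):
    """Data whose sample correlation matrix equals R exactly (QR trick)."""
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, R.shape[0]))
    Z -= Z.mean(axis=0)
    Q, _ = np.linalg.qr(Z)
    Q -= Q.mean(axis=0)
    Q /= Q.std(axis=0, ddof=1)
    return Q @ np.linalg.cholesky(R).T


class TestSpearman:
    def test_monotone_transforms(self):
        x = np.arange(12, dtype=float)
        df = pd.DataFrame({"a": x, "b": np.exp(x / 3), "c": -x})
        sc = spearman_screen(df)
        assert sc.rho.loc["a", "b"] == pytest.approx(1.0)
        assert sc.rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_tied_ranks_match_pearson_on_ranks(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 2, 2, 4, 5])
        # oracle: average ranks by hand, then Pearson on the ranks
        ry = np.array([1.0, 2.5, 2.5, 4, 5])
        expect = np.corrcoef(stats.rankdata(x), ry)[0, 1]
        sc = spearman_screen(pd.DataFrame({"x": x, "y": y}))
        assert sc.rho.loc["x", "y"] == pytest.approx(expect)

    def test_small_n_exact_p_matches_enumeration_scale(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        sc = spearman_screen(pd.DataFrame({"x": x, "y": y}))
        p = sc.p.loc["x", "y"]
        assert 0 < p <= 1 and round(p * 120) == p * 120  # multiple of 1/5!

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            sc = spearman_screen(df)
        assert np.isnan(sc.rho.loc["a", "b"])


class TestBartlett:
    def test_identity_matrix(self):
        out = bartlett_sphericity(np.eye(5), n=50)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_two_variable_formula(self):
        # oracle: direct evaluation of the chi-square expression
        r, n, p = 0.9, 50, 2
        expect = -(n - 1 - (2 * p + 5) / 6) * np.log(1 - r**2)
        out = bartlett_sphericity(np.array([[1, r], [r, 1]]), n=n)
        assert out["chi2"] == pytest.approx(expect)
        assert out["df"] == 1

    def test_df_for_13_variables(self):
        R = np.eye(13)
        assert bartlett_sphericity(R, n=47)["df"] == 78


class TestKmoMsa:
    def test_two_variables_exactly_half(self):
        for r in (0.2, 0.5, 0.9):
            assert kmo(np.array([[1, r], [r, 1]])) == pytest.approx(0.5)

    def test_near_diagonal_partials_push_kmo_high(self):
        # one strong common factor: partials shrink, KMO approaches 1
        lam = np.full(6, 0.95)
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        assert kmo(R) > 0.9

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((60, 5))
        A[:, 1] += A[:, 0]
        A[:, 3] += A[:, 0]
        R = np.corrcoef(A, rowvar=False)
        perm = [3, 0, 4, 1, 2]
        Rp = R[np.ix_(perm, perm)]
        assert kmo(Rp) == pytest.approx(kmo(R))
        b1 = bartlett_sphericity(R, 60)
        b2 = bartlett_sphericity(Rp, 60)
        assert b1["chi2"] == pytest.approx(b2["chi2"])

    def test_msa_matches_residual_regression_oracle(self):
        # 3 correlated variables + 1 noise variable whose only correlations
        # are small chance values of mixed sign (as for truly independent data)
        R = np.array([
            [1.0, 0.8, 0.8, 0.10],
            [0.8, 1.0, 0.8, -0.12],
            [0.8, 0.8, 1.0, 0.05],
            [0.10, -0.12, 0.05, 1.0],
        ])
        X = _exact_corr_data(R, n=500, seed=1)
        # oracle: partial correlations via residuals of least-squares fits
        def partial(i, j):
            others = [k for k in range(4) if k not in (i, j)]
            Zo = np.column_stack([X[:, others], np.ones(len(X))])
            ri = X[:, i] - Zo @ np.linalg.lstsq(Zo, X[:, i], rcond=None)[0]
            rj = X[:, j] - Zo @ np.linalg.lstsq(Zo, X[:, j], rcond=None)[0]
            return np.corrcoef(ri, rj)[0, 1]

        msa = anti_image_msa(R)
        for i in range(4):
            r2 = sum(R[i, j] ** 2 for j in range(4) if j != i)
            p2 = sum(partial(i, j) ** 2 for j in range(4) if j != i)
            assert msa.iloc[i] == pytest.approx(r2 / (r2 + p2), abs=1e-9)
        assert msa.iloc[3] == msa.min()

    def test_eliminate_drops_noise_variable_first(self):
        R = pd.DataFrame(
            [[1.0, 0.8, 0.8, 0.10],
             [0.8, 1.0, 0.8, -0.12],
             [0.8, 0.8, 1.0, 0.05],
             [0.10, -0.12, 0.05, 1.0]],
            index=list("abcd"), columns=list("abcd"))
        retained, dropped = msa_eliminate(R, msa_threshold=0.5)
        assert retained == ["a", "b", "c"]
        assert dropped[0][0] == "d" and dropped[0][1] < 0.5

    def test_high_msa_block_untouched_and_threshold_zero_vacuous(self):
        lam = np.full(5, 0.9)
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        retained, dropped = msa_eliminate(pd.DataFrame(R), msa_threshold=0.5)
        assert dropped == [] and len(retained) == 5
        retained, dropped = msa_eliminate(pd.DataFrame(np.eye(5)), msa_threshold=0.0)
        assert dropped == []

    def test_keep_list_overrides_elimination(self):
        R = pd.DataFrame(
            [[1.0, 0.8, 0.8, 0.10],
             [0.8, 1.0, 0.8, -0.12],
             [0.8, 0.8, 1.0, 0.05],
             [0.10, -0.12, 0.05, 1.0]],
            index=list("abcd"), columns=list("abcd"))
        retained, dropped = msa_eliminate(R, keep=("d",))
        assert "d" in retained and dropped == []


class TestVarimax:
    def test_communalities_conserved(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((10, 3))
        rot, _ = varimax(A)
        assert np.allclose((A**2).sum(axis=1), (rot**2).sum(axis=1), atol=1e-9)

    def test_two_component_brute_force_angle_search(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((8, 2))

        def crit_at(theta):
            c, s = np.cos(theta), np.sin(theta)
            return varimax_criterion(A @ np.array([[c, -s], [s, c]]))

        from scipy.optimize import minimize_scalar
        grid = np.linspace(0, np.pi / 2, 4001)
        vals = [crit_at(t) for t in grid]
        t0 = grid[int(np.argmax(vals))]
        ref = minimize_scalar(lambda t: -crit_at(t),
                              bounds=(t0 - 1e-3, t0 + 1e-3), method="bounded",
                              options={"xatol": 1e-12})
        best = -ref.fun
        rot, _ = varimax(A, kaiser=False)
        assert varimax_criterion(rot) == pytest.approx(best, abs=1e-6)

    def test_criterion_never_decreases(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((12, 4))
        before = varimax_criterion(A / np.linalg.norm(A, axis=1, keepdims=True))
        rot, _ = varimax(A, kaiser=True)
        h = np.sqrt((rot**2).sum(axis=1))
        after = varimax_criterion(rot / h[:, None])
        assert after >= before - 1e-12

    def test_agrees_with_statsmodels_raw_varimax(self):
        sm_rot = pytest.importorskip("statsmodels.multivariate.factor_rotation")
        rng = np.random.default_rng(5)
        A = rng.standard_normal((9, 3))
        ours, _ = varimax(A, kaiser=False)
        theirs = sm_rot.rotate_factors(A, "varimax")[0]
        assert varimax_criterion(ours) == pytest.approx(
            varimax_criterion(theirs), abs=1e-8)

    def test_sign_convention(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((10, 3))
        rot, _ = varimax(A)
        for k in range(3):
            assert rot[np.argmax(np.abs(rot[:, k])), k] > 0


class TestPcaVarimax:
    def test_planted_two_factor_structure_recovered(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal((200, 2))
        load = np.array([[1, 0], [1, 0], [1, 0], [0, 1], [0, 1], [0, 1]], float)
        X = f @ load.T + 0.25 * rng.standard_normal((200, 6))
        sol = pca_varimax(pd.DataFrame(X, columns=list("abcdef")))
        assert sol.n_components == 2
        a_groups = [set(v) for v in sol.assignments.values()]
        assert {"a", "b", "c"} in a_groups and {"d", "e", "f"} in a_groups

    def test_single_unit_loading_communality(self):
        L = pd.DataFrame([[1.0, 0.0], [0.0, 0.6]], index=["a", "b"])
        comm = communalities_from_loadings(L)
        assert comm["a"] == 1.0

    def test_eigenvalue_sum_is_trace(self, leaf_survey):
        sol = pca_varimax(leaf_survey.exposure)
        assert sol.eigenvalues.sum() == pytest.approx(len(leaf_survey.panel), abs=1e-9)

    def test_rotation_preserves_communality_in_solution(self, leaf_survey):
        sol = pca_varimax(leaf_survey.exposure)
        # communalities equal sums over unrotated retained loadings too
        R = np.corrcoef(
            ((leaf_survey.exposure - leaf_survey.exposure.mean())
             / leaf_survey.exposure.std(ddof=1)).to_numpy(), rowvar=False)
        eig, vec = np.linalg.eigh(R)
        order = np.argsort(eig)[::-1][:sol.n_components]
        unrot = vec[:, order] * np.sqrt(eig[order])
        assert np.allclose((unrot**2).sum(axis=1), sol.communalities.to_numpy(),
                           atol=1e-9)

    def test_reported_loading_table_bookkeeping(self):
        L = pd.DataFrame({"PC1": [0.965, 0.2], "PC2": [0.088, 0.9],
                          "PC3": [0.145, 0.1]}, index=["Mn", "X"])
        sol = PcaSolution.from_loadings(L, [46.5, 19.3, 9.6])
        assert round(sol.communalities["Mn"], 2) == 0.96
        assert sol.total_variance_pct == pytest.approx(75.4)
        assert "Mn" in sol.assignments["PC1"]

    def test_apportion_fills_adequacy(self, leaf_survey):
        sol = apportion(leaf_survey)
        assert 0 <= sol.kmo <= 1
        assert sol.bartlett_p < 0.001
        assert sol.n_components == len(sol.explained_variance_pct)
        for el, msa_at_drop in sol.dropped_variables:
            assert el not in sol.retained_variables
            assert msa_at_drop < 0.5
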