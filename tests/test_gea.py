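import numpy as np
import pandas as pd
import pytest

from grazescan.gea import (
    INTERGENIC,
    call_outliers,
    genomic_inflation,
    mahalanobis_d2,
    map_candidates,
    qvalues,
    rda_fit,
    robust_center_cov,
    scan_pvalues,
    screen_predictors,
    select_axes,
    snp_env_correlation,
)
from grazescan.io import EnvTable, GeneAnnotation

from conftest import make_genotypes


def _env(df):
    df.index.name = "site"
    return EnvTable(df)


class TestScreenPredictors:
    def test_highly_correlated_later_member_dropped(self):
        rng = np.random.default_rng(0)
        ph = rng.normal(7, 0.5, 30)
        ec = 2.0 * ph + rng.normal(0, 0.1, 30)  # |r| > 0.9
        env = _env(pd.DataFrame({"pH": ph, "EC": ec},
                                index=[f"s{i}" for i in range(30)]))
        out, report = screen_predictors(env)
        assert out.predictors == ["pH"]
        assert report.iloc[0]["predictor"] == "EC"

    def test_orthogonal_predictors_untouched(self):
        n = 16
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        env = _env(pd.DataFrame({"a": a, "b": b}, index=[f"s{i}" for i in range(n)]))
        out, report = screen_predictors(env)
        assert out.predictors == ["a", "b"] and report.empty

    def test_exact_collinearity_dropped_by_vif(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=30), rng.normal(size=30)
        # c is an exact sum: passes |r|<=0.7 screen but VIF infinite
        env = _env(pd.DataFrame({"a": a, "b": b, "c": 0.7 * a + 0.9 * b},
                                index=[f"s{i}" for i in range(30)]))
        out, report = screen_predictors(env, r_max=0.95)
        assert "VIF" in " ".join(report["reason"])
        assert len(out.predictors) == 2

    def test_constant_predictor_dropped(self):
        env = _env(pd.DataFrame({"a": [1.0, 2.0, 3.0], "k": [5.0, 5.0, 5.0]},
                                index=["s1", "s2", "s3"]))
        with pytest.warns(UserWarning, match="constant"):
            out, _ = screen_predictors(env)
        assert out.predictors == ["a"]


def _scan_fixture(n=50, L=200, p=4, seed=0):
    rng = np.random.default_rng(seed)
    sites = [f"s{i}" for i in range(10)]
    site_of = np.repeat(sites, n // 10)
    env = _env(pd.DataFrame(rng.normal(size=(10, p)),
                            columns=[f"e{j}" for j in range(p)], index=sites))
    d = rng.integers(0, 3, size=(n, L)).astype(np.int8)
    G = make_genotypes(d, sites=list(site_of))
    return G, env


class TestRdaFit:
    def test_constant_response_gives_zero_eigenvalues(self):
        G, env = _scan_fixture()
        G2 = make_genotypes(np.ones_like(G.dosages), sites=list(G.individuals["site"]))
        model = rda_fit(G2, env)
        assert np.allclose(model.eigenvalues, 0.0, atol=1e-16)

    def test_fitted_values_match_per_locus_ols(self):
        """Every column of Y' equals the per-locus OLS fitted values."""
        G, env = _scan_fixture(n=50, L=200, p=4)
        model = rda_fit(G, env, scale=False)
        X = model.X
        Y = G.dosages.astype(float)
        Y = Y - Y.mean(axis=0)
        max_diff = 0.0
        for j in range(Y.shape[1]):
            beta, *_ = np.linalg.lstsq(X, Y[:, j], rcond=None)
            max_diff = max(max_diff, np.abs(X @ beta - model.Yfit[:, j]).max())
        assert max_diff < 1e-8

    def test_fitted_values_match_per_locus_ols_scaled(self):
        G, env = _scan_fixture(n=40, L=80, p=3, seed=5)
        model = rda_fit(G, env, scale=True)
        X = model.X
        Y = G.dosages.astype(float)
        Y = (Y - Y.mean(axis=0)) / Y.std(axis=0)
        for j in range(Y.shape[1]):
            beta, *_ = np.linalg.lstsq(X, Y[:, j], rcond=None)
            assert np.abs(X @ beta - model.Yfit[:, j]).max() < 1e-8

    def test_single_predictor_loadings_proportional_to_slopes(self):
        rng = np.random.default_rng(2)
        sites = [f"s{i}" for i in range(8)]
        env = _env(pd.DataFrame({"e": rng.normal(size=8)}, index=sites))
        d = rng.integers(0, 3, size=(40, 30)).astype(np.int8)
        G = make_genotypes(d, sites=list(np.repeat(sites, 5)))
        model = rda_fit(G, env, scale=False)
        nonzero = np.sum(model.eigenvalues > 1e-12)
        assert nonzero == 1
        X = model.X[:, 0]
        Y = G.dosages.astype(float)
        Y = Y - Y.mean(axis=0)
        slopes = Y.T @ X / (X @ X)
        load = model.loadings[:, 0]
        ratio = load[np.abs(slopes) > 1e-8] / slopes[np.abs(slopes) > 1e-8]
        assert np.allclose(ratio, ratio[0], rtol=1e-6)


class TestSelectAxes:
    def test_single_dominant_axis(self):
        assert select_axes(np.array([10.0, 0.0, 0.0])) == 1

    def test_equal_eigenvalues_broken_stick(self):
        # shares (0.25,...) vs broken-stick (0.521, 0.271, 0.146, 0.062):
        # axes 3 and 4 exceed expectation, so retain through axis 4
        eig = np.array([1.0, 1.0, 1.0, 1.0])
        p = 4
        bs = [sum(1.0 / np.arange(i + 1, p + 1)) / p for i in range(p)]
        expected = max(i + 1 for i in range(p) if 0.25 > bs[i])
        assert select_axes(eig) == expected

    def test_fixed_mode(self):
        assert select_axes(np.array([3.0, 2.0, 1.0]), "fixed:2") == 2

    def test_proportion_mode(self):
        assert select_axes(np.array([6.0, 3.0, 1.0]), "proportion:0.9") == 2


class TestMahalanobis:
    def test_center_is_zero(self):
        mu = np.array([1.0, 2.0])
        assert mahalanobis_d2(mu[None, :], mu, np.eye(2))[0] == 0.0

    def test_identity_cov_is_squared_norm(self):
        z = np.array([[3.0, 4.0]])
        assert mahalanobis_d2(z, np.zeros(2), np.eye(2))[0] == pytest.approx(25.0)

    def test_matches_solve_on_random_instances(self):
        rng = np.random.default_rng(3)
        K = 3
        A = rng.normal(size=(K, K))
        cov = A @ A.T + 0.5 * np.eye(K)
        mu = rng.normal(size=K)
        Z = rng.normal(size=(1000, K))
        got = mahalanobis_d2(Z, mu, cov)
        expect = np.array(
            [ (z - mu) @ np.linalg.solve(cov, z - mu) for z in Z ]
        )
        np.testing.assert_allclose(got, expect, atol=1e-8)


class TestRobustCenterCov:
    def test_clean_cloud_agrees_with_classical(self):
        rng = np.random.default_rng(4)
        Z = rng.multivariate_normal([0, 0], [[2.0, 0.5], [0.5, 1.0]], size=5000)
        mu_r, cov_r = robust_center_cov(Z, method="mcd", seed=0)
        mu_c, cov_c = robust_center_cov(Z, method="classical")
        rel = np.linalg.norm(cov_r - cov_c) / np.linalg.norm(cov_c)
        assert rel < 0.1
        assert np.abs(mu_r - mu_c).max() < 0.1

    def test_contamination_shrinks_robust_determinant(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(900, 2))
        Z = np.vstack([Z, rng.normal(0, 8, size=(100, 2))])
        _, cov_r = robust_center_cov(Z, method="mcd", seed=0)
        _, cov_c = robust_center_cov(Z, method="classical")
        assert np.linalg.det(cov_r) <= np.linalg.det(cov_c)

    def test_univariate_reduction(self):
        rng = np.random.default_rng(6)
        z = rng.normal(2.0, 3.0, size=(500, 1))
        mu, cov = robust_center_cov(z, method="classical")
        d2 = mahalanobis_d2(z, mu, cov)
        np.testing.assert_allclose(
            d2, ((z[:, 0] - mu[0]) ** 2) / cov[0, 0], atol=1e-10
        )


class TestInflationAndPvalues:
    def test_chi2_null_lambda_near_one(self):
        rng = np.random.default_rng(7)
        d2 = rng.chisquare(3, size=10_000)
        assert genomic_inflation(d2, 3) == pytest.approx(1.0, abs=0.05)

    def test_closed_form_median_k2(self):
        lam = genomic_inflation(np.array([1.0, 2.0, 3.0]), 2)
        assert lam == pytest.approx(2.0 / (2.0 * np.log(2.0)), rel=1e-12)

    def test_scale_equivariance(self):
        d2 = np.array([0.5, 1.5, 4.0, 9.0])
        assert genomic_inflation(3.0 * d2, 2) == pytest.approx(
            3.0 * genomic_inflation(d2, 2)
        )

    def test_zero_statistic_gives_p_one(self):
        assert scan_pvalues(np.array([0.0]), 1.0, 2)[0] == 1.0

    def test_bh_hand_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(qvalues(p, method="bh"), [0.04] * 4)

    def test_outlier_threshold_strict(self):
        q = np.array([0.009, 0.01, 0.5])
        np.testing.assert_array_equal(call_outliers(q, 0.01), [True, False, False])


class TestSnpEnvCorrelation:
    def test_perfect_monotone(self):
        G = make_genotypes(np.array([[0], [1], [2]], dtype=np.int8),
                           sites=["s1", "s2", "s3"])
        env = _env(pd.DataFrame({"e": [1.0, 2.0, 3.0]}, index=["s1", "s2", "s3"]))
        r = snp_env_correlation(G, env)
        assert r.iloc[0, 0] == pytest.approx(1.0)

    def test_constant_predictor_flagged_nan(self):
        G = make_genotypes(np.array([[0], [1], [2]], dtype=np.int8),
                           sites=["s1", "s2", "s3"])
        env = _env(pd.DataFrame({"e": [2.0, 2.0, 2.0]}, index=["s1", "s2", "s3"]))
        assert np.isnan(snp_env_correlation(G, env).iloc[0, 0])

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        sites = [f"s{i}" for i in range(12)]
        env = _env(pd.DataFrame({"e": rng.normal(size=12)}, index=sites))
        d = rng.integers(0, 3, size=(60, 5)).astype(np.int8)
        G = make_genotypes(d, sites=list(np.repeat(sites, 5)))
        got = snp_env_correlation(G, env)
        x = np.repeat(env.data["e"].to_numpy(), 5)
        for j in range(5):
            y = d[:, j].astype(float)
            expect = ((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std())
            assert got.iloc[j, 0] == pytest.approx(expect, abs=1e-12)


class TestMapCandidates:
    def _ann(self):
        return GeneAnnotation(pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200],
             "gene_id": ["g1"], "description": ["kinase"]}
        ))

    @pytest.mark.parametrize("pos,expected", [(150, "g1"), (200, "g1"),
                                              (100, "g1"), (250, INTERGENIC)])
    def test_inclusive_interval_assignment(self, pos, expected):
        loci = pd.DataFrame({"chrom": ["chr1"], "pos": [pos]})
        hits = map_candidates(loci, self._ann())
        assert hits.iloc[0]["gene_id"] == expected

    def test_unknown_chromosome_warns_intergenic(self):
        loci = pd.DataFrame({"chrom": ["chr9"], "pos": [150]})
        with pytest.warns(UserWarning, match="chr9"):
            hits = map_candidates(loci, self._ann())
        assert hits.iloc[0]["gene_id"] == INTERGENIC
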