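import numpy as np
import pandas as pd
import pytest

from grazescan.admixture import (
    admixture_loglik,
    align_runs,
    classify_by_parentage,
    evanno_delta_k,
    fit_admixture,
)
from grazescan.io import MISSING

from conftest import make_genotypes


class TestLoglik:
    def test_k1_equals_direct_binomial_sum(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(20, 30)).astype(np.int8)
        G = make_genotypes(d)
        p = np.clip(G.allele_freqs(), 1e-9, 1 - 1e-9)
        direct = float(
            np.sum(d * np.log(p)[None, :] + (2 - d) * np.log(1 - p)[None, :])
        )
        got = admixture_loglik(G, np.ones((20, 1)), p[None, :])
        assert got == pytest.approx(direct, rel=1e-12)

    def test_all_missing_gives_zero(self):
        d = np.full((3, 4), MISSING, dtype=np.int8)
        G = make_genotypes(d)
        assert admixture_loglik(G, np.ones((3, 1)), np.full((1, 4), 0.5)) == 0.0

    def test_degenerate_mixture_row(self):
        d = np.array([[2, 0]], dtype=np.int8)
        G = make_genotypes(d)
        P = np.array([[0.9, 0.1], [0.5, 0.5]])
        got = admixture_loglik(G, np.array([[1.0, 0.0]]), P)
        expected = 2 * np.log(0.9) + 2 * np.log(0.9)
        assert got == pytest.approx(expected, rel=1e-12)


class TestFitAdmixture:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(15, 25)).astype(np.int8)
        G = make_genotypes(d)
        fit = fit_admixture(G, 1)
        assert np.all(fit.Q == 1.0)
        np.testing.assert_allclose(fit.P[0], G.allele_freqs(), atol=1e-9)

    def test_separable_populations_recovered(self):
        # two groups fixed for opposite alleles at every locus
        d = np.vstack([np.zeros((10, 40)), np.full((10, 40), 2)]).astype(np.int8)
        G = make_genotypes(d)
        fit = fit_admixture(G, 2, seed=0, n_init=3, max_iter=500)
        ident = np.zeros((20, 2))
        ident[:10, 0] = 1
        ident[10:, 1] = 1
        err = min(
            np.abs(fit.Q - ident).max(), np.abs(fit.Q[:, ::-1] - ident).max()
        )
        assert err < 0.01

    def test_loglik_monotone_every_iteration(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(30, 50)).astype(np.int8)
        d[rng.random((30, 50)) < 0.1] = MISSING
        fit = fit_admixture(make_genotypes(d), 3, seed=1, n_init=2, max_iter=200)
        diffs = np.diff(fit.loglik_path)
        assert np.all(diffs >= -1e-8 * np.abs(fit.loglik_path[:-1]))

    def test_beats_grid_search_on_tiny_instance(self):
        """EM reaches at least the exhaustive grid-search optimum on a
        3 individuals x 2 loci problem (P on a 0.05 grid, Q rows at 0.01)."""
        d = np.array([[0, 2], [2, 0], [1, 1]], dtype=np.int8)
        G = make_genotypes(d)
        pg = np.arange(0.05, 1.0, 0.05)       # pool ALT freqs, both loci
        qg = np.arange(0.0, 1.001, 0.01)      # per-individual ancestry
        # enumerate P = [[p1a, p2a], [p1b, p2b]]; per individual the optimal
        # q is independent given P, so max over q per individual and sum
        p1a, p1b, p2a, p2b = [g.ravel() for g in np.meshgrid(pg, pg, pg, pg,
                                                             indexing="ij")]
        best = -np.inf
        chunk = 20_000
        for s in range(0, p1a.size, chunk):
            sl = slice(s, s + chunk)
            f1 = np.clip(qg[None, :] * p1a[sl, None]
                         + (1 - qg)[None, :] * p1b[sl, None], 1e-9, 1 - 1e-9)
            f2 = np.clip(qg[None, :] * p2a[sl, None]
                         + (1 - qg)[None, :] * p2b[sl, None], 1e-9, 1 - 1e-9)
            tot = np.zeros(f1.shape[0])
            for i in range(3):
                ll_i = (d[i, 0] * np.log(f1) + (2 - d[i, 0]) * np.log1p(-f1)
                        + d[i, 1] * np.log(f2) + (2 - d[i, 1]) * np.log1p(-f2))
                tot += ll_i.max(axis=1)
            best = max(best, float(tot.max()))
        fit = fit_admixture(G, 2, seed=3, n_init=5, max_iter=2000, tol=1e-9)
        assert fit.loglik >= best - 1e-3

    def test_k_larger_than_n_rejected(self):
        G = make_genotypes(np.zeros((2, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            fit_admixture(G, 3)


class TestEvanno:
    def test_linear_means_give_zero_delta(self):
        ll = np.array([[1.0, 2.0, 3.0, 4.0], [1.1, 2.1, 3.1, 4.1]])
        table, k = evanno_delta_k(ll, ks=[1, 2, 3, 4])
        inner = table.table["delta_k"].iloc[1:-1]
        assert np.allclose(inner, 0.0, atol=1e-9)

    def test_hand_arithmetic(self):
        # runs chosen so mean L = (-1000, -800, -795, -794)
        ll = np.array(
            [
                [-1001.0, -801.0, -796.0, -795.0],
                [-999.0, -799.0, -794.0, -793.0],
            ]
        )
        table, k = evanno_delta_k(ll, ks=[1, 2, 3, 4])
        sd2 = np.std([-801, -799], ddof=1)
        expect = abs(-795 - 2 * (-800) + (-1000)) / sd2
        assert table.table.loc[1, "delta_k"] == pytest.approx(expect)
        assert k == 2

    def test_zero_sd_excluded_with_warning(self):
        ll = np.array([[1.0, 2.0, 4.0, 8.0], [1.0, 2.0, 4.1, 8.0]])
        with pytest.warns(UserWarning, match="SD"):
            table, k = evanno_delta_k(ll, ks=[1, 2, 3, 4])
        assert np.isnan(table.table.loc[1, "delta_k"])
        assert k == 3

    def test_requires_enough_runs_and_ks(self):
        with pytest.raises(ValueError):
            evanno_delta_k(np.ones((1, 4)))
        with pytest.raises(ValueError):
            evanno_delta_k(np.ones((3, 2)))


class TestAlignRuns:
    def test_single_run_identity(self):
        q = np.array([[0.7, 0.3], [0.2, 0.8]])
        np.testing.assert_allclose(align_runs([q]), q)

    def test_swapped_columns_realigned(self):
        q = np.array([[0.7, 0.3], [0.2, 0.8], [0.5, 0.5]])
        consensus = align_runs([q, q[:, ::-1]])
        np.testing.assert_allclose(consensus, q, atol=1e-12)

    def test_consensus_beats_single_noisy_runs(self):
        rng = np.random.default_rng(4)
        truth = rng.dirichlet((1, 1), size=50)
        runs = []
        for _ in range(5):
            noisy = np.clip(truth + rng.normal(0, 0.08, truth.shape), 1e-6, None)
            noisy /= noisy.sum(axis=1, keepdims=True)
            perm = rng.permutation(2)
            runs.append(noisy[:, perm])
        consensus = align_runs(runs)
        # consensus is aligned to the (possibly swapped) first run, so compare
        # to truth up to one global column swap
        cons_err = min(
            np.linalg.norm(consensus - truth),
            np.linalg.norm(consensus[:, ::-1] - truth),
        )
        # align each single run to truth for a fair comparison
        single_errs = []
        for r in runs:
            single_errs.append(
                min(np.linalg.norm(r - truth), np.linalg.norm(r[:, ::-1] - truth))
            )
        assert cons_err < min(single_errs)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            align_runs([np.ones((3, 2)) / 2, np.ones((4, 2)) / 2])


class TestParentage:
    @pytest.mark.parametrize(
        "q,expected",
        [(0.6, "sativa"), (0.5, "falcata"), (0.84, "sativa"), (0.34, "falcata")],
    )
    def test_majority_rule_boundary(self, q, expected):
        assert classify_by_parentage(np.array([q]))[0] == expected

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            classify_by_parentage(np.array([0.5]), threshold=1.0)
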