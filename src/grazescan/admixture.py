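"""Maximum-likelihood admixture model, model-order selection and run
consensus.

The model is the classical admixture likelihood over unlinked biallelic
loci: individual i carries 2 allele draws per locus l, each from ancestral
pool k with probability Q_ik, and pool k has ALT frequency P_kl, so the
per-copy ALT probability is f_il = sum_k Q_ik P_kl and

    log L(Q, P) = sum_il [ g_il log f_il + (2 - g_il) log(1 - f_il) ],

omitting the genotype-independent binomial coefficient. Missing genotype
cells are skipped (observed-data likelihood). Estimation is by EM with
closed-form updates and multiple seeded restarts; the log-likelihood is
non-decreasing across iterations. The EM point estimates target the same
Q/P estimands as Bayesian MCMC samplers of this model, and the maximized
log-likelihood plays the role of LnP(K) in the Evanno second-difference
statistic used to choose the number of ancestral pools.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from grazescan.io import GenotypeMatrix

_EPS = 1e-9


@dataclass
class AdmixtureFit:
    Q: np.ndarray       # individuals x K, rows on the simplex
    P: np.ndarray       # K x loci, in (0, 1)
    loglik: float
    K: int
    n_iter: int
    converged: bool
    loglik_path: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")


def _split_counts(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """ALT-copy and REF-copy count matrices with missing cells zeroed."""
    g = G.dosages.astype(float)
    miss = G.is_missing()
    g1 = np.where(miss, 0.0, g)          # ALT copies
    g2 = np.where(miss, 0.0, 2.0 - g)    # REF copies
    return g1, g2


def admixture_loglik(G: GenotypeMatrix, Q: np.ndarray, P: np.ndarray) -> float:
    """Observed-data log-likelihood at (Q, P); missing cells contribute 0."""
    if Q.shape[1] != P.shape[0] or Q.shape[0] != G.n_individuals or P.shape[1] != G.n_loci:
        raise ValueError("shape mismatch between G, Q and P")
    if np.any(P <= 0) or np.any(P >= 1):
        raise ValueError("P must be strictly inside (0, 1)")
    g1, g2 = _split_counts(G)
    F = Q @ P
    if np.any(F <= 0) or np.any(F >= 1):
        warnings.warn("mixture frequencies clipped to (eps, 1-eps)")
        F = np.clip(F, _EPS, 1.0 - _EPS)
    return float(np.sum(g1 * np.log(F) + g2 * np.log1p(-F)))


def fit_admixture(
    G: GenotypeMatrix,
    K: int,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> AdmixtureFit:
    """EM fit of the admixture model; best of ``n_init`` seeded restarts.

    Convergence is declared when the per-iteration log-likelihood gain drops
    below ``tol``. K = 1 is the closed form (P = observed allele frequencies).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > G.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    g1, g2 = _split_counts(G)
    n, L = g1.shape
    n_calls = g1 + g2  # 2 where observed, 0 where missing
    per_ind_calls = n_calls.sum(axis=1)

    if K == 1:
        tot = n_calls.sum(axis=0)
        p = np.where(tot > 0, g1.sum(axis=0) / np.maximum(tot, 1.0), 0.5)
        P = np.clip(p, _EPS, 1.0 - _EPS)[None, :]
        Q = np.ones((n, 1))
        ll = admixture_loglik(G, Q, P)
        return AdmixtureFit(Q, P, ll, 1, 0, True, np.array([ll]))

    rng = np.random.default_rng(seed)
    best: AdmixtureFit | None = None
    for _ in range(max(1, n_init)):
        Q = rng.dirichlet(np.ones(K), size=n)
        P = np.clip(rng.uniform(0.05, 0.95, size=(K, L)), _EPS, 1 - _EPS)
        Q, P, path, it, converged = _squarem(
            Q, P, g1, g2, per_ind_calls, tol=tol, max_iter=max_iter
        )
        fit = AdmixtureFit(Q, P, path[-1], K, it, converged, np.asarray(path))
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def _em_step(Q, P, g1, g2, per_ind_calls):
    """One EM update of (Q, P) from expected pool-of-origin allele counts."""
    F = np.clip(Q @ P, _EPS, 1.0 - _EPS)
    R1 = g1 / F            # ALT copies / mixture freq
    R2 = g2 / (1.0 - F)
    A = Q * (R1 @ P.T)               # sum_l a_ilk
    B = Q * (R2 @ (1.0 - P).T)       # sum_l b_ilk
    num = P * (Q.T @ R1)             # sum_i a_ilk, per (k, l)
    den = num + (1.0 - P) * (Q.T @ R2)
    Qn = (A + B) / np.maximum(per_ind_calls, 1.0)[:, None]
    Qn = np.clip(Qn, _EPS, None)
    Qn /= Qn.sum(axis=1, keepdims=True)
    Pn = np.where(den > 0, num / np.maximum(den, _EPS), P)
    return Qn, np.clip(Pn, _EPS, 1.0 - _EPS)


def _ll(Q, P, g1, g2) -> float:
    F = np.clip(Q @ P, _EPS, 1.0 - _EPS)
    return float(np.sum(g1 * np.log(F) + g2 * np.log1p(-F)))


def _project(Q, P):
    Q = np.clip(Q, _EPS, None)
    Q /= Q.sum(axis=1, keepdims=True)
    return Q, np.clip(P, _EPS, 1.0 - _EPS)


def _squarem(Q, P, g1, g2, per_ind_calls, tol, max_iter):
    """SQUAREM-accelerated EM with a monotonicity safeguard.

    Each outer iteration takes two EM steps, extrapolates along the implied
    direction (Varadhan-Roland S3 step length), and falls back to the plain
    double EM step whenever the extrapolated point does not improve the
    log-likelihood, so the recorded path is non-decreasing.
    """
    path = []
    prev = _ll(Q, P, g1, g2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Q1, P1 = _em_step(Q, P, g1, g2, per_ind_calls)
        Q2, P2 = _em_step(Q1, P1, g1, g2, per_ind_calls)
        rQ, rP = Q1 - Q, P1 - P
        vQ, vP = (Q2 - Q1) - rQ, (P2 - P1) - rP
        vnorm = np.sqrt(np.sum(vQ**2) + np.sum(vP**2))
        ll2 = _ll(Q2, P2, g1, g2)
        if vnorm > 0:
            alpha = -np.sqrt(np.sum(rQ**2) + np.sum(rP**2)) / vnorm
            alpha = min(alpha, -1.0)
            Qs, Ps = _project(
                Q - 2 * alpha * rQ + alpha**2 * vQ,
                P - 2 * alpha * rP + alpha**2 * vP,
            )
            # stabilizing EM step keeps the iterate in the fixed-point basin
            Qs, Ps = _em_step(Qs, Ps, g1, g2, per_ind_calls)
            lls = _ll(Qs, Ps, g1, g2)
            if lls >= ll2:
                Q, P, ll = Qs, Ps, lls
            else:
                Q, P, ll = Q2, P2, ll2
        else:
            Q, P, ll = Q2, P2, ll2
        path.append(ll)
        if np.isfinite(prev) and ll - prev < tol:
            converged = True
            break
        prev = ll
    return Q, P, path, it, converged


@dataclass
class EvannoTable:
    table: pd.DataFrame  # columns: K, mean_loglik, sd_loglik, delta_k

    def __str__(self) -> str:  # pragma: no cover
        return self.table.to_string(index=False)


def evanno_delta_k(logliks: pd.DataFrame | np.ndarray, ks: list[int] | None = None):
    """Evanno second-difference statistic over a grid of K.

    Parameters
    ----------
    logliks : runs x K array (or DataFrame with K values as columns)
    ks : the K value of each column when ``logliks`` is a bare array;
        defaults to 1..Kmax. Must be consecutive.

    Returns
    -------
    (EvannoTable, K*) where
    ``delta_k(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / SD(L(K))``
    is defined for interior K only, and K* maximizes it. Interior K with
    zero run-to-run SD are excluded with a warning.
    """
    if isinstance(logliks, pd.DataFrame):
        ks = [int(c) for c in logliks.columns]
        arr = logliks.to_numpy(float)
    else:
        arr = np.asarray(logliks, float)
        ks = list(ks) if ks is not None else list(range(1, arr.shape[1] + 1))
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 runs per K")
    if arr.shape[1] < 3:
        raise ValueError("need >= 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    delta = np.full(len(ks), np.nan)
    for j in range(1, len(ks) - 1):
        if sd[j] == 0:
            warnings.warn(f"SD of loglik is 0 at K={ks[j]}; delta K undefined there")
            continue
        delta[j] = abs(mean[j + 1] - 2.0 * mean[j] + mean[j - 1]) / sd[j]
    table = pd.DataFrame(
        {"K": ks, "mean_loglik": mean, "sd_loglik": sd, "delta_k": delta}
    )
    if np.all(np.isnan(delta)):
        raise ValueError("delta K undefined for every interior K")
    k_star = int(table.loc[np.nanargmax(delta), "K"])
    return EvannoTable(table), k_star


def align_runs(Q_runs: list[np.ndarray]) -> np.ndarray:
    """Permute ancestry labels of each run to match the first, then average.

    Label matching is exhaustive over K! permutations for K <= 6 and greedy
    otherwise; the consensus is the element-wise mean re-normalized to the
    simplex. This is the role the CLUMPP consensus plays for MCMC replicates.
    """
    shapes = {q.shape for q in Q_runs}
    if len(shapes) != 1:
        raise ValueError("all runs must have the same shape")
    ref = Q_runs[0]
    K = ref.shape[1]
    aligned = [ref]
    for Q in Q_runs[1:]:
        if K <= 6:
            best_perm, best_score = None, -np.inf
            for perm in itertools.permutations(range(K)):
                score = float(np.sum(ref * Q[:, perm]))
                if score > best_score:
                    best_score, best_perm = score, perm
            aligned.append(Q[:, list(best_perm)])
        else:
            # greedy column matching by correlation with the reference
            remaining = list(range(K))
            perm = []
            for k in range(K):
                scores = [float(ref[:, k] @ Q[:, j]) for j in remaining]
                pick = remaining.pop(int(np.argmax(scores)))
                perm.append(pick)
            aligned.append(Q[:, perm])
    consensus = np.mean(aligned, axis=0)
    consensus /= consensus.sum(axis=1, keepdims=True)
    return consensus


def classify_by_parentage(
    q: np.ndarray,
    ancestry_label: str = "sativa",
    other_label: str = "falcata",
    threshold: float = 0.5,
) -> np.ndarray:
    """Group individuals by majority parentage.

    ``q`` holds the focal ancestry's membership proportions. Strictly greater
    than ``threshold`` assigns the focal label; ties at exactly the threshold
    go to the alternative class (the rule is "greater than", and the boundary
    is assigned to the non-focal side).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    q = np.asarray(q, float)
    return np.where(q > threshold, ancestry_label, other_label)
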