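"""Discriminant analysis of principal components (DAPC).

Dosages are centered and reduced by PCA; K-means over a grid of candidate
cluster numbers is scored with BIC (lowest wins); the retained-PC count for
the discriminant step is chosen by held-out assignment accuracy on a
stratified split grid; linear discriminant axes are then computed on the
retained PCs against the chosen clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedShuffleSplit

from grazescan.io import GenotypeMatrix


@dataclass
class DapcResult:
    n_pcs: int
    n_clusters: int
    assignments: np.ndarray            # individuals -> cluster id
    bic: pd.Series                     # candidate K -> BIC
    scores: np.ndarray                 # individuals x (K-1) discriminant scores
    pc_accuracy: pd.Series             # candidate n_pcs -> held-out accuracy


def _kmeans_bic(X: np.ndarray, k: int, seed: int) -> tuple[float, np.ndarray]:
    """BIC = n ln(WSS/n) + k ln(n) for a K-means solution."""
    n = X.shape[0]
    if k == 1:
        wss = float(((X - X.mean(axis=0)) ** 2).sum())
        return n * np.log(wss / n) + np.log(n), np.zeros(n, dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    wss = float(km.inertia_)
    return n * np.log(max(wss, 1e-12) / n) + k * np.log(n), km.labels_


def dapc(
    G: GenotypeMatrix | np.ndarray,
    max_k: int = 10,
    seed: int = 0,
    n_pcs_grid: tuple[int, ...] | None = None,
    n_splits: int = 10,
    test_size: float = 0.25,
) -> DapcResult:
    """Cluster discovery and discriminant axes on centered dosages.

    Raises if ``max_k`` is not below the number of individuals.
    """
    X = G.dosages.astype(float) if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    n = X.shape[0]
    if not 1 <= max_k < n:
        raise ValueError("need n individuals > max_k >= 1")
    Xc = X - X.mean(axis=0)
    n_comp = int(min(n - 1, Xc.shape[1], 60))
    pca = PCA(n_components=n_comp, random_state=seed)
    pcs_all = pca.fit_transform(Xc)

    # cluster discovery uses the full PC space (total-variance preserving)
    bic = {}
    labels_by_k = {}
    for k in range(1, max_k + 1):
        bic[k], labels_by_k[k] = _kmeans_bic(pcs_all, k, seed)
    bic = pd.Series(bic).sort_index()
    k_best = int(bic.idxmin())
    labels = labels_by_k[k_best]

    if k_best == 1:
        return DapcResult(
            n_pcs=min(2, n_comp),
            n_clusters=1,
            assignments=labels,
            bic=bic,
            scores=np.zeros((n, 0)),
            pc_accuracy=pd.Series(dtype=float),
        )

    # retained-PC count: held-out LDA assignment accuracy over a grid
    if n_pcs_grid is None:
        hi = max(2, n_comp)
        n_pcs_grid = tuple(sorted({2, 5, 10, 20, 40, hi} & set(range(2, hi + 1))))
    counts = np.bincount(labels)
    can_stratify = counts.min() >= 2 and n * test_size >= k_best
    acc = {}
    for npc in n_pcs_grid:
        npc = min(npc, n_comp)
        if not can_stratify:
            acc[npc] = np.nan
            continue
        splitter = StratifiedShuffleSplit(
            n_splits=n_splits, test_size=test_size, random_state=seed
        )
        scores = []
        for tr, te in splitter.split(pcs_all[:, :npc], labels):
            lda = LinearDiscriminantAnalysis()
            lda.fit(pcs_all[tr, :npc], labels[tr])
            scores.append(float(lda.score(pcs_all[te, :npc], labels[te])))
        acc[npc] = float(np.mean(scores))
    acc = pd.Series(acc).sort_index()
    if acc.notna().any():
        n_pcs = int(acc.idxmax())
    else:
        n_pcs = min(10, n_comp)

    lda = LinearDiscriminantAnalysis(n_components=k_best - 1)
    scores = lda.fit_transform(pcs_all[:, :n_pcs], labels)
    return DapcResult(
        n_pcs=n_pcs,
        n_clusters=k_best,
        assignments=labels,
        bic=bic,
        scores=scores,
        pc_accuracy=acc,
    )
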