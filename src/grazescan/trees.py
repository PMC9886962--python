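"""Nei (1972) genetic distance, UPGMA trees and locus-bootstrap support."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from grazescan.io import GenotypeMatrix

#: cap for -ln(I) when the normalized identity I underflows to 0
DEFAULT_MAX_DISTANCE = 10.0


def population_freqs(G: GenotypeMatrix, by: str = "population") -> pd.DataFrame:
    """Per-population ALT allele frequency matrix (populations x loci)."""
    d = G.dosages.astype(float)
    d[G.is_missing()] = np.nan
    groups = G.individuals[by]
    out = {}
    for g in pd.unique(groups):
        rows = d[(groups == g).to_numpy()]
        with np.errstate(invalid="ignore"):
            out[g] = np.nanmean(rows, axis=0) / 2.0
    return pd.DataFrame.from_dict(out, orient="index")


@dataclass
class DistanceMatrix:
    labels: list[str]
    D: np.ndarray
    capped: np.ndarray | None = None  # True where I <= 0 forced the cap

    def __post_init__(self) -> None:
        D = np.asarray(self.D, float)
        if D.shape[0] != D.shape[1] or D.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(D, D.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(D) != 0):
            raise ValueError("distance matrix diagonal must be 0")
        self.D = D

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


def nei_distance(
    pop_freqs: pd.DataFrame | np.ndarray,
    labels: list[str] | None = None,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> DistanceMatrix:
    """Nei's (1972) standard genetic distance between allele-frequency rows.

    For biallelic loci with ALT frequencies x, y per population:
    Jx = mean(x^2 + (1-x)^2), Jy likewise, Jxy = mean(x y + (1-x)(1-y)),
    I = Jxy / sqrt(Jx Jy) and D = -ln I. I <= 0 (disjoint alleles at every
    locus) gives infinite distance, capped at ``max_distance`` with a flag;
    numerical overshoot above 1 is clamped to 1 (D = 0).
    """
    if isinstance(pop_freqs, pd.DataFrame):
        labels = [str(x) for x in pop_freqs.index]
        F = pop_freqs.to_numpy(float)
    else:
        F = np.asarray(pop_freqs, float)
        labels = labels if labels is not None else [f"pop{i}" for i in range(len(F))]
    if F.ndim != 2 or F.shape[1] < 1:
        raise ValueError("need a populations x loci frequency matrix with >= 1 locus")
    if np.nanmin(F) < 0 or np.nanmax(F) > 1:
        raise ValueError("allele frequencies must be in [0, 1]")
    npop = F.shape[0]
    J = np.array([np.nanmean(F[i] ** 2 + (1 - F[i]) ** 2) for i in range(npop)])
    D = np.zeros((npop, npop))
    capped = np.zeros((npop, npop), bool)
    for i in range(npop):
        for j in range(i + 1, npop):
            jxy = np.nanmean(F[i] * F[j] + (1 - F[i]) * (1 - F[j]))
            identity = jxy / np.sqrt(J[i] * J[j])
            if identity <= 0:
                D[i, j] = D[j, i] = max_distance
                capped[i, j] = capped[j, i] = True
            else:
                D[i, j] = D[j, i] = -np.log(min(identity, 1.0))
    return DistanceMatrix(labels, D, capped)


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0           # branch length to parent
    height: float = 0.0           # ultrametric height above the leaves
    support: float | None = None  # bootstrap %, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(lf.name for lf in self.leaves())


@dataclass
class Tree:
    root: TreeNode

    def leaf_depths(self) -> dict[str, float]:
        depths = {}

        def walk(node: TreeNode, depth: float) -> None:
            if node.is_leaf():
                depths[node.name] = depth
            for c in node.children:
                walk(c, depth + c.length)

        walk(self.root, 0.0)
        return depths

    def internal_bipartitions(self) -> list[frozenset[str]]:
        """Leaf sets under internal, non-root nodes (clades of a rooted tree)."""
        out = []

        def walk(node: TreeNode) -> None:
            for c in node.children:
                if not c.is_leaf():
                    out.append(c.leaf_names())
                walk(c)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf():
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def newick(self, support_as_label: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if support_as_label and node.support is not None:
                label = f"{node.support:.0f}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = ""
        if support_as_label and self.root.support is not None:
            label = f"{self.root.support:.0f}"
        return f"({inner}){label};"


def upgma(dm: DistanceMatrix) -> Tree:
    """Classical UPGMA: merge the closest pair; the merged cluster's distance
    to any other cluster is the size-weighted average of member distances
    (equivalently, the arithmetic mean over all original leaf pairs). Node
    height is half the merge distance, so the tree is ultrametric. Ties are
    broken by the lowest (row, col) index pair in current cluster order.
    """
    D = np.asarray(dm.D, float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    clusters = [TreeNode(name=lab) for lab in dm.labels]
    sizes = [1] * n
    D = D.copy()
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                d = D[active[ai], active[aj]]
                if best is None or d < best[0]:
                    best = (d, ai, aj)
        d, ai, aj = best
        i, j = active[ai], active[aj]
        h = d / 2.0
        left, right = clusters[i], clusters[j]
        for child in (left, right):
            child.length = h - child.height
        node = TreeNode(height=h, children=[left, right])
        # weighted average distance to every other active cluster
        for ak in range(len(active)):
            k = active[ak]
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = (
                sizes[i] * D[i, k] + sizes[j] * D[j, k]
            ) / (sizes[i] + sizes[j])
        sizes[i] += sizes[j]
        clusters[i] = node
        active.pop(aj)
    return Tree(clusters[active[0]])


def bootstrap_support(
    G: GenotypeMatrix,
    by: str = "population",
    n_boot: int = 1000,
    seed: int = 0,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> Tree:
    """UPGMA tree on Nei distances with locus-bootstrap clade support.

    Loci are resampled with replacement ``n_boot`` times; population
    frequencies, distances and the tree are recomputed per replicate, and
    each internal node of the original tree gets the percentage of replicates
    whose tree contains the same leaf set as a clade. ``n_boot=0`` returns
    the original tree without supports.
    """
    freqs = population_freqs(G, by=by)
    if len(freqs) < 2:
        raise ValueError("need >= 2 populations")
    if freqs.shape[1] < 2:
        raise ValueError("need >= 2 loci")
    tree = upgma(nei_distance(freqs, max_distance=max_distance))
    if n_boot == 0:
        return tree
    rng = np.random.default_rng(seed)
    L = freqs.shape[1]
    counts: dict[frozenset, int] = {}
    for _ in range(n_boot):
        idx = rng.integers(0, L, size=L)
        rep = upgma(nei_distance(freqs.iloc[:, idx], max_distance=max_distance))
        seen = set(rep.internal_bipartitions())
        seen.add(rep.root.leaf_names())
        for clade in seen:
            counts[clade] = counts.get(clade, 0) + 1
    for node in tree.internal_nodes():
        clade = node.leaf_names()
        node.support = 100.0 * counts.get(clade, 0) / n_boot
    return tree
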