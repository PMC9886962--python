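"""RDA-based genotype-environment association genome scan.

The scan regresses the centered individual x locus dosage matrix Y on
standardized site-level environmental predictors X broadcast to individuals
(one soil test per site), takes the PCA of the fitted values Y' = X B
(redundancy analysis), and treats each locus's loadings on the first K
constrained axes as a point in K-space. A robust center and covariance of
that cloud (minimum covariance determinant) give a squared Mahalanobis
distance per locus; after rescaling by the genomic inflation factor the
distances are referred to a chi-squared distribution with K degrees of
freedom, p-values are converted to q-values (Storey or Benjamini-Hochberg),
and loci with q below a threshold (default 0.01) are called outliers.
Outliers are then assigned to annotated genes by position and to the
environmental predictor they correlate with most strongly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet

from grazescan.io import EnvTable, GeneAnnotation, GenotypeMatrix


# ---------------------------------------------------------------------------
# predictor screening
# ---------------------------------------------------------------------------

def screen_predictors(
    env: EnvTable, r_max: float = 0.7, vif_max: float = 5.0
) -> tuple[EnvTable, pd.DataFrame]:
    """Drop collinear predictors before the regression-based scan.

    Greedy pairwise pass first: while any pair has |Pearson r| > ``r_max``,
    the later-listed member is dropped. Then the variance inflation factor
    VIF = 1/(1-R^2) of each survivor regressed on the others is computed and
    predictors above ``vif_max`` are dropped iteratively, largest first.
    Constant predictors are dropped up front (undefined correlation).
    Returns the reduced table and a report of drops with reasons.
    """
    df = env.data.copy()
    drops: list[tuple[str, str]] = []
    for col in list(df.columns):
        if df[col].std(ddof=0) == 0:
            warnings.warn(f"constant predictor {col!r} dropped")
            drops.append((col, "constant"))
            df = df.drop(columns=col)

    changed = True
    while changed and df.shape[1] >= 2:
        changed = False
        corr = df.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        cols = list(df.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if corr[i, j] > r_max:
                    drops.append((cols[j], f"|r|={corr[i, j]:.3f} with {cols[i]}"))
                    df = df.drop(columns=cols[j])
                    changed = True
                    break
            if changed:
                break

    while df.shape[1] >= 2:
        vifs = _vif(df)
        worst = vifs.idxmax()
        if vifs[worst] <= vif_max:
            break
        drops.append((worst, f"VIF={vifs[worst]:.2f}"))
        df = df.drop(columns=worst)

    report = pd.DataFrame(drops, columns=["predictor", "reason"])
    return EnvTable(df, zones=env.zones, units=env.units), report


def _vif(df: pd.DataFrame) -> pd.Series:
    X = (df - df.mean()) / df.std(ddof=0)
    X = X.to_numpy()
    out = {}
    for j, col in enumerate(df.columns):
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        r2 = 1.0 - resid @ resid / (X[:, j] @ X[:, j])
        out[col] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# RDA fit and axis retention
# ---------------------------------------------------------------------------

@dataclass
class RdaModel:
    X: np.ndarray                # individuals x p standardized predictors
    B: np.ndarray                # p x L coefficients
    Yfit: np.ndarray             # fitted genetic values Y'
    eigenvalues: np.ndarray      # constrained-axis eigenvalues, non-increasing
    loadings: np.ndarray         # loci x n_axes (right singular vectors)
    scores: np.ndarray           # individuals x n_axes site scores
    predictor_names: list[str] = field(default_factory=list)


def rda_fit(G: GenotypeMatrix, env: EnvTable, scale: bool = True) -> RdaModel:
    """Redundancy analysis of centered dosages on standardized predictors.

    Y (n x L) is the column-centered dosage matrix; X is the standardized
    predictor matrix expanded to individuals by their site. B is the OLS
    solution, Y' = X B, and the SVD of Y' yields constrained axes with
    eigenvalues (squared singular values)/(n-1), individual scores and locus
    loadings (unit-norm right singular vectors).

    With ``scale=True`` (default) dosage columns are standardized to unit
    variance before the regression. Binomial dosage variance depends on
    allele frequency, so unscaled loadings form a scale mixture across loci
    whose Mahalanobis distances have heavier-than-chi-squared tails;
    standardizing makes loci exchangeable and the outlier test well
    calibrated. ``scale=False`` is the plain covariance-based RDA.
    """
    if G.is_missing().any():
        raise ValueError("impute or filter missing calls before rda_fit")
    Xdf = env.expand_to_individuals(G.individuals["site"])
    names = list(Xdf.columns)
    X = Xdf.to_numpy(float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("need at least p+2 individuals")
    xtx = X.T @ X
    if np.linalg.cond(xtx) > 1e12:
        raise np.linalg.LinAlgError(
            "X'X is singular; remove collinear predictors with screen_predictors"
        )
    Y = G.dosages.astype(float)
    Y = Y - Y.mean(axis=0)
    if scale:
        sd = Y.std(axis=0, ddof=0)
        Y = Y / np.where(sd > 0, sd, 1.0)
    B = np.linalg.solve(xtx, X.T @ Y)
    Yfit = X @ B
    U, s, Vt = np.linalg.svd(Yfit, full_matrices=False)
    n_axes = min(p, n - 1)
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]
    eig = s**2 / (n - 1)
    return RdaModel(
        X=X,
        B=B,
        Yfit=Yfit,
        eigenvalues=eig,
        loadings=Vt.T,
        scores=U * s,
        predictor_names=names,
    )


def select_axes(eigenvalues: np.ndarray, method: str = "broken_stick") -> int:
    """Number of constrained axes to retain.

    ``broken_stick`` retains the leading axes through the last one whose
    eigenvalue share exceeds the broken-stick expectation
    b_i = (1/p) * sum_{j>=i} 1/j. (Stopping at the first axis below its
    expectation instead would discard diffuse multi-predictor signal behind
    a dominant structure axis.) ``fixed:K`` and ``proportion:x`` (smallest K
    reaching cumulative share x) are the mechanized alternatives. Always
    returns K >= 1.
    """
    eig = np.asarray(eigenvalues, float)
    if eig.size < 1:
        raise ValueError("need >= 1 eigenvalue")
    if method.startswith("fixed:"):
        k = int(method.split(":", 1)[1])
        return max(1, min(k, eig.size))
    total = eig.sum()
    if total <= 0:
        return 1
    share = eig / total
    if method.startswith("proportion:"):
        x = float(method.split(":", 1)[1])
        cum = np.cumsum(share) + 1e-12  # guard float round-off at the boundary
        return max(1, min(int(np.searchsorted(cum, x)) + 1, eig.size))
    if method != "broken_stick":
        raise ValueError(f"unknown axis-selection method {method!r}")
    p = eig.size
    bstick = np.array([np.sum(1.0 / np.arange(i + 1, p + 1)) / p for i in range(p)])
    above = np.flatnonzero(share > bstick)
    return int(above.max()) + 1 if above.size else 1


# ---------------------------------------------------------------------------
# robust outlier statistic
# ---------------------------------------------------------------------------

def robust_center_cov(
    loadings: np.ndarray,
    method: str = "mcd",
    support_fraction: float = 0.75,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Robust location/scatter of the locus-loading cloud.

    ``mcd`` uses the FAST-MCD minimum covariance determinant estimate with
    the given support fraction (contaminated loci — true outliers — then do
    not inflate the null covariance). ``classical`` returns the sample mean
    and covariance and exists for transparent small-instance cross-checks.
    A singular scatter is ridged by 1e-8 with a warning.
    """
    Z = np.atleast_2d(np.asarray(loadings, float))
    if Z.shape[0] <= 5 * Z.shape[1] and method == "mcd":
        raise ValueError("MCD needs L > 5*K loci")
    if method == "classical":
        mu = Z.mean(axis=0)
        cov = np.cov(Z, rowvar=False)
    elif method == "mcd":
        est = MinCovDet(support_fraction=support_fraction, random_state=seed).fit(Z)
        mu, cov = est.location_, est.covariance_
    else:
        raise ValueError(f"unknown method {method!r}")
    cov = np.atleast_2d(cov)
    if np.linalg.matrix_rank(cov) < cov.shape[0] or np.linalg.det(cov) <= 0:
        warnings.warn("singular scatter matrix; adding ridge 1e-8")
        cov = cov + 1e-8 * np.eye(cov.shape[0])
    return mu, cov


def mahalanobis_d2(loadings: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of each locus's loadings from (mu, cov)."""
    Z = np.atleast_2d(np.asarray(loadings, float)) - np.asarray(mu, float)
    cov = np.atleast_2d(cov)
    sol = np.linalg.solve(cov, Z.T)
    return np.einsum("ij,ji->i", Z, sol)


def genomic_inflation(d2: np.ndarray, k: int) -> float:
    """Genomic inflation factor: median observed statistic over the
    chi-squared(K) median (for K=2 the null median is exactly 2 ln 2)."""
    d2 = np.asarray(d2, float)
    if d2.size < 1:
        raise ValueError("need >= 1 locus")
    return float(np.median(d2) / stats.chi2.median(df=k))


def scan_pvalues(d2: np.ndarray, lam: float, k: int) -> np.ndarray:
    """Upper-tail chi-squared(K) p-values of the rescaled statistics D^2/lambda."""
    if lam <= 0:
        raise ValueError("inflation factor must be positive")
    return np.clip(stats.chi2.sf(np.asarray(d2, float) / lam, df=k), 0.0, 1.0)


def qvalues(p: np.ndarray, method: str = "storey") -> np.ndarray:
    """FDR q-values.

    ``bh`` is the Benjamini-Hochberg step-up adjustment. ``storey`` estimates
    the null proportion pi0 on a grid of tuning values lambda in [0.05, 0.95]
    with a cubic smoothing spline evaluated at the grid maximum (falling back
    to pi0 = 1 when the estimate is unstable), then scales the BH values.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    q_bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q_bh
    if method != "storey":
        raise ValueError(f"unknown q-value method {method!r}")
    pi0 = _storey_pi0(p)
    return np.minimum(pi0 * q_bh, 1.0)


def _storey_pi0(p: np.ndarray) -> float:
    grid = np.arange(0.05, 0.96, 0.05)
    pi0_raw = np.array([(p > lam).mean() / (1.0 - lam) for lam in grid])
    if p.size < 100 or np.all(pi0_raw == 0):
        return 1.0
    try:
        from scipy.interpolate import UnivariateSpline

        spl = UnivariateSpline(grid, pi0_raw, k=3)
        pi0 = float(spl(grid[-1]))
    except Exception:  # pragma: no cover - spline failure fallback
        pi0 = float(pi0_raw[-1])
    if not np.isfinite(pi0) or pi0 <= 0:
        return 1.0
    return min(pi0, 1.0)


def call_outliers(q: np.ndarray, q_max: float = 0.01) -> np.ndarray:
    """Boolean outlier mask: q strictly below the threshold."""
    return np.asarray(q, float) < q_max


# ---------------------------------------------------------------------------
# per-SNP environment correlation and gene mapping
# ---------------------------------------------------------------------------

def snp_env_correlation(
    G: GenotypeMatrix, env: EnvTable, locus_idx=None, predictors=None
) -> pd.DataFrame:
    """Pearson correlation between individual dosages and the individual's
    site-level predictor value (loci x predictors). Zero-variance dosage or
    predictor columns yield NaN (flagged undefined)."""
    locus_idx = np.arange(G.n_loci) if locus_idx is None else np.asarray(locus_idx)
    predictors = env.predictors if predictors is None else list(predictors)
    Xdf = env.expand_to_individuals(G.individuals["site"])
    d = G.dosages.astype(float)[:, locus_idx]
    d[G.is_missing()[:, locus_idx]] = np.nan
    out = np.full((len(locus_idx), len(predictors)), np.nan)
    for pj, pred in enumerate(predictors):
        x = Xdf[pred].to_numpy(float)
        for lj in range(len(locus_idx)):
            y = d[:, lj]
            ok = ~np.isnan(y)
            if ok.sum() < 3:
                continue
            xs, ys = x[ok], y[ok]
            if xs.std() == 0 or ys.std() == 0:
                continue
            out[lj, pj] = np.corrcoef(xs, ys)[0, 1]
    return pd.DataFrame(out, index=locus_idx, columns=predictors)


INTERGENIC = "Intergenic region"


def map_candidates(
    loci: pd.DataFrame, annotation: GeneAnnotation
) -> pd.DataFrame:
    """Assign each SNP to every gene interval containing its position
    (1-based inclusive, boundaries inside). SNPs outside all intervals get
    the label "Intergenic region"; chromosomes absent from the annotation
    trigger a warning and map intergenic."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    desc: dict[str, str] = {}
    for _, row in annotation.intervals.iterrows():
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end + 1, row.gene_id
        )
        desc[row.gene_id] = row.description
    known_chroms = set(trees)
    missing_chroms = set(loci["chrom"]) - known_chroms
    if missing_chroms:
        warnings.warn(
            f"chromosomes absent from annotation (mapped intergenic): "
            f"{sorted(missing_chroms)}"
        )
    rows = []
    for idx, row in loci.iterrows():
        hits = trees[row.chrom][row.pos] if row.chrom in trees else []
        if hits:
            for h in sorted(hits, key=lambda h: h.data):
                rows.append((idx, row.chrom, row.pos, h.data, desc.get(h.data, "")))
        else:
            rows.append((idx, row.chrom, row.pos, INTERGENIC, ""))
    return pd.DataFrame(
        rows, columns=["locus", "chrom", "pos", "gene_id", "annotation"]
    )


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

@dataclass
class RdaScanResult:
    model: RdaModel
    k_axes: int
    mu: np.ndarray
    cov: np.ndarray
    lam: float
    table: pd.DataFrame  # per locus: chrom, pos, d2, p, q, outlier (+ annotation)

    @property
    def outliers(self) -> pd.DataFrame:
        return self.table[self.table["outlier"]]


def rda_scan(
    G: GenotypeMatrix,
    env: EnvTable,
    axes: str = "broken_stick",
    robust: str = "mcd",
    q_method: str = "storey",
    q_max: float = 0.01,
    annotation: GeneAnnotation | None = None,
    seed: int = 0,
) -> RdaScanResult:
    """End-to-end genome scan: RDA, axis retention, robust Mahalanobis D^2,
    inflation-corrected chi-squared p-values, q-values, outlier calls, and
    (optionally) candidate-gene and best-predictor assignment for outliers.
    """
    model = rda_fit(G, env)
    k = select_axes(model.eigenvalues, method=axes)
    Z = model.loadings[:, :k]
    mu, cov = robust_center_cov(Z, method=robust, seed=seed)
    d2 = mahalanobis_d2(Z, mu, cov)
    lam = genomic_inflation(d2, k)
    p = scan_pvalues(d2, lam, k)
    q = qvalues(p, method=q_method)
    out = call_outliers(q, q_max=q_max)
    table = pd.DataFrame(
        {
            "locus": np.arange(G.n_loci),
            "chrom": G.loci["chrom"].to_numpy(),
            "pos": G.loci["pos"].to_numpy(),
            "d2": d2,
            "p": p,
            "q": q,
            "outlier": out,
        }
    )
    table["predictor"] = pd.NA
    table["r"] = np.nan
    if out.any():
        corr = snp_env_correlation(G, env, locus_idx=np.flatnonzero(out))
        best = corr.abs().idxmax(axis=1)
        for locus, pred in best.items():
            table.loc[table["locus"] == locus, "predictor"] = pred
            table.loc[table["locus"] == locus, "r"] = corr.loc[locus, pred]
    if annotation is not None and out.any():
        hits = map_candidates(
            G.loci.iloc[np.flatnonzero(out)], annotation
        ).set_index("locus")
        gene = hits.groupby(level=0)["gene_id"].agg(";".join)
        ann = hits.groupby(level=0)["annotation"].agg(
            lambda s: ";".join(x for x in s if x)
        )
        table["gene"] = table["locus"].map(gene)
        table["gene_annotation"] = table["locus"].map(ann)
    return RdaScanResult(model=model, k_axes=k, mu=mu, cov=cov, lam=lam, table=table)
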