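"""Marker QC and deterministic imputation.

Filtering follows standard GBS practice: drop loci below a minor-allele
frequency threshold (default 5%), gate on per-locus and per-individual
missingness, then replace remaining missing calls by the locus mean dosage.
Mean-dosage imputation is the variance-minimizing single value for the
centered-dosage statistics downstream (RDA, LD, DAPC); the admixture EM
instead skips missing cells and never needs imputed input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from grazescan.io import GenotypeMatrix


@dataclass
class QcReport:
    n_in: int
    n_kept: int
    n_removed_maf: int = 0
    n_removed_missing: int = 0
    n_individuals_removed: int = 0
    maf: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_in != self.n_kept + self.n_removed_maf + self.n_removed_missing:
            raise ValueError("QcReport counts do not add up")

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_kept": self.n_kept,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_missing": self.n_removed_missing,
            "n_individuals_removed": self.n_individuals_removed,
        }


def minor_allele_freq(G: GenotypeMatrix) -> np.ndarray:
    """Per-locus MAF = min(f, 1-f) over non-missing calls; NaN if no calls."""
    f = G.allele_freqs()
    return np.minimum(f, 1.0 - f)


def maf_filter(G: GenotypeMatrix, threshold: float = 0.05) -> tuple[GenotypeMatrix, QcReport]:
    """Remove loci with MAF strictly below ``threshold``.

    All-missing loci are removed too but counted under missingness. Locus
    order is preserved; the operation is idempotent.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5]")
    maf = minor_allele_freq(G)
    all_missing = np.isnan(maf)
    low = ~all_missing & (maf < threshold)
    keep = ~all_missing & ~low
    out = G.subset(locus_idx=np.flatnonzero(keep))
    report = QcReport(
        n_in=G.n_loci,
        n_kept=int(keep.sum()),
        n_removed_maf=int(low.sum()),
        n_removed_missing=int(all_missing.sum()),
        maf=maf[keep],
    )
    return out, report


def missingness_filter(
    G: GenotypeMatrix,
    max_locus_missing: float = 0.5,
    max_indiv_missing: float = 0.5,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop loci, then individuals, whose missing-call rate exceeds the caps."""
    for r in (max_locus_missing, max_indiv_missing):
        if not 0.0 <= r <= 1.0:
            raise ValueError("missingness thresholds must be in [0, 1]")
    miss = G.is_missing()
    locus_rate = miss.mean(axis=0)
    keep_loci = locus_rate <= max_locus_missing
    G2 = G.subset(locus_idx=np.flatnonzero(keep_loci))
    ind_rate = G2.is_missing().mean(axis=1) if G2.n_loci else np.zeros(G2.n_individuals)
    keep_ind = ind_rate <= max_indiv_missing
    out = G2.subset(ind_idx=np.flatnonzero(keep_ind))
    report = QcReport(
        n_in=G.n_loci,
        n_kept=int(keep_loci.sum()),
        n_removed_missing=int((~keep_loci).sum()),
        n_individuals_removed=int((~keep_ind).sum()),
    )
    return out, report


def impute_mean_dosage(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by the locus mean dosage (float output).

    Observed cells are unchanged, so column means are conserved exactly.
    """
    miss = G.is_missing()
    if not miss.any():
        return GenotypeMatrix(
            G.dosages.astype(float), G.loci.copy(), G.individuals.copy()
        )
    d = G.dosages.astype(float)
    d[miss] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(d, axis=0)
    if np.isnan(col_mean).any():
        bad = int(np.isnan(col_mean).sum())
        raise ValueError(
            f"{bad} loci have no observed calls; run missingness_filter first"
        )
    rows, cols = np.nonzero(miss)
    d[rows, cols] = col_mean[cols]
    return GenotypeMatrix(d, G.loci.copy(), G.individuals.copy())
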