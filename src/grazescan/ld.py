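"""Pairwise linkage disequilibrium (genotypic r^2) and its decay with
physical distance.

r^2 here is the squared Pearson correlation of ALT-allele dosages between
two loci over the individuals with non-missing calls at both — the
composite genotypic measure appropriate for unphased dosage data. The decay
summary follows the common practice of binning same-chromosome pairs by
distance and reporting where the (smoothed) mean-r^2 curve first drops below
a threshold (0.2 by convention); because that phrase is used ambiguously in
the literature, the mean distance among sub-threshold pairs is reported as a
second statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from grazescan.io import GenotypeMatrix
from grazescan.qc import minor_allele_freq

#: returned when the decay curve never crosses the threshold
BEYOND_MAX_DISTANCE = math.inf


def pairwise_r2(
    G: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    maf_min: float = 0.05,
    min_calls: int = 10,
) -> pd.DataFrame:
    """Genotypic r^2 for every same-chromosome locus pair within
    ``max_dist_bp``. Loci below ``maf_min`` are excluded; pairs with fewer
    than ``min_calls`` shared non-missing calls or zero dosage variance are
    skipped. Returns columns chrom, pos1, pos2, dist_bp, r2."""
    maf = minor_allele_freq(G)
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= maf_min))
    d = G.dosages.astype(float)
    d[G.is_missing()] = np.nan
    rows = []
    for chrom in pd.unique(G.loci["chrom"]):
        idx = keep[(G.loci["chrom"].to_numpy()[keep] == chrom)]
        pos = G.loci["pos"].to_numpy()[idx]
        order = np.argsort(pos)
        idx, pos = idx[order], pos[order]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                dist = pos[b] - pos[a]
                if dist > max_dist_bp:
                    break
                if dist == 0:
                    continue
                x, y = d[:, idx[a]], d[:, idx[b]]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < min_calls:
                    continue
                xs, ys = x[ok], y[ok]
                if xs.std() == 0 or ys.std() == 0:
                    continue
                r = np.corrcoef(xs, ys)[0, 1]
                rows.append((chrom, int(pos[a]), int(pos[b]), int(dist), r * r))
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "dist_bp", "r2"])


def decay_curve(pairs: pd.DataFrame, bin_width_bp: int = 10_000) -> pd.DataFrame:
    """Mean r^2 per non-overlapping distance bin (midpoint, mean, n)."""
    if len(pairs) < 1:
        raise ValueError("need >= 1 pair")
    edges = np.arange(0, pairs["dist_bp"].max() + bin_width_bp, bin_width_bp)
    which = np.digitize(pairs["dist_bp"], edges) - 1
    rows = []
    for b in range(len(edges)):
        sel = which == b
        if not sel.any():
            continue
        rows.append(
            (edges[b] + bin_width_bp / 2.0, float(pairs.loc[sel, "r2"].mean()), int(sel.sum()))
        )
    return pd.DataFrame(rows, columns=["dist_mid_bp", "mean_r2", "n_pairs"])


@dataclass
class ThresholdDistance:
    #: midpoint of the first bin where the smoothed curve drops below threshold
    first_crossing_bp: float
    #: mean distance among pairs with r^2 below the threshold
    mean_subthreshold_bp: float
    r2_threshold: float


def threshold_distance(
    curve: pd.DataFrame,
    pairs: pd.DataFrame | None = None,
    r2_threshold: float = 0.2,
    smooth_window: int = 3,
) -> ThresholdDistance:
    """Distance at which LD falls under ``r2_threshold``.

    The headline statistic is the midpoint of the first bin at which the
    moving-average-smoothed decay curve drops below the threshold; if the
    curve never crosses, the sentinel ``inf`` ("beyond max distance") is
    returned. When ``pairs`` is given, the mean distance among pairs with
    r^2 < threshold is reported as the secondary statistic.
    """
    vals = curve["mean_r2"].to_numpy(float)
    if smooth_window > 1 and len(vals) >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(vals, kernel, mode="same")
        # edges of 'same' convolution shrink toward 0; patch with raw values
        half = smooth_window // 2
        smoothed[:half] = vals[:half]
        smoothed[len(vals) - half:] = vals[len(vals) - half:]
    else:
        smoothed = vals
    below = np.flatnonzero(smoothed < r2_threshold)
    first = float(curve["dist_mid_bp"].iloc[below[0]]) if below.size else BEYOND_MAX_DISTANCE
    mean_sub = BEYOND_MAX_DISTANCE
    if pairs is not None:
        sub = pairs.loc[pairs["r2"] < r2_threshold, "dist_bp"]
        if len(sub):
            mean_sub = float(sub.mean())
    return ThresholdDistance(first, mean_sub, r2_threshold)
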