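"""Phenotype-side statistics: growing degree days, one-way ANOVA with
Tukey-Kramer multiple comparisons and compact letter display, and linear
regression of traits on ancestry membership probability."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# growing degree days
# ---------------------------------------------------------------------------

def gdd(series: pd.DataFrame, base: float = 5.0) -> pd.Series:
    """Cumulative growing degree days from a daily tmax/tmin table.

    Daily GDD = max(0, (tmax + tmin)/2 - base); negative days truncate to 0
    and never subtract. Returns the cumulative sum indexed like ``series``.
    """
    if (series["tmax"] < series["tmin"]).any():
        raise ValueError("tmax < tmin in the temperature series")
    daily = np.maximum(0.0, (series["tmax"] + series["tmin"]) / 2.0 - base)
    return daily.cumsum()


def days_to_flower_gdd(series: pd.DataFrame, flower_day: int, base: float = 5.0) -> float:
    """Thermal time accumulated from the series start to the flowering day
    (inclusive). ``flower_day`` refers to the ``day`` column."""
    days = series["day"].to_numpy()
    if flower_day < days.min() or flower_day > days.max():
        raise ValueError(f"flowering day {flower_day} outside the series")
    cum = gdd(series, base=base)
    return float(cum[series["day"] <= flower_day].iloc[-1])


# ---------------------------------------------------------------------------
# ANOVA + Tukey-Kramer + compact letter display
# ---------------------------------------------------------------------------

@dataclass
class TukeyTable:
    table: pd.DataFrame        # group, n, mean, letters
    f_stat: float
    p_value: float
    mse: float
    sem: float                 # sqrt(MSE / harmonic mean n)
    alpha: float
    pairwise_p: pd.DataFrame   # symmetric group x group Tukey p-values


def anova_tukey(values, groups, alpha: float = 0.05) -> TukeyTable:
    """One-way fixed-effects ANOVA followed by Tukey-Kramer comparisons.

    All pairwise mean differences are referred to the studentized-range
    distribution (Tukey-Kramer form for unbalanced group sizes); the compact
    letter display is built by insert-and-absorb so that two groups share a
    letter iff they are not significantly different at ``alpha``.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    data = [values[groups == g] for g in labels]
    ns = np.array([len(d) for d in data])
    if ns.min() < 2:
        raise ValueError("need >= 2 observations per group")
    means = np.array([d.mean() for d in data])
    n_tot = ns.sum()
    grand = values.mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((d - m) ** 2).sum() for d, m in zip(data, means)))
    df_between, df_within = k - 1, n_tot - k
    mse = ss_within / df_within
    if mse == 0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = (ss_between / df_between) / mse
        p_value = float(stats.f.sf(f_stat, df_between, df_within))

    pw = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0:
                pval = 0.0 if means[i] != means[j] else 1.0
            else:
                qstat = abs(means[i] - means[j]) / se
                pval = float(stats.studentized_range.sf(qstat, k, df_within))
            pw[i, j] = pw[j, i] = pval
    sig = pw < alpha  # True where groups differ

    letters = _compact_letter_display(sig, order=np.argsort(-means))
    harm_n = k / np.sum(1.0 / ns)
    table = pd.DataFrame(
        {"group": labels, "n": ns, "mean": means, "letters": letters}
    )
    return TukeyTable(
        table=table,
        f_stat=float(f_stat),
        p_value=p_value,
        mse=mse,
        sem=float(np.sqrt(mse / harm_n)),
        alpha=alpha,
        pairwise_p=pd.DataFrame(pw, index=labels, columns=labels),
    )


def _compact_letter_display(sig: np.ndarray, order: np.ndarray) -> list[str]:
    """Insert-and-absorb compact letter display.

    ``sig[i, j]`` is True when groups i and j differ. Letter sets are grown
    so every non-significant pair shares a letter and every significant pair
    shares none; redundant (absorbed) letters are removed and letters are
    assigned in the given group order (typically by descending mean).
    """
    k = sig.shape[0]
    # start with one letter covering everything; split it on each significant
    # pair, then absorb columns contained in another
    cols: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            new_cols: list[set[int]] = []
            for col in cols:
                if i in col and j in col:
                    new_cols.append(col - {i})
                    new_cols.append(col - {j})
                else:
                    new_cols.append(col)
            cols = [
                c
                for c in new_cols
                if c and not any(c < d for d in new_cols if d is not c)
            ]
            # drop exact duplicates
            uniq = []
            for c in cols:
                if c not in uniq:
                    uniq.append(c)
            cols = uniq
    # deterministic letter order: by the first (best) group each column contains
    rank = {int(g): r for r, g in enumerate(order)}
    cols.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ["" for _ in range(k)]
    for li, col in enumerate(cols):
        ch = alphabet[li] if li < len(alphabet) else f"z{li}"
        for g in col:
            out[g] += ch
    return ["".join(sorted(s)) for s in out]


# ---------------------------------------------------------------------------
# membership regression
# ---------------------------------------------------------------------------

@dataclass
class MembershipRegression:
    trait: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    stderr: float
    n: int


def membership_regression(
    trait_values, membership, trait: str = ""
) -> MembershipRegression:
    """OLS of a trait on ancestry membership probability (slope t-test)."""
    y = np.asarray(trait_values, float)
    x = np.asarray(membership, float)
    ok = ~np.isnan(y) & ~np.isnan(x)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0:
        raise ValueError("membership has zero variance; regression undefined")
    if y.std() == 0:
        # constant trait: no association by definition
        return MembershipRegression(
            trait=trait, slope=0.0, intercept=float(y[0]), r2=0.0,
            p_value=1.0, stderr=0.0, n=len(y),
        )
    res = stats.linregress(x, y)
    return MembershipRegression(
        trait=trait,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n=len(y),
    )
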