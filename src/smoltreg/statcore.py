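"""Shared statistical kernel for the differential analyses.

All differential testing in the pipeline runs through this module: CPM
normalisation, a one-way (ANOVA-like) F-test across time points, Welch's
two-sample t for pairwise contrasts, Benjamini-Hochberg FDR, Fisher's exact
test for 2x2 association, the upper-tail hypergeometric over-representation
test, and Pearson correlation with its t-based p-value.

The count-based quasi-likelihood machinery of dedicated RNA-seq packages is
deliberately replaced by these classical tests on log2 CPM values (with a
pseudocount); the tests are calibrated on synthetic nulls and the transform
and pseudocount are surfaced as parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def cpm_normalize(
    counts: pd.DataFrame, log: bool = False, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Counts-per-million per sample column; optionally log2(CPM + pseudocount).

    Each column is scaled to sum to 1e6 before the log. Columns with zero
    total raise, naming the sample.
    """
    colsums = counts.sum(axis=0)
    empty = colsums[colsums <= 0]
    if len(empty):
        raise ValueError(f"empty count column(s): {list(empty.index)}")
    cpm = counts / colsums * 1e6
    if log:
        return np.log2(cpm + pseudocount)
    return cpm


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, order-preserving, NaN-propagating.

    NaN p-values are excluded from the number of tests m and returned as
    NaN. Output is monotone in the sorted p-values and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if np.any((pm < 0) | (pm > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pm.size
    if m == 0:
        return out
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


# ---------------------------------------------------------------------------
# Differential tests
# ---------------------------------------------------------------------------

def anova_like_test(values: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-feature one-way F-test across groups on (already transformed) values.

    Parameters
    ----------
    values : features x samples matrix (e.g. log2 CPM).
    groups : group label per sample column.

    Returns a DataFrame indexed like ``values`` with columns F, PValue, FDR.
    Features with zero total variance get F=0, p=1 by convention; features
    with zero within-group variance but non-zero between-group variance get
    p=0 (infinite evidence under this model).
    """
    groups = np.asarray(groups)
    if groups.size != values.shape[1]:
        raise ValueError("groups length must match the number of sample columns")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    x = values.to_numpy(dtype=float)
    n = x.shape[1]
    k = len(labels)
    df_within = n - k
    if df_within <= 0:
        raise ValueError("no within-group degrees of freedom (all groups singleton?)")
    grand = x.mean(axis=1)
    ss_between = np.zeros(x.shape[0])
    ss_within = np.zeros(x.shape[0])
    for lab in labels:
        sel = x[:, groups == lab]
        mu = sel.mean(axis=1)
        ss_between += sel.shape[1] * (mu - grand) ** 2
        ss_within += ((sel - mu[:, None]) ** 2).sum(axis=1)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / df_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    p = np.empty(x.shape[0])
    ok = ms_within > 0
    p[ok] = stats.f.sf(f[ok], k - 1, df_within)
    # zero within-group variance: p=1 if also no between-group variance, else 0
    degenerate = ~ok
    between_zero = ss_between <= 1e-12
    p[degenerate & between_zero] = 1.0
    f[degenerate & between_zero] = 0.0
    p[degenerate & ~between_zero] = 0.0
    f[degenerate & ~between_zero] = np.inf
    return pd.DataFrame(
        {"F": f, "PValue": p, "FDR": bh_adjust(p)}, index=values.index
    )


def pairwise_test(
    values: pd.DataFrame, samples_a, samples_b
) -> pd.DataFrame:
    """Welch two-sample t-test per feature between two sample sets.

    ``logFC`` is mean(A) - mean(B) on the provided (log2) scale, so a
    positive value means higher in the first-named group. Returns columns
    logFC, logCPM (mean over both groups), t, PValue, FDR.
    """
    a = values.loc[:, list(samples_a)].to_numpy(dtype=float)
    b = values.loc[:, list(samples_b)].to_numpy(dtype=float)
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both groups must be non-empty")
    if a.shape[1] < 2 and b.shape[1] < 2:
        raise ValueError("at least one group needs >= 2 observations")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant features trigger scipy precision warnings; the
        # degenerate cases are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    # degenerate: both groups constant
    var_a = a.var(axis=1, ddof=1) if a.shape[1] > 1 else np.zeros(a.shape[0])
    var_b = b.var(axis=1, ddof=1) if b.shape[1] > 1 else np.zeros(b.shape[0])
    degenerate = (np.nan_to_num(var_a) == 0) & (np.nan_to_num(var_b) == 0)
    t = np.where(degenerate & (logfc == 0), 0.0, t)
    p = np.where(degenerate & (logfc == 0), 1.0, p)
    p = np.where(degenerate & (logfc != 0), 0.0, p)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "logCPM": np.concatenate([a, b], axis=1).mean(axis=1),
            "t": t,
            "PValue": p,
            "FDR": bh_adjust(p),
        },
        index=values.index,
    )


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

@dataclass
class Contingency2x2:
    """2x2 contingency table with Fisher's exact test result.

    ``odds_ratio`` is the sample OR (a*d)/(b*c); when any cell is zero the
    Haldane correction (+0.5 to every cell) is applied and flagged. A table
    with a zero margin carries no association information: p is 1 and the OR
    is flagged undefined.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_sided: float
    haldane: bool = False
    or_defined: bool = True


def fisher_exact_2x2(table) -> Contingency2x2:
    """Two-sided Fisher's exact test (sum of tables no more probable than
    the observed one, conditional on the margins)."""
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return Contingency2x2(a, b, c, d, math.nan, 1.0, or_defined=False)
    haldane = 0 in (a, b, c, d)
    if haldane:
        oratio = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        oratio = a * d / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return Contingency2x2(a, b, c, d, oratio, float(p), haldane=haldane)


def hypergeom_ora(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric over-representation p-value, P(X >= k).

    ``k`` hits in a set of size ``n`` drawn from a universe of size ``N``
    containing ``K`` hits in total.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError("require 0 <= k <= min(n, K)")
    if n > N or K > N:
        raise ValueError("require n <= N and K <= N")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-based p-value (n-2 df).

    Zero variance on either side raises ValueError (the caller excludes
    such pairs and counts them).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
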