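"""Differential expression across the smoltification time course.

The experiment follows liver gene expression in Atlantic salmon over four
sampling weeks (1, 10, 19, 25): week 1 is the freshwater parr stage, a
winter-like short photoperiod is applied between weeks 1 and 10,
smoltification completes by week 19, and fish are transferred to seawater
before week 25. Three fish groups exist: ``short`` (short photoperiod then
seawater), ``long`` (constant light), and ``fresh_control`` (short
photoperiod but kept in freshwater).

This module tests for expression changes across the weeks of the short
photoperiod group (ANOVA-like F-test), groups the resulting DEGs into
co-expression clusters by hierarchical clustering of gene-scaled profiles
with a correlation-gated membership, runs the pairwise photoperiod and
salinity contrasts, and provides a generic hypergeometric pathway
over-representation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import statcore

WEEKS = ("week_1", "week_10", "week_19", "week_25")
GROUPS = ("short", "long", "fresh_control")

#: named pairwise contrasts: (week, group A, group B); logFC = A - B
CONTRASTS = {
    "photoperiod_w10": ("week_10", "short", "long"),
    "photoperiod_w19": ("week_19", "short", "long"),
    "salinity_w25": ("week_25", "short", "fresh_control"),
}


@dataclass
class ExpressionMatrix:
    """Gene x sample counts with the sample design.

    ``samples`` has one row per count column with columns
    sample_id, week, group, replicate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValueError("sample sheet rows must match count columns in order")
        bad = set(self.samples["week"]) - set(WEEKS)
        if bad:
            raise ValueError(f"unknown week labels: {sorted(bad)}")

    def subset(self, group: str | None = None, week: str | None = None,
               exclude_samples: tuple[str, ...] = ()) -> "ExpressionMatrix":
        keep = pd.Series(True, index=self.samples.index)
        if group is not None:
            keep &= self.samples["group"] == group
        if week is not None:
            keep &= self.samples["week"] == week
        if exclude_samples:
            keep &= ~self.samples["sample_id"].isin(exclude_samples)
        samples = self.samples[keep]
        return ExpressionMatrix(self.counts[samples["sample_id"]], samples)

    def log_cpm(self, pseudocount: float = 0.5) -> pd.DataFrame:
        return statcore.cpm_normalize(self.counts, log=True, pseudocount=pseudocount)


@dataclass
class ClusterAssignment:
    gene_id: str
    cluster: int | None
    correlation_to_mean: float


# ---------------------------------------------------------------------------
# ANOVA-like DE across weeks
# ---------------------------------------------------------------------------

def run_anova_de(
    matrix: ExpressionMatrix,
    group: str = "short",
    alpha: float = 0.05,
    exclude_samples: tuple[str, ...] = (),
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """F-test for any change between weeks within one fish group.

    Returns the full per-gene table (F, PValue, FDR) with a boolean ``deg``
    column marking FDR < alpha.
    """
    sub = matrix.subset(group=group, exclude_samples=exclude_samples)
    present = set(sub.samples["week"])
    missing = set(WEEKS) - present
    if missing:
        raise ValueError(
            f"missing week(s) {sorted(missing)}; present: {sorted(present)}"
        )
    values = sub.log_cpm(pseudocount)
    res = statcore.anova_like_test(values, sub.samples["week"].to_numpy())
    res["deg"] = res["FDR"] < alpha
    return res


# ---------------------------------------------------------------------------
# Co-expression clustering
# ---------------------------------------------------------------------------

def scaled_profiles(
    matrix: ExpressionMatrix,
    genes,
    group: str = "short",
    exclude_samples: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Gene-scaled expression: per-gene z-score of CPM across samples.

    This is the profile used both for clustering distance and for the
    correlation gate; a per-gene scale/offset (e.g. gene length, turning CPM
    into TPM) does not change it.
    """
    sub = matrix.subset(group=group, exclude_samples=exclude_samples)
    cpm = statcore.cpm_normalize(sub.counts, log=False)
    prof = cpm.loc[list(genes)]
    mu = prof.mean(axis=1)
    sd = prof.std(axis=1, ddof=0)
    sd = sd.replace(0, np.nan)
    z = prof.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    return z


def cluster_degs(
    matrix: ExpressionMatrix,
    degs,
    k: int = 7,
    membership_threshold: float = 0.5,
    group: str = "short",
    linkage_method: str = "ward",
    exclude_samples: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Hierarchical co-expression clustering of DEGs with a correlation gate.

    Gene-scaled profiles are clustered on Euclidean distances (Ward linkage
    by default) and the tree cut at ``k`` clusters. Each gene's Pearson
    correlation to its own cluster's mean profile is computed; genes at or
    below ``membership_threshold`` are excluded (cluster <NA>) but keep
    their failing correlation. Input gene order does not matter: genes are
    processed in sorted gene_id order.

    Returns a DataFrame with columns gene_id, cluster (nullable Int64),
    correlation.
    """
    degs = sorted(set(degs))
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(degs) < k:
        raise ValueError(f"need at least k={k} DEGs, got {len(degs)}")
    z = scaled_profiles(matrix, degs, group=group, exclude_samples=exclude_samples)
    dist = pdist(z.to_numpy(), metric="euclidean")
    tree = hierarchy.linkage(dist, method=linkage_method)
    labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    out = pd.DataFrame({"gene_id": degs, "cluster": labels})
    corr = np.empty(len(degs))
    zm = z.to_numpy()
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        mean_prof = zm[idx].mean(axis=0)
        for i in idx:
            gi = zm[i]
            denom = np.std(gi) * np.std(mean_prof)
            if denom == 0:
                corr[i] = np.nan
            else:
                corr[i] = float(np.corrcoef(gi, mean_prof)[0, 1])
    out["correlation"] = corr
    gate = ~(out["correlation"] > membership_threshold)
    out["cluster"] = out["cluster"].astype("Int64")
    out.loc[gate, "cluster"] = pd.NA
    return out


def cluster_sum_of_squares(
    matrix: ExpressionMatrix, degs, k_range=range(2, 13), group: str = "short",
    linkage_method: str = "ward",
) -> pd.DataFrame:
    """Within/between sum-of-squares across candidate k, for model inspection."""
    degs = sorted(set(degs))
    z = scaled_profiles(matrix, degs, group=group).to_numpy()
    tree = hierarchy.linkage(pdist(z), method=linkage_method)
    rows = []
    total = ((z - z.mean(axis=0)) ** 2).sum()
    for k in k_range:
        labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
        within = 0.0
        for c in np.unique(labels):
            sel = z[labels == c]
            within += ((sel - sel.mean(axis=0)) ** 2).sum()
        rows.append({"k": k, "within_ss": within, "between_ss": total - within})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pairwise contrasts
# ---------------------------------------------------------------------------

def run_pairwise_contrasts(
    matrix: ExpressionMatrix,
    contrast: str,
    alpha: float = 0.05,
    exclude_samples: tuple[str, ...] = (),
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Welch test between the two arms of a named contrast at one week.

    logFC follows the first-named-arm-minus-second convention, so for
    ``photoperiod_w10`` a positive logFC means higher under the short
    photoperiod, and for ``salinity_w25`` higher in seawater.
    """
    if contrast not in CONTRASTS:
        raise ValueError(
            f"unknown contrast {contrast!r}; valid: {sorted(CONTRASTS)}"
        )
    week, group_a, group_b = CONTRASTS[contrast]
    sub = matrix.subset(week=week, exclude_samples=exclude_samples)
    ids_a = sub.samples.loc[sub.samples["group"] == group_a, "sample_id"]
    ids_b = sub.samples.loc[sub.samples["group"] == group_b, "sample_id"]
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError(f"contrast {contrast}: an arm has no samples at {week}")
    values = sub.log_cpm(pseudocount)
    res = statcore.pairwise_test(values, ids_a, ids_b)
    res["deg"] = res["FDR"] < alpha
    return res


# ---------------------------------------------------------------------------
# Pathway over-representation
# ---------------------------------------------------------------------------

def ora_pathways(
    gene_set, universe, pathway_db: dict[str, set], alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric over-representation of pathways in a gene set.

    ``pathway_db`` maps pathway name to gene ids; genes outside ``universe``
    are ignored. BH adjustment is applied across pathways.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(gene_set) & universe
    rows = []
    for pathway, members in sorted(pathway_db.items()):
        members = set(members) & universe
        if not members:
            continue
        k = len(hits & members)
        rows.append(
            {
                "pathway": pathway,
                "hits": k,
                "set_size": len(hits),
                "pathway_size": len(members),
                "universe": len(universe),
                "PValue": statcore.hypergeom_ora(
                    k, len(hits), len(members), len(universe)
                ),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["FDR"] = statcore.bh_adjust(out["PValue"])
        out["significant"] = out["FDR"] < alpha
    return out


# ---------------------------------------------------------------------------
# PCA screening report
# ---------------------------------------------------------------------------

def pca_report(matrix: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """Sample-level PCA of log2 CPM, as an outlier-screening report.

    Screening is reported, never applied automatically; excluded samples are
    an explicit configuration choice.
    """
    from sklearn.decomposition import PCA

    values = matrix.log_cpm().to_numpy().T
    pca = PCA(n_components=min(n_components, values.shape[0] - 1))
    coords = pca.fit_transform(values - values.mean(axis=0))
    out = matrix.samples.copy()
    for i in range(coords.shape[1]):
        out[f"PC{i + 1}"] = coords[:, i]
        out[f"PC{i + 1}_var"] = pca.explained_variance_ratio_[i]
    return out
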