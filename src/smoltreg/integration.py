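"""Binding-pattern x co-expression-cluster enrichment.

Each motif site's bound/unbound calls over the four sampling weeks are
encoded as a 4-character binding pattern ("1001" = bound in weeks 1 and
25). Sites are tied to genes through their host peak's nearest-TSS link.
For every combination of motif, non-constant binding pattern, and
co-expression cluster, a Fisher's exact test asks whether the motif's
DEG-linked sites carrying that pattern are over-represented near genes of
that cluster. The constant patterns "0000" and "1111" carry no temporal
information and are excluded from testing (14 informative patterns
remain); an assumed primary/secondary pattern per cluster can be flagged
for display, with the most significant motifs labelled per test family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import statcore
from .expression import WEEKS

CONSTANT_PATTERNS = ("0000", "1111")
ALL_PATTERNS = tuple(f"{i:04b}" for i in range(16))
NONCONSTANT_PATTERNS = tuple(
    p for p in ALL_PATTERNS if p not in CONSTANT_PATTERNS
)

#: Default assumed binding patterns per cluster (primary, secondary),
#: encoding binding at the weeks of each cluster's peak expression.
#: Editable configuration, not a measured quantity.
DEFAULT_ASSUMED_PATTERNS: dict[int, tuple[str, str]] = {
    1: ("0001", "0011"),
    2: ("0010", "0011"),
    3: ("0010", "0110"),
    4: ("0100", "0110"),
    5: ("0100", "1100"),
    6: ("1001", "1000"),
    7: ("1000", "1100"),
}


def validate_pattern(pattern: str) -> str:
    if len(pattern) != 4 or any(ch not in "01" for ch in pattern):
        raise ValueError(f"invalid binding pattern {pattern!r}")
    return pattern


def encode_patterns(site_scores: pd.DataFrame) -> pd.Series:
    """4-character bound/unbound string per site, weeks in chronological order.

    Raises if any week's bound flag column is missing.
    """
    cols = [f"bound_{w}" for w in WEEKS]
    missing = [c for c in cols if c not in site_scores.columns]
    if missing:
        raise ValueError(f"missing bound flag column(s): {missing}")
    flags = site_scores[cols].to_numpy(dtype=bool)
    patterns = ["".join("1" if b else "0" for b in row) for row in flags]
    return pd.Series(patterns, index=site_scores.index, name="pattern")


def enrich_patterns(
    site_scores: pd.DataFrame,
    site_links: pd.DataFrame,
    cluster_assignments: pd.DataFrame,
    exclude_constant: bool = True,
    min_sites: int = 10,
) -> pd.DataFrame:
    """Fisher enrichment of each (motif, pattern, cluster) combination.

    ``site_links`` maps site name -> gene_id (via the host peak's
    nearest-TSS link); only sites linked to clustered DEGs enter the test.
    For motif M, pattern P, cluster C the 2x2 is
    [P & C, P & not-C; not-P & C, not-P & not-C] over M's DEG-linked
    sites, so each table's total is M's DEG-linked site count. Motifs with
    no DEG-linked sites (or fewer than ``min_sites``) are skipped and
    reported in ``attrs['skipped_motifs']``. Output is sorted by cluster
    then p-value.
    """
    gene_cluster = (
        cluster_assignments.dropna(subset=["cluster"])
        .set_index("gene_id")["cluster"]
        .astype(int)
    )
    df = site_scores.copy()
    df["pattern"] = encode_patterns(df)
    link_map = site_links.set_index("site")["gene_id"]
    df["gene_id"] = df["site"].map(link_map)
    df["cluster"] = df["gene_id"].map(gene_cluster)
    df = df.dropna(subset=["cluster"])
    df["cluster"] = df["cluster"].astype(int)
    patterns = NONCONSTANT_PATTERNS if exclude_constant else ALL_PATTERNS
    clusters = sorted(gene_cluster.unique())
    rows = []
    skipped = []
    for motif_id, grp in df.groupby("motif_id", sort=True):
        if len(grp) < min_sites:
            skipped.append(motif_id)
            continue
        total = len(grp)
        for cluster in clusters:
            in_c = grp["cluster"] == cluster
            n_c = int(in_c.sum())
            for pattern in patterns:
                has_p = grp["pattern"] == pattern
                a = int((has_p & in_c).sum())
                b = int(has_p.sum()) - a
                c = n_c - a
                d = total - a - b - c
                res = statcore.fisher_exact_2x2([[a, b], [c, d]])
                rows.append(
                    {
                        "deg_cluster": cluster,
                        "binding": pattern,
                        "count": a,
                        "pval": res.p_two_sided,
                        "OR": res.odds_ratio,
                        "TFBS_name": motif_id,
                        "a": a, "b": b, "c": c, "d": d,
                    }
                )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["deg_cluster", "pval", "TFBS_name", "binding"]
        ).reset_index(drop=True)
    out.attrs["skipped_motifs"] = skipped
    return out


def flag_assumed_and_label(
    enrichments: pd.DataFrame,
    assumed_map: dict[int, tuple[str, str]] | None = None,
    top_quantile: float = 0.1,
) -> pd.DataFrame:
    """Flag rows matching each cluster's assumed patterns and label top hits.

    ``assumed_map`` maps cluster -> (primary pattern, secondary pattern);
    it must cover every cluster present and use valid non-constant
    patterns. Within each (cluster, pattern) test family, motifs whose
    p-value falls in the most significant ``top_quantile`` fraction are
    marked ``labeled`` for display.
    """
    if assumed_map is None:
        assumed_map = DEFAULT_ASSUMED_PATTERNS
    if not 0 <= top_quantile <= 1:
        raise ValueError("top_quantile must be in [0, 1]")
    for cluster, (prim, sec) in assumed_map.items():
        for p in (prim, sec):
            validate_pattern(p)
            if p in CONSTANT_PATTERNS:
                raise ValueError(
                    f"assumed pattern {p} for cluster {cluster} is constant"
                )
    missing = set(enrichments["deg_cluster"].unique()) - set(assumed_map)
    if missing:
        raise ValueError(f"assumed-pattern map missing cluster(s) {missing}")
    out = enrichments.copy()
    def role(row):
        prim, sec = assumed_map[row["deg_cluster"]]
        if row["binding"] == prim:
            return "primary"
        if row["binding"] == sec:
            return "secondary"
        return "other"
    out["assumed"] = out.apply(role, axis=1) if len(out) else []
    out["labeled"] = False
    for (_, _), grp in out.groupby(["deg_cluster", "binding"], sort=False):
        if top_quantile == 0:
            continue
        cut = grp["pval"].quantile(top_quantile, interpolation="lower")
        out.loc[grp.index[grp["pval"] <= cut], "labeled"] = True
    if top_quantile == 0:
        out["labeled"] = False
    elif top_quantile == 1:
        out["labeled"] = True
    return out


def expected_test_count(n_motifs: int, n_clusters: int,
                        exclude_constant: bool = True) -> int:
    """Number of Fisher tests: motifs x patterns x clusters."""
    n_patterns = len(NONCONSTANT_PATTERNS if exclude_constant else ALL_PATTERNS)
    return n_motifs * n_patterns * n_clusters
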