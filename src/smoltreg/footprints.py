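"""TF footprint scoring, global binding changes, and environment labels.

A bound transcription factor protects its motif from transposase insertion,
leaving a local dip in ATAC coverage inside an otherwise accessible peak.
The footprint score of a site in one week is the log2 ratio of mean
coverage in the flanking windows to mean coverage over the motif span
(replicates pooled per week); a site is called bound when the score
exceeds a fixed threshold. Genome-wide per-motif binding changes between
weeks are the log2 fold change of mean site scores, with significance from
a seeded paired permutation of week labels across sites.

Motifs are then classified by environment concordance: a motif whose
binding increases at week 25 relative to both freshwater weeks (1 and 19)
is 'sea' (and 'fresh' for a concordant decrease); one increasing at week
10 relative to both constant-light weeks (1 and 19) is 'short' (and
'long' for a decrease). The photoperiod and salinity labels are assigned
independently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import WEEKS
from .formats import CoverageTrack, GenomicInterval

#: (earlier, later) week pairs required by the environment classification
SALINITY_PAIRS = (("week_1", "week_25"), ("week_19", "week_25"))
PHOTOPERIOD_PAIRS = (("week_1", "week_10"), ("week_10", "week_19"))


# ---------------------------------------------------------------------------
# Site scoring
# ---------------------------------------------------------------------------

def score_sites(
    week_coverage: dict[str, CoverageTrack],
    motif_sites: list[GenomicInterval],
    peaks: list[GenomicInterval] | None = None,
    flank_bp: int = 20,
    gap_bp: int = 5,
    bound_threshold: float = 0.5,
    epsilon: float = 1.0,
) -> pd.DataFrame:
    """Score footprint dips at motif sites for every week.

    score = log2((flank_mean + eps) / (center_mean + eps)), center over the
    motif span, flank over [gap, gap+flank] on both sides. When ``peaks``
    is given, sites not contained in any peak are skipped (their count is
    available as ``df.attrs['n_skipped']``).

    Returns one row per retained site with columns motif_id, site, chrom,
    start, end, and per week ``score_{week}`` / ``bound_{week}``.
    """
    if peaks is not None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
        for v in by_chrom.values():
            v.sort()

        def in_peak(site: GenomicInterval) -> bool:
            for (a, b) in by_chrom.get(site.chrom, []):
                if a <= site.start and site.end <= b:
                    return True
            return False

    rows = []
    n_skipped = 0
    for site in motif_sites:
        if peaks is not None and not in_peak(site):
            n_skipped += 1
            continue
        motif_id = site.name.split("|")[0]
        row = {
            "motif_id": motif_id,
            "site": site.name,
            "chrom": site.chrom,
            "start": site.start,
            "end": site.end,
        }
        for week, track in week_coverage.items():
            center = track.mean(site.chrom, site.start, site.end)
            left = track.mean(
                site.chrom, site.start - gap_bp - flank_bp, site.start - gap_bp
            )
            right = track.mean(
                site.chrom, site.end + gap_bp, site.end + gap_bp + flank_bp
            )
            flank = 0.5 * (left + right)
            score = float(np.log2((flank + epsilon) / (center + epsilon)))
            row[f"score_{week}"] = score
            row[f"bound_{week}"] = score > bound_threshold
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = n_skipped
    return out


# ---------------------------------------------------------------------------
# Global binding change
# ---------------------------------------------------------------------------

def global_binding_change(
    site_scores: pd.DataFrame,
    week_a: str,
    week_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    min_sites: int = 10,
    epsilon: float = 0.1,
) -> pd.DataFrame:
    """Per-motif genome-wide binding change between two weeks.

    change = log2((mean score week_b + eps) / (mean score week_a + eps));
    positive = more binding at ``week_b``. Significance by a paired
    permutation: each site's two week labels are independently swapped and
    |change| recomputed, p = (1 + #more extreme) / (n_perm + 1). Motifs
    with fewer than ``min_sites`` sites are excluded (reported via
    ``attrs['excluded_motifs']``).
    """
    rng = np.random.default_rng(seed)
    rows = []
    excluded = []
    for motif_id, grp in site_scores.groupby("motif_id", sort=True):
        sa = grp[f"score_{week_a}"].to_numpy()
        sb = grp[f"score_{week_b}"].to_numpy()
        n = len(grp)
        if n < min_sites:
            excluded.append(motif_id)
            continue

        def change_of(a: np.ndarray, b: np.ndarray) -> float:
            return float(np.log2((b.mean() + epsilon) / (a.mean() + epsilon)))

        obs = change_of(sa, sb)
        flips = rng.random((n_perm, n)) < 0.5
        more_extreme = 0
        for f in flips:
            pa = np.where(f, sb, sa)
            pb = np.where(f, sa, sb)
            if abs(change_of(pa, pb)) >= abs(obs):
                more_extreme += 1
        p = (1 + more_extreme) / (n_perm + 1)
        rows.append(
            {
                "motif_id": motif_id,
                "week_a": week_a,
                "week_b": week_b,
                "n_sites": n,
                f"mean_score_{week_a}": float(sa.mean()),
                f"mean_score_{week_b}": float(sb.mean()),
                f"n_bound_{week_a}": int(grp[f"bound_{week_a}"].sum()),
                f"n_bound_{week_b}": int(grp[f"bound_{week_b}"].sum()),
                "change": obs,
                "PValue": p,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded_motifs"] = excluded
    return out


def binding_summary(
    site_scores: pd.DataFrame, min_sites: int = 10
) -> pd.DataFrame:
    """Per-motif per-week mean scores and bound counts (S6-table shape)."""
    rows = []
    for motif_id, grp in site_scores.groupby("motif_id", sort=True):
        if len(grp) < min_sites:
            continue
        row = {"motif_id": motif_id, "total_tfbs": len(grp)}
        for week in WEEKS:
            row[f"{week}_mean_score"] = float(grp[f"score_{week}"].mean())
            row[f"{week}_bound"] = int(grp[f"bound_{week}"].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def scale_bound_counts(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-motif z-score of bound-site counts across the 4 weeks.

    Constant rows (no change in bound counts) map to all zeros.
    """
    cols = [f"{w}_bound" for w in WEEKS]
    x = summary[cols].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    out = pd.DataFrame(z, columns=[f"{w}_scaled" for w in WEEKS])
    out.insert(0, "motif_id", summary["motif_id"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Environment classification
# ---------------------------------------------------------------------------

def _pair_change(row: pd.Series, wa: str, wb: str) -> float:
    """Change of the later week relative to the earlier, from a table that
    may carry either internal ``change``+week_a/week_b rows or published
    ``{wa}_{wb}_change`` columns (where positive = earlier week higher)."""
    col = f"{wa}_{wb}_change"
    if col in row.index:
        return -float(row[col])  # published convention: positive = earlier higher
    raise KeyError(col)


def classify_environment(
    change_table: pd.DataFrame,
    change_cutoff: float = 0.1,
    id_column: str | None = None,
) -> pd.DataFrame:
    """Label motifs by concordant environment response.

    ``change_table`` is a wide per-motif table with pairwise change columns
    named ``{week_a}_{week_b}_change`` (published convention: positive
    change = more binding in the first-named, earlier week). Rules, with
    cutoff c on the log2 scale:

    * sea:   binding at week 25 above both week 1 and week 19 by > c
    * fresh: below both by > c
    * short: binding at week 10 above both week 1 and week 19 by > c
    * long:  below both by > c

    A motif can carry one salinity and one photoperiod label; motifs
    meeting neither conjunction get 'none'. Missing change columns raise.
    """
    if change_cutoff <= 0:
        raise ValueError("change_cutoff must be > 0")
    if id_column is None:
        id_column = "name" if "name" in change_table.columns else "motif_id"
    needed = [f"{a}_{b}_change" for a, b in (*SALINITY_PAIRS, *PHOTOPERIOD_PAIRS)]
    missing = [c for c in needed if c not in change_table.columns]
    if missing:
        raise ValueError(f"missing pairwise change column(s): {missing}")
    rows = []
    for _, row in change_table.iterrows():
        # later-vs-earlier changes
        w25_vs_w1 = _pair_change(row, "week_1", "week_25")
        w25_vs_w19 = _pair_change(row, "week_19", "week_25")
        w10_vs_w1 = _pair_change(row, "week_1", "week_10")
        w10_vs_w19 = -_pair_change(row, "week_10", "week_19")
        c = change_cutoff
        if w25_vs_w1 > c and w25_vs_w19 > c:
            salinity = "sea"
        elif w25_vs_w1 < -c and w25_vs_w19 < -c:
            salinity = "fresh"
        else:
            salinity = "none"
        if w10_vs_w1 > c and w10_vs_w19 > c:
            photoperiod = "short"
        elif w10_vs_w1 < -c and w10_vs_w19 < -c:
            photoperiod = "long"
        else:
            photoperiod = "none"
        rows.append(
            {
                id_column: row[id_column],
                "salinity": salinity,
                "photoperiod": photoperiod,
            }
        )
    return pd.DataFrame(rows)


def change_table_from_results(results: list[pd.DataFrame],
                              id_column: str = "motif_id") -> pd.DataFrame:
    """Pivot :func:`global_binding_change` outputs into the wide published
    layout, negating so a positive ``{wa}_{wb}_change`` means more binding
    in the first-named (earlier) week."""
    wide = None
    for res in results:
        wa, wb = res["week_a"].iloc[0], res["week_b"].iloc[0]
        part = res[[id_column, "change", "PValue"]].rename(
            columns={
                "change": f"{wa}_{wb}_change",
                "PValue": f"{wa}_{wb}_pvalue",
            }
        )
        part[f"{wa}_{wb}_change"] = -part[f"{wa}_{wb}_change"]
        wide = part if wide is None else wide.merge(part, on=id_column)
    return wide


def s7_style_table(classes: pd.DataFrame, change_table: pd.DataFrame,
                   id_column: str | None = None) -> pd.DataFrame:
    """Long-format classification table mirroring the published layout:
    one row per labelled motif and classifying comparison."""
    if id_column is None:
        id_column = "name" if "name" in classes.columns else "motif_id"
    rows = []
    ct = change_table.set_index(id_column)
    for _, row in classes.iterrows():
        for category, pairs, label in (
            ("salinity", SALINITY_PAIRS, row["salinity"]),
            ("photoperiod", PHOTOPERIOD_PAIRS, row["photoperiod"]),
        ):
            if label == "none":
                continue
            for (wa, wb) in pairs:
                rows.append(
                    {
                        "name": row[id_column],
                        "comparison": f"{wa}_{wb}",
                        "change": float(ct.loc[row[id_column],
                                               f"{wa}_{wb}_change"]),
                        "pvalue": float(
                            ct.loc[row[id_column], f"{wa}_{wb}_pvalue"]
                        ) if f"{wa}_{wb}_pvalue" in ct.columns else np.nan,
                        "category": category,
                        "week_A": wa,
                        "week_B": wb,
                        "sig": label,
                    }
                )
    return pd.DataFrame(rows)
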