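"""RRBS differential methylation with a random-pair correlation null.

CpG calls are filtered per sample (>= 10 reads, below the sample's 99.9th
coverage percentile, on whitelisted chromosomes), merged into a per-week
consensus (present in at least three replicates of the week, intersected
across weeks), and tested for differential methylation across the four
weeks with a one-way F-test on logit-transformed methylation proportions.
A differentially methylated cytosine (DMC) requires both FDR < 0.05 and a
maximum pairwise difference in mean methylation above 25 percentage
points. DMCs are annotated with genomic context and their nearest gene,
and each DMC's per-week methylation profile is correlated with its gene's
per-week expression; the observed correlation distribution is compared
with that of randomly drawn DMC-gene pairs by a two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import statcore
from .chromatin import LocationAnnotator, link_positions_to_genes
from .expression import WEEKS
from .formats import CpGRecord, GenomeAnnotation


def _locus_key(rec: CpGRecord) -> str:
    return f"{rec.chrom}:{rec.position}"


# ---------------------------------------------------------------------------
# Filtering and consensus
# ---------------------------------------------------------------------------

def filter_cpgs(
    samples: dict[str, list[CpGRecord]],
    min_cov: int = 10,
    max_percentile: float = 99.9,
    chrom_whitelist: set[str] | None = None,
) -> dict[str, list[CpGRecord]]:
    """Per-sample coverage and chromosome filters.

    A locus is dropped for a sample when its coverage is below ``min_cov``
    or strictly above that sample's ``max_percentile`` coverage percentile,
    or when its chromosome is off the whitelist. Drop reasons are
    available per sample in the result's ``drop_reasons`` attribute
    mapping sample -> {locus: reason}.
    """
    if chrom_whitelist is not None and not chrom_whitelist:
        raise ValueError("empty chromosome whitelist")
    out: dict[str, list[CpGRecord]] = {}
    reasons: dict[str, dict[str, str]] = {}
    for sample, recs in samples.items():
        covs = np.array([r.coverage for r in recs])
        # "higher" order statistic: ties with the cutoff survive (strict >),
        # so a sample of identical coverages loses nothing
        cutoff = (
            np.percentile(covs, max_percentile, method="higher")
            if len(covs) else np.inf
        )
        kept = []
        why: dict[str, str] = {}
        for r in recs:
            if chrom_whitelist is not None and r.chrom not in chrom_whitelist:
                why[_locus_key(r)] = "off_whitelist"
            elif r.coverage < min_cov:
                why[_locus_key(r)] = "low_coverage"
            elif r.coverage > cutoff:
                why[_locus_key(r)] = "high_coverage_percentile"
            else:
                kept.append(r)
        out[sample] = kept
        reasons[sample] = why
    out_obj = _FilteredSamples(out)
    out_obj.drop_reasons = reasons
    return out_obj


class _FilteredSamples(dict):
    """dict subclass carrying per-sample drop reasons."""

    drop_reasons: dict[str, dict[str, str]]


def merge_replicates(
    filtered: dict[str, list[CpGRecord]],
    sample_weeks: dict[str, str],
    min_present: int = 3,
) -> pd.DataFrame:
    """Consensus CpG matrix across weeks.

    A locus enters a week's consensus when present (post-filter) in at
    least ``min_present`` replicates of that week; the per-week consensus
    sets are intersected across weeks. Returns a tidy DataFrame with one
    row per (locus, sample) of the consensus, columns chrom, position,
    locus, sample, week, count_m, count_u, score.
    """
    weeks = sorted(set(sample_weeks.values()))
    per_week_counts: dict[str, dict[str, int]] = {w: {} for w in weeks}
    for sample, recs in filtered.items():
        week = sample_weeks[sample]
        n_reps = sum(1 for s in sample_weeks.values() if s == week)
        if min_present > n_reps:
            raise ValueError(
                f"min_present={min_present} exceeds {n_reps} replicates of {week}"
            )
        for r in recs:
            key = _locus_key(r)
            per_week_counts[week][key] = per_week_counts[week].get(key, 0) + 1
    consensus = None
    for week in weeks:
        present = {k for k, n in per_week_counts[week].items() if n >= min_present}
        consensus = present if consensus is None else consensus & present
    rows = []
    for sample, recs in filtered.items():
        week = sample_weeks[sample]
        for r in recs:
            key = _locus_key(r)
            if key in consensus:
                rows.append(
                    {
                        "chrom": r.chrom,
                        "position": r.position,
                        "locus": key,
                        "sample": sample,
                        "week": week,
                        "count_m": r.count_m,
                        "count_u": r.count_u,
                        "score": r.score,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DMC calling
# ---------------------------------------------------------------------------

def call_dmcs(
    consensus: pd.DataFrame,
    alpha: float = 0.05,
    min_delta: float = 25.0,
) -> pd.DataFrame:
    """Differential methylation across weeks with an effect-size gate.

    Per CpG, a one-way F-test across weeks on logit-transformed
    proportions (0.5-read pseudocount on both methylated and unmethylated
    counts), BH-adjusted; a DMC additionally needs a maximum pairwise
    difference in per-week mean methylation above ``min_delta`` percentage
    points. Loci missing a whole week are excluded and counted in
    ``attrs['n_missing_week']``. Per-pair log2 fold changes of methylated
    counts are reported alongside.
    """
    weeks = sorted(consensus["week"].unique(), key=list(WEEKS).index)
    pivot_m = consensus.pivot_table(
        index="locus", columns="sample", values="count_m", aggfunc="first"
    )
    pivot_u = consensus.pivot_table(
        index="locus", columns="sample", values="count_u", aggfunc="first"
    )
    sample_week = consensus.drop_duplicates("sample").set_index("sample")["week"]
    sample_week = sample_week.loc[pivot_m.columns]
    # drop loci with an entire week missing
    present = ~pivot_m.isna()
    ok = pd.Series(True, index=pivot_m.index)
    for w in weeks:
        cols = sample_week.index[sample_week == w]
        ok &= present[cols].any(axis=1)
    n_missing_week = int((~ok).sum())
    pivot_m, pivot_u = pivot_m[ok], pivot_u[ok]
    m = pivot_m.to_numpy(dtype=float)
    u = pivot_u.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        logit = np.log2((m + 0.5) / (u + 0.5))
        score = 100.0 * m / (m + u)
    # F-test on logit values, ignoring per-locus missing samples
    groups = sample_week.to_numpy()
    f_stat = np.zeros(logit.shape[0])
    pvals = np.ones(logit.shape[0])
    for i in range(logit.shape[0]):
        vals = [
            logit[i, (groups == w) & ~np.isnan(logit[i])] for w in weeks
        ]
        flat = np.concatenate(vals)
        if np.ptp(flat) == 0:
            f_stat[i], pvals[i] = 0.0, 1.0
            continue
        with warnings.catch_warnings():
            # near-constant loci trigger scipy precision warnings; the
            # resulting tiny F / p~1 is the behaviour we want
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.f_oneway(*vals)
        f_stat[i] = float(res.statistic)
        pvals[i] = float(res.pvalue)
    out = pd.DataFrame(index=pivot_m.index)
    week_means = {}
    for w in weeks:
        cols = np.flatnonzero((groups == w))
        week_means[w] = np.nanmean(score[:, cols], axis=1)
        out[f"{w}_score"] = week_means[w]
    stacked = np.vstack([week_means[w] for w in weeks])
    out["max_abs_delta"] = stacked.max(axis=0) - stacked.min(axis=0)
    for i, wa in enumerate(weeks):
        for wb in weeks[i + 1:]:
            ca = np.flatnonzero(groups == wa)
            cb = np.flatnonzero(groups == wb)
            mean_m_a = np.nanmean(m[:, ca], axis=1)
            mean_m_b = np.nanmean(m[:, cb], axis=1)
            out[f"{wb}_{wa}_logFC"] = np.log2(
                (mean_m_b + 0.5) / (mean_m_a + 0.5)
            )
    out["logCPM"] = np.log2(np.nanmean(m, axis=1) + 0.5)
    out["F"] = f_stat
    out["PValue"] = pvals
    out["FDR"] = statcore.bh_adjust(pvals)
    out["is_dmc"] = (out["FDR"] < alpha) & (out["max_abs_delta"] > min_delta)
    locus_info = consensus.drop_duplicates("locus").set_index("locus")
    out.insert(0, "chr", locus_info.loc[out.index, "chrom"])
    out.insert(1, "locus_pos", locus_info.loc[out.index, "position"])
    out.index.name = "uniq_pos"
    out.attrs["n_missing_week"] = n_missing_week
    return out


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_dmcs(
    dmcs: pd.DataFrame,
    annotation: GenomeAnnotation,
    promoter_window: tuple[int, int] = (1500, 500),
) -> pd.DataFrame:
    """Genomic context and nearest gene per CpG.

    Positions are converted to internal 0-based coordinates before lookup.
    Adds columns genomic_feature, gene_id, tss, strand, distance.
    """
    annot = LocationAnnotator(annotation, promoter_window)
    out = dmcs.copy()
    pos0 = [(c, int(p) - 1) for c, p in zip(out["chr"], out["locus_pos"])]
    out["genomic_feature"] = [annot.classify(c, p) for c, p in pos0]
    links = link_positions_to_genes(pos0, annotation)
    out["gene_id"] = [l["gene_id"] for l in links]
    out["distance"] = [l["distance"] for l in links]
    tss, strand = [], []
    for g in out["gene_id"]:
        if g is None:
            tss.append(pd.NA)
            strand.append(pd.NA)
        else:
            tss.append(annotation[g].tss)
            strand.append(annotation[g].strand)
    out["tss"] = tss
    out["strand"] = strand
    return out


# ---------------------------------------------------------------------------
# DMC-expression correlation with simulated-pair null
# ---------------------------------------------------------------------------

@dataclass
class CorrelationNull:
    """Observed vs random-pair correlation comparison."""

    observed: pd.DataFrame
    null_r: np.ndarray
    ks_statistic: float
    ks_pvalue: float
    seed: int
    n_excluded: int


def correlate_dmc_expression(
    annotated_dmcs: pd.DataFrame,
    expression_week_means: pd.DataFrame,
    n_random_pairs: int = 1000,
    seed: int = 0,
    r_threshold: float = 0.95,
    alpha: float = 0.05,
) -> CorrelationNull:
    """Pearson correlation of DMC methylation vs nearest-gene expression.

    Both sides are the 4 per-week means (methylation score in percent,
    expression in CPM). A pair is significant when p < alpha and
    |r| > ``r_threshold`` (with n=4 that combination sits near the
    feasibility boundary; the thresholds are applied literally). The null
    draws ``n_random_pairs`` uniformly random (DMC, gene) pairs with the
    recorded seed and the observed r distribution is compared to the null
    r distribution by a two-sample KS test. Zero-variance series are
    excluded and counted.
    """
    rng = np.random.default_rng(seed)
    dmcs = annotated_dmcs[annotated_dmcs["is_dmc"]]
    score_cols = [f"{w}_score" for w in WEEKS]
    expr = expression_week_means[list(WEEKS)]
    rows = []
    n_excluded = 0
    meth_profiles = {}
    for locus, row in dmcs.iterrows():
        meth_profiles[locus] = row[score_cols].to_numpy(dtype=float)
    for locus, row in dmcs.iterrows():
        gene = row["gene_id"]
        if gene is None or gene not in expr.index:
            n_excluded += 1
            continue
        x = meth_profiles[locus]
        y = expr.loc[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_excluded += 1
            continue
        r, p = statcore.pearson_with_p(x, y)
        rows.append(
            {
                "cpg_id": locus,
                "gene_id": gene,
                "r": r,
                "PValue": p,
                "significant": (p < alpha) and (abs(r) > r_threshold),
            }
        )
    observed = pd.DataFrame(rows)
    loci = list(meth_profiles)
    genes = list(expr.index)
    null_r = []
    while len(null_r) < n_random_pairs:
        locus = loci[int(rng.integers(0, len(loci)))]
        gene = genes[int(rng.integers(0, len(genes)))]
        x = meth_profiles[locus]
        y = expr.loc[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        null_r.append(float(np.corrcoef(x, y)[0, 1]))
    null_r = np.array(null_r)
    if len(observed):
        ks = stats.ks_2samp(observed["r"].to_numpy(), null_r)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = np.nan, np.nan
    return CorrelationNull(observed, null_r, ks_stat, ks_p, seed, n_excluded)


def expression_week_means(matrix, group: str = "short") -> pd.DataFrame:
    """Per-week mean CPM per gene for the named group (columns = weeks)."""
    sub = matrix.subset(group=group)
    cpm = statcore.cpm_normalize(sub.counts, log=False)
    cols = {}
    for w in WEEKS:
        ids = sub.samples.loc[sub.samples["week"] == w, "sample_id"]
        cols[w] = cpm[list(ids)].mean(axis=1)
    return pd.DataFrame(cols)
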