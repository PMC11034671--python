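"""Differential chromatin accessibility and peak-to-gene linking.

Per-week ATAC peak sets are merged into a unified set (interval union,
book-ended intervals merge), read counts are integrated from per-sample
coverage, accessibility is tested between the three key periods of the
study (short photoperiod: weeks 1->10, smoltification: weeks 10->19,
seawater transfer: weeks 19->25), peaks are linked to the gene with the
nearest TSS, genomic context is annotated with promoter > exon > intron >
intergenic precedence, and the association between accessibility direction
and co-expression cluster membership is tested per cluster with Fisher's
exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import statcore
from .expression import WEEKS
from .formats import CoverageTrack, GenomeAnnotation, GenomicInterval

#: contrast name -> (earlier week, later week)
DA_CONTRASTS = {
    "w1_w10": ("week_1", "week_10"),
    "w10_w19": ("week_10", "week_19"),
    "w19_w25": ("week_19", "week_25"),
}


@dataclass
class UnifiedPeak:
    interval: GenomicInterval
    weeks: frozenset[str]

    @property
    def peak_id(self) -> str:
        return self.interval.name


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

def merge_peak_sets(
    per_week: dict[str, list[GenomicInterval]]
) -> list[UnifiedPeak]:
    """Union of per-week peak sets into a unified peak set.

    Overlapping or book-ended intervals (gap <= 0) merge. Each unified peak
    records which weeks contributed at least one interval, so per-week
    intersection counts are derivable. Peak ids are assigned in genomic
    order as ``upeak_#####``.
    """
    tagged: list[tuple[str, int, int, str]] = []
    for week, ivs in per_week.items():
        for iv in ivs:
            tagged.append((iv.chrom, iv.start, iv.end, week))
    tagged.sort()
    out: list[UnifiedPeak] = []
    cur = None  # [chrom, start, end, weeks]
    def flush():
        if cur is not None:
            out.append(
                UnifiedPeak(
                    GenomicInterval(cur[0], cur[1], cur[2],
                                    f"upeak_{len(out):05d}"),
                    frozenset(cur[3]),
                )
            )
    for chrom, start, end, week in tagged:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(week)
        else:
            flush()
            cur = [chrom, start, end, {week}]
    flush()
    return out


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_reads_in_peaks(
    peaks: list[UnifiedPeak], coverage: dict[str, CoverageTrack]
) -> pd.DataFrame:
    """Per-peak read-equivalent counts: sum of coverage x width per sample.

    Coverage chromosomes absent from the peak set trigger a warning (reads
    there are simply not counted).
    """
    peak_chroms = {p.interval.chrom for p in peaks}
    counts = {}
    for sample, track in coverage.items():
        extra = set(track.chroms) - peak_chroms
        if extra:
            warnings.warn(
                f"sample {sample}: coverage on chromosome(s) {sorted(extra)} "
                "with no peaks"
            )
        counts[sample] = [
            track.integral(p.interval.chrom, p.interval.start, p.interval.end)
            for p in peaks
        ]
    return pd.DataFrame(
        counts, index=pd.Index([p.peak_id for p in peaks], name="peak_id")
    )


# ---------------------------------------------------------------------------
# Differential accessibility
# ---------------------------------------------------------------------------

def test_da(
    counts: pd.DataFrame,
    sample_weeks: dict[str, str],
    contrast: str,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Welch test on log2 CPM of peak counts between the weeks of a contrast.

    logFC is later-week minus earlier-week, so direction ``up`` means more
    accessible at the later time point. Only FDR < alpha peaks carry a
    direction.
    """
    if contrast not in DA_CONTRASTS:
        raise ValueError(
            f"unknown contrast {contrast!r}; valid: {sorted(DA_CONTRASTS)}"
        )
    wa, wb = DA_CONTRASTS[contrast]
    samples_a = [s for s in counts.columns if sample_weeks.get(s) == wa]
    samples_b = [s for s in counts.columns if sample_weeks.get(s) == wb]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(f"contrast {contrast}: need >= 2 replicates per week")
    values = statcore.cpm_normalize(counts, log=True, pseudocount=pseudocount)
    res = statcore.pairwise_test(values, samples_b, samples_a)  # later - earlier
    res = res.rename(columns={"logCPM": "logCPM", "t": "t"})
    res["contrast"] = contrast
    res["significant"] = res["FDR"] < alpha
    res["direction"] = pd.NA
    res.loc[res["significant"] & (res["logFC"] > 0), "direction"] = "up"
    res.loc[res["significant"] & (res["logFC"] < 0), "direction"] = "down"
    return res


# ---------------------------------------------------------------------------
# Nearest-TSS linking
# ---------------------------------------------------------------------------

def _nearest_tss(
    annotation: GenomeAnnotation,
) -> dict[str, tuple[np.ndarray, list]]:
    """Per chromosome: sorted TSS positions with gene records.

    Ties at the same TSS position keep the lexicographically smallest
    gene_id first so the documented tie rule falls out of the ordering.
    """
    out = {}
    for chrom, genes in annotation.by_chrom().items():
        pairs = sorted(((g.tss, g.gene_id, g) for g in genes))
        out[chrom] = (np.array([p[0] for p in pairs]), [p[2] for p in pairs])
    return out


def link_positions_to_genes(
    positions: list[tuple[str, int]], annotation: GenomeAnnotation
) -> list[dict]:
    """Link genomic positions to the gene with the minimal |position - TSS|.

    Ties (two TSSs exactly equidistant) resolve to the lexicographically
    smallest gene_id. The signed distance is relative to the gene's strand:
    negative = upstream of the TSS. Positions on chromosomes with no genes
    are flagged unassigned (gene_id None).
    """
    index = _nearest_tss(annotation)
    links = []
    for chrom, pos in positions:
        if chrom not in index:
            links.append({"gene_id": None, "distance": None})
            continue
        tss_arr, genes = index[chrom]
        i = int(np.searchsorted(tss_arr, pos))
        best = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(genes):
                g = genes[j]
                d = abs(pos - g.tss)
                key = (d, g.gene_id)
                if best is None or key < best[0]:
                    best = (key, g)
        g = best[1]
        signed = pos - g.tss if g.strand == "+" else g.tss - pos
        links.append({"gene_id": g.gene_id, "distance": int(signed)})
    return links


def link_peaks_to_genes(
    peaks: list[UnifiedPeak], annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Nearest-TSS gene per peak, measured from the peak midpoint."""
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    pos = [(p.interval.chrom, p.interval.midpoint) for p in peaks]
    links = link_positions_to_genes(pos, annotation)
    return pd.DataFrame(
        {
            "peak_id": [p.peak_id for p in peaks],
            "gene_id": [l["gene_id"] for l in links],
            "distance": [l["distance"] for l in links],
        }
    )


# ---------------------------------------------------------------------------
# Genomic-context annotation
# ---------------------------------------------------------------------------

def annotate_location(
    chrom: str,
    position: int,
    annotation: GenomeAnnotation,
    promoter_window: tuple[int, int] = (1500, 500),
) -> str:
    """Classify a position: promoter > exon > intron > intergenic.

    The promoter window is strand-aware: ``upstream_bp`` before the TSS to
    ``downstream_bp`` after it, in the gene's reading direction.
    """
    return LocationAnnotator(annotation, promoter_window).classify(chrom, position)


class LocationAnnotator:
    """Vectorised-ish location classifier reusing per-chromosome indexes."""

    def __init__(self, annotation: GenomeAnnotation,
                 promoter_window: tuple[int, int] = (1500, 500)):
        self.by_chrom = annotation.by_chrom()
        self.promoter_window = promoter_window

    def classify(self, chrom: str, position: int) -> str:
        up, down = self.promoter_window
        genes = self.by_chrom.get(chrom, [])
        feature = "intergenic"
        for g in genes:
            if g.strand == "+":
                in_prom = g.tss - up <= position < g.tss + down
            else:
                in_prom = g.tss - down < position <= g.tss + up
            if in_prom:
                return "promoter"
            if g.start <= position < g.end and feature == "intergenic":
                feature = "intron"
                for (a, b) in g.exons:
                    if a <= position < b:
                        feature = "exon"
                        break
        return feature


# ---------------------------------------------------------------------------
# DA x co-expression-cluster association
# ---------------------------------------------------------------------------

def da_deg_association(
    da_results: pd.DataFrame,
    links: pd.DataFrame,
    cluster_assignments: pd.DataFrame,
) -> pd.DataFrame:
    """Per-cluster Fisher association between DA direction and cluster.

    For one contrast's DA peaks linked to clustered DEGs, each cluster c is
    tested with the 2x2 table
    [up-peaks linked to cluster-c DEGs, up-peaks linked to other-cluster
    DEGs] x [down same]. Clusters with zero linked peaks are emitted with
    p = 1 and a flag rather than dropped.
    """
    gene_cluster = (
        cluster_assignments.dropna(subset=["cluster"])
        .set_index("gene_id")["cluster"]
        .astype(int)
    )
    sig = da_results[da_results["significant"]].copy()
    sig = sig.join(links.set_index("peak_id"), how="left")
    sig["cluster"] = sig["gene_id"].map(gene_cluster)
    sig = sig.dropna(subset=["cluster"])
    sig["cluster"] = sig["cluster"].astype(int)
    n_up = int((sig["direction"] == "up").sum())
    n_down = int((sig["direction"] == "down").sum())
    rows = []
    clusters = sorted(gene_cluster.unique())
    contrast = (
        da_results["contrast"].iloc[0] if len(da_results) else None
    )
    for c in clusters:
        a = int(((sig["direction"] == "up") & (sig["cluster"] == c)).sum())
        b = n_up - a
        cc = int(((sig["direction"] == "down") & (sig["cluster"] == c)).sum())
        d = n_down - cc
        if a + cc == 0:
            rows.append(
                {"contrast": contrast, "cluster": c, "a": a, "b": b, "c": cc,
                 "d": d, "odds_ratio": np.nan, "PValue": 1.0,
                 "no_linked_degs": True}
            )
            continue
        res = statcore.fisher_exact_2x2([[a, b], [cc, d]])
        rows.append(
            {"contrast": contrast, "cluster": c, "a": a, "b": b, "c": cc,
             "d": d, "odds_ratio": res.odds_ratio, "PValue": res.p_two_sided,
             "no_linked_degs": False}
        )
    return pd.DataFrame(rows)


def tss_distance_histogram(
    links: pd.DataFrame, max_abs_distance: int = 10_000, bin_width: int = 500
) -> pd.DataFrame:
    """Counts of peak-TSS distances in signed bins (distance-profile report)."""
    d = links["distance"].dropna().astype(int)
    d = d[d.abs() <= max_abs_distance]
    bins = np.arange(-max_abs_distance, max_abs_distance + bin_width, bin_width)
    hist, edges = np.histogram(d, bins=bins)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": hist}
    )
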