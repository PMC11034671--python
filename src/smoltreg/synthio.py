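"""Synthetic multi-omics data with machine-readable planted ground truth.

Everything downstream of read alignment in the smoltification study design
is emulated here at desk scale: a coordinate-skeleton genome annotation,
negative-binomial expression counts with planted co-expression archetypes,
ATAC peaks and piecewise-constant coverage with planted accessibility
changes and motif-site footprint dips, CpG methylation calls with planted
differential methylation, and a stand-in for the published genome-wide
TF-binding-change table.

The design mirrors the study: four sampling weeks (1, 10, 19, 25), a short
winter-like photoperiod between weeks 1 and 10, seawater transfer between
weeks 19 and 25, with a constant-light group and a freshwater control
group. Every planted effect is recorded in a :class:`GroundTruth` object
that downstream recovery metrics are computed against.

All randomness flows through one integer seed; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import WEEKS, GROUPS, ExpressionMatrix
from .formats import (
    CoverageTrack,
    CpGRecord,
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    write_bed,
    write_bedgraph,
    write_bismark_coverage,
    write_counts_tsv,
    write_gtf_lite,
)

#: Co-expression archetypes: per-week mean multipliers for the short
#: photoperiod group. The seven qualitative trends: (1) strong increase in
#: seawater, (2) sharp smolt peak at week 19, (3) rise through
#: smoltification staying elevated, (4) sharp short-photoperiod peak at
#: week 10, (5) week-10 peak with gradual decline, (6) drop after the short
#: photoperiod and in smolts with recovery at sea, (7) steady decrease from
#: parr onwards. Values are chosen so the gene-scaled profiles are mutually
#: distinguishable (max pairwise correlation ~0.74 on the log scale).
ARCHETYPE_PROFILES: dict[int, tuple[float, float, float, float]] = {
    1: (1, 1, 1, 8),
    2: (1, 1, 8, 2),
    3: (1, 5, 8, 5),
    4: (1, 8, 1, 1),
    5: (4, 8, 5, 2),
    6: (8, 1, 1, 6),
    7: (8, 4, 2, 1),
}

#: Week pairs carrying the environment classification (first = earlier).
CLASSIFYING_PAIRS = [
    ("week_1", "week_10"),
    ("week_10", "week_19"),
    ("week_1", "week_25"),
    ("week_19", "week_25"),
]
ALL_WEEK_PAIRS = [
    ("week_1", "week_10"),
    ("week_1", "week_19"),
    ("week_1", "week_25"),
    ("week_10", "week_19"),
    ("week_10", "week_25"),
    ("week_19", "week_25"),
]


@dataclass
class SimDesign:
    """Dimensions and seed of one synthetic study."""

    n_chroms: int = 2
    chrom_len: int = 1_000_000
    n_genes: int = 200
    weeks: tuple[str, ...] = WEEKS
    replicates_per_week: int = 4
    atac_replicates: int = 4
    groups: tuple[str, ...] = GROUPS
    seed: int = 0

    def __post_init__(self):
        if len(self.weeks) != 4:
            raise ValueError("design requires exactly 4 weeks")
        if self.replicates_per_week < 2:
            raise ValueError("replicates_per_week must be >= 2")
        if self.atac_replicates < 2:
            raise ValueError("atac_replicates must be >= 2")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class GroundTruth:
    """Machine-readable record of every planted effect.

    Populated incrementally by the generators; recovery metrics downstream
    are computed against this record, never against generator intent.
    """

    #: gene_id -> archetype cluster (1..7)
    gene_clusters: dict[str, int] = field(default_factory=dict)
    #: gene_id -> +1/-1 (sign of short-minus-long logFC at week 10)
    photoperiod_genes: dict[str, int] = field(default_factory=dict)
    #: gene_id -> +1/-1 (sign of sea-minus-fresh logFC at week 25)
    salinity_genes: dict[str, int] = field(default_factory=dict)
    #: peak_id -> {"contrast": "week_A:week_B", "fold": f, "direction": up/down}
    da_peaks: dict[str, dict] = field(default_factory=dict)
    #: motif_id -> {"pattern": "0010", "coupled_cluster": int | None}
    motif_patterns: dict[str, dict] = field(default_factory=dict)
    #: site name -> {"motif_id": m, "pattern": p, "gene_id": nearest gene}
    site_patterns: dict[str, dict] = field(default_factory=dict)
    #: cpg id -> {"delta": points, "weeks": [...], "direction": +1/-1}
    dmcs: dict[str, dict] = field(default_factory=dict)
    #: motif name -> {"photoperiod": short/long/none, "salinity": sea/fresh/none}
    binding_classes: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(design: SimDesign) -> GenomeAnnotation:
    """Pack non-overlapping gene bodies with exon/intron structure.

    Genes are laid out chromosome by chromosome with intergenic gaps large
    enough to host promoter peaks. Raises if the chromosomes cannot hold
    the requested genes, naming the required length.
    """
    rng = np.random.default_rng(design.seed)
    chroms = design.chrom_names()
    per_chrom = [design.n_genes // design.n_chroms] * design.n_chroms
    for i in range(design.n_genes % design.n_chroms):
        per_chrom[i] += 1
    max_footprint = 5000 + 3000  # max gene body + min gap
    need = max(per_chrom, default=0) * max_footprint + 2000
    if design.n_genes and need > design.chrom_len:
        raise ValueError(
            f"chrom_len {design.chrom_len} too short for "
            f"{max(per_chrom)} genes per chromosome; need >= {need} bp"
        )
    genes: list[Gene] = []
    gidx = 0
    for chrom, n in zip(chroms, per_chrom):
        pos = 2000
        for _ in range(n):
            body = int(rng.integers(2000, 5001))
            gap = int(rng.integers(3000, 4001))
            start, end = pos, pos + body
            strand = "+" if rng.random() < 0.5 else "-"
            # 2-4 exons alternating with introns inside the body
            n_exons = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(
                np.arange(start + 100, end - 100, 50), size=2 * n_exons - 2,
                replace=False,
            ))
            bounds = [start, *cuts.tolist(), end]
            exons = [
                (int(bounds[i]), int(bounds[i + 1]))
                for i in range(0, len(bounds) - 1, 2)
            ]
            genes.append(
                Gene(
                    gene_id=f"g{gidx:05d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                )
            )
            gidx += 1
            pos = end + gap
    return GenomeAnnotation(genes)


# ---------------------------------------------------------------------------
# Ground-truth planting for expression
# ---------------------------------------------------------------------------

def plant_expression_truth(
    design: SimDesign,
    annotation: GenomeAnnotation,
    truth: GroundTruth | None = None,
    genes_per_cluster: int | None = None,
    n_photoperiod: int | None = None,
    n_salinity: int | None = None,
) -> GroundTruth:
    """Assign archetype clusters and contrast-responsive genes.

    Cluster genes, photoperiod-responsive genes, and salinity-responsive
    genes are disjoint sets drawn deterministically from the annotation.
    Defaults scale with the design: 10% of genes per archetype cluster
    (capped at 20), with smaller photoperiod- and salinity-responsive sets.
    """
    truth = truth or GroundTruth()
    rng = np.random.default_rng(design.seed + 1)
    gene_ids = [g.gene_id for g in annotation.genes]
    if genes_per_cluster is None:
        genes_per_cluster = min(20, len(gene_ids) // 10)
    if n_photoperiod is None:
        n_photoperiod = min(8, len(gene_ids) // 25)
    if n_salinity is None:
        n_salinity = min(12, len(gene_ids) // 16)
    need = genes_per_cluster * len(ARCHETYPE_PROFILES) + n_photoperiod + n_salinity
    if need > len(gene_ids):
        raise ValueError(f"need {need} genes to plant, have {len(gene_ids)}")
    chosen = rng.choice(gene_ids, size=need, replace=False)
    i = 0
    for cluster in ARCHETYPE_PROFILES:
        for g in chosen[i : i + genes_per_cluster]:
            truth.gene_clusters[str(g)] = cluster
        i += genes_per_cluster
    for g in chosen[i : i + n_photoperiod]:
        truth.photoperiod_genes[str(g)] = int(rng.choice([-1, 1]))
    i += n_photoperiod
    for g in chosen[i : i + n_salinity]:
        truth.salinity_genes[str(g)] = int(rng.choice([-1, 1]))
    return truth


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative binomial with mean/dispersion parameterisation."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_expression(
    design: SimDesign,
    truth: GroundTruth,
    dispersion: float = 0.1,
    base_mean: float = 100.0,
    contrast_fold: float = 4.0,
    annotation: GenomeAnnotation | None = None,
    gene_ids: list[str] | None = None,
) -> ExpressionMatrix:
    """Negative-binomial counts over all groups, weeks and replicates.

    Planted cluster genes follow their archetype mean profile: the
    developmental program is shared by all groups, except that the
    freshwater control (never transferred to sea) holds its week-19 level
    at week 25. Photoperiod-responsive genes differ between short and long
    groups at week 10 only; salinity-responsive genes differ between the
    seawater (short) group and the freshwater control at week 25 only.
    Library sizes vary +-20% between samples.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if gene_ids is None:
        if annotation is None:
            raise ValueError("need annotation or explicit gene_ids")
        gene_ids = [g.gene_id for g in annotation.genes]
    rng = np.random.default_rng(design.seed + 2)
    base = base_mean * rng.lognormal(mean=0.0, sigma=1.0, size=len(gene_ids))
    sample_rows = []
    for group in design.groups:
        for week in design.weeks:
            for rep in range(1, design.replicates_per_week + 1):
                sample_rows.append(
                    {
                        "sample_id": f"{group}_{week}_r{rep}",
                        "week": week,
                        "group": group,
                        "replicate": rep,
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample_id", drop=False)
    lib = rng.uniform(0.8, 1.2, size=len(samples))
    widx = {w: i for i, w in enumerate(design.weeks)}
    cols = {}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for s, (sid, row) in enumerate(samples.iterrows()):
        mu = base.copy()
        week = row["week"]
        if row["group"] == "fresh_control" and week == "week_25":
            week = "week_19"  # control never entered seawater
        for g, cluster in truth.gene_clusters.items():
            mu[gene_pos[g]] *= ARCHETYPE_PROFILES[cluster][widx[week]]
        if row["group"] == "short":
            if row["week"] == "week_10":
                for g, sign in truth.photoperiod_genes.items():
                    mu[gene_pos[g]] *= contrast_fold ** sign
            if row["week"] == "week_25":
                for g, sign in truth.salinity_genes.items():
                    mu[gene_pos[g]] *= contrast_fold ** sign
        cols[sid] = _nb_draw(rng, mu * lib[s], dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionMatrix(counts, samples)


# ---------------------------------------------------------------------------
# ATAC: peaks, coverage, motif-site footprints
# ---------------------------------------------------------------------------

@dataclass
class AtacSim:
    """Bundle of everything the ATAC generator produces."""

    peaks_per_week: dict[str, list[GenomicInterval]]
    sample_coverage: dict[str, CoverageTrack]  # "{week}_r{rep}" -> track
    week_coverage: dict[str, CoverageTrack]  # replicates pooled
    motif_sites: list[GenomicInterval]  # name = "{motif_id}|{site_id}"
    sample_weeks: dict[str, str]  # sample name -> week


def simulate_atac(
    design: SimDesign,
    truth: GroundTruth,
    annotation: GenomeAnnotation,
    peak_height: float = 20.0,
    replicate_cv: float = 0.1,
    dip_fraction: float = 0.3,
    da_fold: float = 2.0,
    n_da_per_contrast: int = 12,
    n_motifs: int = 12,
    sites_per_motif: int = 40,
    week_specific_fraction: float = 0.1,
    n_coupled_motifs: int = 3,
    da_coupled_cluster: int | None = None,
    da_coupled_contrast: tuple[str, str] = ("week_10", "week_19"),
) -> AtacSim:
    """Peaks, per-sample coverage and motif sites with planted effects.

    Peaks are flat elevated plateaus: one promoter peak per gene plus
    intergenic peaks. Accessibility changes are planted by scaling a peak's
    plateau from the later week of a contrast onward (fold ``da_fold`` up
    or down). TF occupancy is planted as footprint dips: for weeks where a
    site's binding-pattern digit is 1, coverage over the motif span drops
    to ``dip_fraction`` of the plateau. Some motifs are "coupled": their
    bound sites sit in promoter peaks of genes from one expression cluster,
    planting the binding-pattern x cluster association tested downstream.
    """
    rng = np.random.default_rng(design.seed + 3)
    weeks = list(design.weeks)

    # ---- peak geometry ----
    peaks: list[dict] = []
    for g in annotation.genes:
        half = int(rng.integers(200, 351))
        start = max(0, g.tss - half)
        end = min(design.chrom_len, g.tss + half)
        peaks.append(dict(chrom=g.chrom, start=start, end=end, gene_id=g.gene_id))
    by_chrom = annotation.by_chrom()
    for chrom, genes in by_chrom.items():
        for g1, g2 in zip(genes[:-1], genes[1:]):
            gap_start, gap_end = g1.end, g2.start
            if gap_end - gap_start >= 2400 and rng.random() < 0.5:
                mid = (gap_start + gap_end) // 2
                peaks.append(
                    dict(chrom=chrom, start=mid - 200, end=mid + 200, gene_id=None)
                )
    peaks.sort(key=lambda p: (p["chrom"], p["start"]))
    for i, p in enumerate(peaks):
        p["peak_id"] = f"peak_{i:05d}"

    # ---- week membership ----
    for p in peaks:
        if rng.random() < week_specific_fraction:
            p["weeks"] = [weeks[int(rng.integers(0, 4))]]
        else:
            p["weeks"] = list(weeks)

    # ---- DA planting: peaks present in all weeks, not promoter peaks of
    # planted cluster genes (keeps the DA and footprint signals separable) ----
    contrasts = [(weeks[0], weeks[1]), (weeks[1], weeks[2]), (weeks[2], weeks[3])]
    candidates = [
        p for p in peaks
        if len(p["weeks"]) == 4 and p["gene_id"] not in truth.gene_clusters
    ]
    rng.shuffle(candidates)
    # optional coupling: up-peaks of one contrast land on promoter peaks of
    # one expression cluster's genes, planting the accessibility-direction x
    # cluster association tested downstream
    coupled_pool = []
    if da_coupled_cluster is not None:
        coupled_genes = {
            g for g, c in truth.gene_clusters.items() if c == da_coupled_cluster
        }
        coupled_pool = [
            p for p in peaks
            if len(p["weeks"]) == 4 and p["gene_id"] in coupled_genes
        ]
    ci = 0
    for (wa, wb) in contrasts:
        for direction in ("up", "down"):
            coupled_here = (
                da_coupled_cluster is not None
                and (wa, wb) == da_coupled_contrast
                and direction == "up"
            )
            for j in range(n_da_per_contrast):
                if coupled_here and j < len(coupled_pool):
                    p = coupled_pool[j]
                else:
                    if ci >= len(candidates):
                        raise ValueError("not enough peaks to plant DA effects")
                    p = candidates[ci]
                    ci += 1
                p["da"] = (wa, wb, direction)
                truth.da_peaks[p["peak_id"]] = {
                    "contrast": f"{wa}:{wb}",
                    "fold": da_fold,
                    "direction": direction,
                }

    # ---- motif catalogue and site placement ----
    motif_widths = {
        f"MOTIF{m:03d}": int(rng.integers(8, 17)) for m in range(n_motifs)
    }
    cluster_ids = sorted(set(truth.gene_clusters.values()))
    # sites only on peaks present in every week, so footprint scores are
    # defined at all four time points
    promoter_by_gene = {
        p["gene_id"]: p for p in peaks
        if p["gene_id"] and len(p["weeks"]) == 4
    }
    noncoupled_pool = [p for p in peaks if "da" not in p and len(p["weeks"]) == 4]
    patterns_noncst = [
        f"{i:04b}" for i in range(16) if i not in (0, 15)
    ]
    sites: list[dict] = []
    slot_next: dict[str, int] = {}

    def place_site(peak: dict, motif_id: str, pattern: str) -> dict | None:
        width = motif_widths[motif_id]
        slot = slot_next.get(peak["peak_id"], 0)
        pos = peak["start"] + 60 + slot * 80
        if pos + width > peak["end"] - 60:
            return None
        if width > peak["end"] - peak["start"]:
            raise ValueError(
                f"motif {motif_id} wider than host peak {peak['peak_id']}"
            )
        slot_next[peak["peak_id"]] = slot + 1
        site = dict(
            chrom=peak["chrom"], start=pos, end=pos + width,
            motif_id=motif_id, pattern=pattern, peak=peak,
            name=f"{motif_id}|s{len(sites):05d}",
        )
        sites.append(site)
        return site

    def fill_sites(motif_id: str, target: int, pattern_fn) -> int:
        """Place up to ``target`` sites on random all-week peaks."""
        placed, attempts = 0, 0
        while placed < target and noncoupled_pool and attempts < 20 * target:
            attempts += 1
            peak = noncoupled_pool[int(rng.integers(0, len(noncoupled_pool)))]
            if place_site(peak, motif_id, pattern_fn()):
                placed += 1
        return placed

    motif_ids = sorted(motif_widths)
    for mi, motif_id in enumerate(motif_ids):
        if mi < n_coupled_motifs and cluster_ids:
            cluster = cluster_ids[mi % len(cluster_ids)]
            pattern = patterns_noncst[int(rng.integers(0, len(patterns_noncst)))]
            truth.motif_patterns[motif_id] = {
                "pattern": pattern, "coupled_cluster": cluster,
            }
            cluster_genes = sorted(
                g for g, c in truth.gene_clusters.items() if c == cluster
            )
            placed = 0
            for g in cluster_genes:
                if placed >= sites_per_motif // 2:
                    break
                peak = promoter_by_gene.get(g)
                if peak is not None and place_site(peak, motif_id, pattern):
                    placed += 1
            # background sites with per-site random patterns
            fill_sites(motif_id, sites_per_motif - placed,
                       lambda: f"{int(rng.integers(0, 16)):04b}")
        elif mi < n_coupled_motifs + (n_motifs - n_coupled_motifs) // 2:
            # planted uniform-pattern motif (drives global binding change)
            pattern = patterns_noncst[int(rng.integers(0, len(patterns_noncst)))]
            truth.motif_patterns[motif_id] = {
                "pattern": pattern, "coupled_cluster": None,
            }
            fill_sites(motif_id, sites_per_motif, lambda: pattern)
        else:
            # null motif: never bound
            truth.motif_patterns[motif_id] = {
                "pattern": "0000", "coupled_cluster": None,
            }
            fill_sites(motif_id, sites_per_motif, lambda: "0000")

    for site in sites:
        truth.site_patterns[site["name"]] = {
            "motif_id": site["motif_id"],
            "pattern": site["pattern"],
            "gene_id": site["peak"]["gene_id"],
        }

    # ---- coverage construction ----
    widx = {w: i for i, w in enumerate(weeks)}
    sites_by_peak: dict[str, list[dict]] = {}
    for site in sites:
        sites_by_peak.setdefault(site["peak"]["peak_id"], []).append(site)

    def peak_week_mult(p: dict, week: str) -> float:
        if "da" not in p:
            return 1.0
        wa, wb, direction = p["da"]
        if widx[week] >= widx[wb]:
            return da_fold if direction == "up" else 1.0 / da_fold
        return 1.0

    base_height = {
        p["peak_id"]: peak_height * rng.lognormal(0.0, 0.25) for p in peaks
    }
    sample_coverage: dict[str, CoverageTrack] = {}
    week_coverage: dict[str, CoverageTrack] = {}
    sample_weeks: dict[str, str] = {}
    for week in weeks:
        rep_heights = {
            p["peak_id"]: [
                base_height[p["peak_id"]]
                * peak_week_mult(p, week)
                * rng.gamma(1.0 / replicate_cv**2, replicate_cv**2)
                for _ in range(design.atac_replicates)
            ]
            for p in peaks
            if week in p["weeks"]
        }
        rep_segments: list[list[tuple[str, int, int, float]]] = [
            [] for _ in range(design.atac_replicates)
        ]
        pooled_segments: list[tuple[str, int, int, float]] = []
        for p in peaks:
            if week not in p["weeks"]:
                continue
            dips = sorted(
                (s["start"], s["end"])
                for s in sites_by_peak.get(p["peak_id"], [])
                if s["pattern"][widx[week]] == "1"
            )
            bounds = [p["start"]]
            flags = []
            for (a, b) in dips:
                bounds.extend([a, b])
            bounds.append(p["end"])
            heights = rep_heights[p["peak_id"]]
            for j in range(len(bounds) - 1):
                a, b = bounds[j], bounds[j + 1]
                if a >= b:
                    continue
                frac = dip_fraction if j % 2 == 1 else 1.0
                for r in range(design.atac_replicates):
                    rep_segments[r].append((p["chrom"], a, b, heights[r] * frac))
                pooled_segments.append((p["chrom"], a, b, sum(heights) * frac))
        for r in range(design.atac_replicates):
            name = f"{week}_r{r + 1}"
            sample_coverage[name] = CoverageTrack(rep_segments[r])
            sample_weeks[name] = week
        week_coverage[week] = CoverageTrack(pooled_segments)

    peaks_per_week = {
        week: [
            GenomicInterval(p["chrom"], p["start"], p["end"], p["peak_id"])
            for p in peaks
            if week in p["weeks"]
        ]
        for week in weeks
    }
    motif_sites = [
        GenomicInterval(s["chrom"], s["start"], s["end"], s["name"])
        for s in sites
    ]
    return AtacSim(peaks_per_week, sample_coverage, week_coverage,
                   motif_sites, sample_weeks)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    design: SimDesign,
    truth: GroundTruth,
    n_cpgs: int = 2000,
    n_dmcs: int = 100,
    delta: float = 40.0,
    affected_weeks: tuple[str, ...] = ("week_19", "week_25"),
    mean_coverage: float = 30.0,
    coverage_sigma: float = 0.5,
) -> dict[str, list[CpGRecord]]:
    """Per-sample Bismark-style CpG calls with planted DMCs.

    Each CpG has a base methylation proportion; planted DMCs shift it by
    ``delta`` percentage points in the affected weeks (direction chosen
    away from the nearer boundary; deltas that would leave [0, 1] are
    clipped with a warning). Coverage is log-normal around
    ``mean_coverage`` so most sites pass a >=10-read filter while a heavy
    tail exercises the percentile filter.

    Returns {"{week}_r{rep}": [CpGRecord, ...]}.
    """
    if not (0 < delta <= 100):
        raise ValueError("delta must be in (0, 100] percentage points")
    rng = np.random.default_rng(design.seed + 4)
    chroms = design.chrom_names()
    positions = sorted(
        {
            (chroms[int(rng.integers(0, design.n_chroms))],
             int(rng.integers(1, design.chrom_len)))
            for _ in range(int(n_cpgs * 1.1))
        }
    )[:n_cpgs]
    base_p = 0.1 + 0.8 * rng.beta(2.0, 2.0, size=len(positions))
    dmc_idx = rng.choice(len(positions), size=n_dmcs, replace=False)
    direction = np.zeros(len(positions), dtype=int)
    for i in dmc_idx:
        d = 1 if base_p[i] <= 0.5 else -1
        if not (0.0 <= base_p[i] + d * delta / 100 <= 1.0):
            warnings.warn(
                f"planted delta clipped at CpG index {i} "
                f"(base {base_p[i]:.2f}, delta {delta})"
            )
        direction[i] = d
        chrom, pos = positions[i]
        truth.dmcs[f"{chrom}:{pos}"] = {
            "delta": float(delta),
            "weeks": list(affected_weeks),
            "direction": d,
        }
    out: dict[str, list[CpGRecord]] = {}
    for week in design.weeks:
        shifted = week in affected_weeks
        for rep in range(1, design.replicates_per_week + 1):
            recs = []
            cov = np.maximum(
                1,
                rng.lognormal(np.log(mean_coverage), coverage_sigma,
                              size=len(positions)).astype(int),
            )
            p = base_p.copy()
            if shifted:
                p = np.clip(p + direction * delta / 100.0, 0.0, 1.0)
            m = rng.binomial(cov, p)
            for (chrom, pos), c, mm in zip(positions, cov, m):
                recs.append(CpGRecord(chrom, pos, int(mm), int(c - mm)))
            out[f"{week}_r{rep}"] = recs
    return out


# ---------------------------------------------------------------------------
# Synthetic stand-in for the published global TF-binding-change table
# ---------------------------------------------------------------------------

def simulate_binding_change_table(
    seed: int,
    n_short: int = 20,
    n_long: int = 13,
    n_sea: int = 5,
    n_fresh: int = 30,
    n_none: int = 92,
    cutoff: float = 0.1,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """SYNTHETIC stand-in for the study's global TF-binding-change table.

    The published table (TOBIAS output: per-motif mean binding scores per
    week and pairwise change/p-value columns) is not deposited with the
    text, so this generator builds a table of the same shape with the
    published memberships planted as ground truth: by default 33
    photoperiod-associated motifs (20 short + 13 long) and 35
    salinity-associated motifs (30 with less binding at sea, 5 with more).

    Per-week mean scores are generated so the implied pairwise log2 changes
    satisfy (or stay below) the classification cutoff, then the change
    columns are computed from the scores. The change sign convention
    matches the published legend: positive change = more binding in the
    first-named (earlier) week. Null motifs are drawn strictly sub-cutoff
    on the four classifying pairs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    specs = (
        [("short", None)] * n_short
        + [("long", None)] * n_long
        + [(None, "sea")] * n_sea
        + [(None, "fresh")] * n_fresh
        + [(None, None)] * n_none
    )
    for i, (photo, salin) in enumerate(specs):
        name = f"TF{i:03d}"
        base = rng.uniform(0.15, 0.6)
        labelled = photo is not None or salin is not None
        # labelled motifs get tight jitter so effect - jitter clears the
        # cutoff; null motifs roam wider but stay strictly sub-cutoff
        amp = 0.02 if labelled else 0.045
        jitter = lambda: base * 2 ** rng.uniform(-amp, amp)
        scores = {w: jitter() for w in WEEKS}
        eff = lambda: rng.uniform(cutoff + 2 * amp + 0.01, 0.5)
        if photo == "short":
            scores["week_10"] = base * 2 ** eff()
        elif photo == "long":
            scores["week_10"] = base * 2 ** -eff()
        if salin == "sea":
            scores["week_25"] = base * 2 ** eff()
        elif salin == "fresh":
            scores["week_25"] = base * 2 ** -eff()
        total = int(rng.integers(500, 5000))
        row = {
            "output_prefix": f"{name}_MA{i:04d}.1",
            "name": name,
            "motif_id": f"MA{i:04d}.1",
            "cluster": f"C{int(rng.integers(1, 20))}",
            "total_tfbs": total,
        }
        for w in WEEKS:
            row[f"{w}_mean_score"] = round(scores[w], 6)
        for w in WEEKS:
            row[f"{w}_bound"] = int(total * min(1.0, scores[w]))
        for (wa, wb) in ALL_WEEK_PAIRS:
            change = float(np.log2(scores[wa] / scores[wb]))
            planted = (
                ((wa, wb) in CLASSIFYING_PAIRS)
                and (photo is not None or salin is not None)
                and abs(change) > cutoff
            )
            row[f"{wa}_{wb}_change"] = round(change, 6)
            row[f"{wa}_{wb}_pvalue"] = (
                float(10 ** -rng.uniform(3, 8)) if planted
                else float(rng.uniform(0.05, 1.0))
            )
        rows.append(row)
        if truth is not None:
            truth.binding_classes[name] = {
                "photoperiod": photo or "none",
                "salinity": salin or "none",
            }
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# One-call simulation to disk
# ---------------------------------------------------------------------------

def simulate_all(design: SimDesign, outdir, **params) -> GroundTruth:
    """Run every generator and write the study to ``outdir``.

    Writes: annotation (GTF-lite + TSS TSV), counts TSV + sample sheet,
    per-week peak BEDs, per-sample and pooled bedGraph coverage, motif-site
    BED, per-sample Bismark coverage files, the synthetic binding-change
    table, and ground_truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth()
    annotation = simulate_annotation(design)
    write_gtf_lite(annotation, outdir / "annotation.gtf")
    annotation.tss_table().to_csv(outdir / "tss.tsv", sep="\t", index=False)
    plant_expression_truth(design, annotation, truth,
                           **params.get("truth", {}))
    mat = simulate_expression(design, truth, annotation=annotation,
                              **params.get("expression", {}))
    write_counts_tsv(mat.counts, outdir / "counts.tsv")
    mat.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    atac_params = dict(params.get("atac", {}))
    if design.n_genes == 0:
        atac_params.setdefault("n_da_per_contrast", 0)
        atac_params.setdefault("n_motifs", 0)
    atac = simulate_atac(design, truth, annotation, **atac_params)
    for week, peaks in atac.peaks_per_week.items():
        write_bed(peaks, outdir / f"peaks_{week}.bed")
    for name, track in atac.sample_coverage.items():
        write_bedgraph(track, outdir / f"coverage_{name}.bedgraph")
    for week, track in atac.week_coverage.items():
        write_bedgraph(track, outdir / f"coverage_{week}_pooled.bedgraph")
    write_bed(atac.motif_sites, outdir / "motif_sites.bed")
    meth = simulate_methylation(design, truth, **params.get("methylation", {}))
    for name, recs in meth.items():
        write_bismark_coverage(recs, outdir / f"methylation_{name}.cov")
    table = simulate_binding_change_table(design.seed + 5, truth=truth,
                                          **params.get("binding_table", {}))
    table.to_csv(outdir / "binding_changes_synthetic.tsv", sep="\t", index=False)
    truth.to_json(outdir / "ground_truth.json")
    return truth
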