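# smoltreg

Multi-omics regulatory analysis of Atlantic salmon liver **smoltification**
— the preparatory transformation juvenile salmon (parr) undergo in
freshwater before migrating to sea. The package re-implements, as a tested
and reusable pipeline, an integration analysis across three genomic layers
sampled at four weeks (1, 10, 19, 25) spanning a winter-like short
photoperiod, smolt development, and seawater transfer:

* **Expression** — an ANOVA-like F-test for differential expression across
  weeks (DEGs at FDR < 0.05), hierarchical co-expression clustering of
  gene-scaled profiles into k = 7 clusters with a Pearson-correlation
  membership gate (r > 0.5 to the cluster mean), pairwise photoperiod and
  salinity contrasts, and hypergeometric pathway over-representation.
* **Chromatin accessibility (ATAC)** — per-week peak sets merged into a
  unified set, differential accessibility (DA) between consecutive periods
  tested on log2 CPM of peak read counts, peaks linked to the gene with the
  nearest TSS, and a per-cluster Fisher's exact test asking whether DA
  direction (up/down) associates with co-expression cluster membership.
* **TF footprints** — occupancy at motif sites scored as the log2 ratio of
  flanking to central ATAC coverage (a bound factor protects its motif,
  leaving a dip), sites called bound above a threshold, genome-wide
  per-motif binding changes with permutation p-values, and motifs labelled
  by environment concordance: `sea`/`fresh` when binding at week 25 moves
  the same way relative to both freshwater weeks (|log2 change| > 0.1),
  `short`/`long` analogously for week 10 versus the constant-light weeks.
* **Integration** — each site's 4-week bound/unbound calls encoded as a
  binding pattern (14 informative patterns; `0000`/`1111` carry no temporal
  signal), and every (motif, pattern, cluster) combination tested for
  enrichment with Fisher's exact test.
* **Methylation (RRBS)** — CpG calls filtered (≥ 10 reads, below the
  99.9th coverage percentile per sample), merged into a consensus
  (present in ≥ 3 replicates per week), differentially methylated cytosines
  (DMCs) called by a one-way F-test on logit proportions with an effect
  gate (FDR < 0.05 and > 25 percentage-point max pairwise difference),
  annotated by genomic context, and correlated with nearest-gene expression
  against a seeded random-pair null (two-sample Kolmogorov-Smirnov).

Because the original sequencing data are not redistributable at desk scale,
the package ships a first-class synthetic-data generator
(`smoltreg.synthio`) that emulates the study design with machine-readable
planted ground truth — archetype expression trends, accessibility fold
changes, footprint dips following planted binding patterns, methylation
shifts — so every claim the pipeline makes is checked by recovery and
calibration against known truth.

## Worked example

```python
from smoltreg import synthio, expression, chromatin, footprints
from smoltreg.synthio import SimDesign, GroundTruth

design = SimDesign(seed=4)                      # 200 genes, 4 weeks x 4 reps
ann = synthio.simulate_annotation(design)
truth = GroundTruth()
synthio.plant_expression_truth(design, ann, truth)
mat = synthio.simulate_expression(design, truth, annotation=ann)

de = expression.run_anova_de(mat)               # F-test across weeks
degs = de.index[de["deg"]].tolist()
clusters = expression.cluster_degs(mat, degs, k=7)

atac = synthio.simulate_atac(design, truth, ann)
unified = chromatin.merge_peak_sets(atac.peaks_per_week)
counts = chromatin.count_reads_in_peaks(unified, atac.sample_coverage)
da = chromatin.test_da(counts, atac.sample_weeks, "w19_w25")

scores = footprints.score_sites(atac.week_coverage, atac.motif_sites)
res = [footprints.global_binding_change(scores, a, b, seed=4)
       for a, b in (*footprints.PHOTOPERIOD_PAIRS, *footprints.SALINITY_PAIRS)]
classes = footprints.classify_environment(
    footprints.change_table_from_results(res))
```

With seed 4 this prints (via the obvious `print` calls):

```
DEGs (FDR < 0.05): 160 of 200
assigned: 160 excluded by correlation gate: 0
unified peaks: 289 | DA w19->w25: up 21 down 17
motif labels: {'none': 11, 'fresh': 1} {'none': 9, 'short': 3}
```

160 of 200 genes change across the time course (140 planted archetype
genes plus the planted contrast-responsive genes), all pass the
correlation gate into one of the 7 clusters; the DA peaks at the seawater
transition include the planted fold-2 accessibility changes; and the motif
labels recover the planted occupancy trends (one motif losing binding at
sea, three gaining binding after the short photoperiod).

The full pipeline, from simulation to every output table, runs from one
config:

```sh
smoltreg run-all --seed 1 --outdir runs/demo
```

which writes DE/cluster/DA/footprint/enrichment/DMC tables and a
`manifest.json` recording input hashes and per-stage row counts; re-running
skips unchanged stages.

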