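# Methods

## Study design being modelled

Liver samples from Atlantic salmon across four sampling weeks (1, 10, 19,
25). Between weeks 1 and 10 one fish group experiences a winter-like short
photoperiod (8 h light : 16 h dark) before returning to constant light;
smoltification completes by week 19; fish are moved to seawater before
week 25. Three groups exist: `short` (short photoperiod, then seawater),
`long` (constant light throughout), and `fresh_control` (short photoperiod
history but kept in freshwater). Expression is sampled in all groups; ATAC
and RRBS data follow the `short` group time course.

## Statistical model

All differential testing runs on classical linear-model statistics applied
to transformed values rather than count-based generalised linear models:

* **Expression / accessibility**: counts are normalised to counts per
  million (CPM) per sample and transformed to `log2(CPM + 0.5)`. Changes
  across the four weeks are tested per feature with a one-way F-test;
  pairwise contrasts use Welch's unequal-variance t. This replaces
  quasi-likelihood count GLMs deliberately: the package's claims concern
  the downstream integration, the classical tests are fully specified and
  self-contained, and both are calibrated on null simulations (empirical
  type-I within 2 points of nominal at α = 0.05; the Welch test at n = 4
  vs 4 is mildly conservative, ~0.035–0.047 empirically). The transform
  pseudocount (0.5) is exposed as a parameter. TMM-style compositional
  normalisation is out of scope; the synthetic data are constructed so the
  developmental program is shared across fish groups, keeping library
  composition comparable between contrast arms.
* **Methylation**: per-CpG one-way F-test across weeks on
  `log2((M + 0.5)/(U + 0.5))` (logit-transformed methylation proportion
  with a 0.5-read pseudocount on methylated and unmethylated counts). A
  DMC requires FDR < 0.05 **and** a maximum pairwise difference in
  per-week mean methylation above 25 percentage points. The effect
  threshold is interpreted as absolute percentage points (not 25%
  relative), the stricter and more common reading; the gate can only
  reduce calls, so the gated null rate is bounded by the FDR level.
* **Multiple testing**: Benjamini-Hochberg step-up, written in-house to
  propagate NaN p-values while excluding them from the test count m.
* **Association tests**: Fisher's exact test (two-sided by the
  sum-of-less-probable-tables definition, sample odds ratio with Haldane
  +0.5 correction when a cell is zero; zero-margin tables report p = 1 with
  the odds ratio flagged undefined) and the upper-tail hypergeometric test
  for pathway over-representation. Both agree with exhaustive enumeration
  oracles to ~1e-15 over all 2×2 tables with total ≤ 40.

## Co-expression clustering

DEG profiles are gene-scaled (per-gene z-score of CPM across samples — a
per-gene scale factor such as gene length cancels, so this equals
gene-scaled TPM up to sample-level normalisation) and clustered
hierarchically on Euclidean distances. Ward linkage is the default (the
linkage is a free choice; Ward gives compact clusters of temporal shapes)
with the tree cut at k = 7. A gene stays in its cluster only if its
Pearson correlation to the cluster's mean profile exceeds 0.5; excluded
genes keep their failing correlation in the output. The correlation gate
runs on the same scaled profiles used for clustering (scaled vs raw was an
open choice; scaled keeps the gate consistent with the distance). A
within/between sum-of-squares report across k supports the cluster-count
choice.

## Chromatin accessibility

Per-week peak sets are merged by interval union with book-ended merging
(gap ≤ 0), matching common merge-tool semantics; the merge is idempotent
and each unified peak records its contributing weeks. Reads per peak are
integrated from per-sample coverage (sum of coverage × width). DA is
tested between the three consecutive periods (weeks 1→10, 10→19, 19→25)
with direction = sign of the later-minus-earlier log fold change for
FDR < 0.05 peaks. Peak-to-gene links use the interval **midpoint** to the
nearest TSS (midpoint vs nearest-edge is unspecified in general; the
midpoint is symmetric and matches the all-pairs oracle), ties resolve to
the lexicographically smallest gene id, and signed distance is
strand-aware (negative = upstream). Genomic context is classified with
precedence promoter > exon > intron > intergenic; the promoter window
defaults to 1500 bp upstream / 500 bp downstream of the TSS (a common
convention; "promoter" is otherwise undefined). The DA-direction ×
cluster association uses, per cluster c, the 2×2 table
[up-peaks linked to cluster-c DEGs | up-peaks linked to other-cluster
DEGs] × [down-peaks, same split].

## TF footprints

Replicates are pooled per week before scoring. A site's score in one week
is `log2((flank + 1)/(center + 1))` with center = mean coverage over the
motif span and flank = mean over 20 bp windows starting 5 bp outside each
motif edge; the +1 guards zero coverage. A site is bound when its score
exceeds 0.5 — with the generator's default dip (coverage falling to 0.3×
the plateau) true dips score ≳ 1.5 while flat sites score ~0, and on null
simulations ≤ 5% of sites are called bound. This flank/center ratio with a
fixed threshold replaces a full footprinting model (insertion-bias
correction, mixture-based bound/unbound assignment) while keeping the same
bound/unbound contract.

Genome-wide change per motif between two weeks is
`log2((mean_B + 0.1)/(mean_A + 0.1))` over site scores, with significance
from a seeded paired permutation (each site's two week labels swapped
independently; default 1000 permutations). Environment classification uses
a log2 cutoff of 0.1 on the four week pairs (1,25), (19,25), (1,10),
(10,19): `sea` when week 25 exceeds both freshwater weeks by more than the
cutoff, `fresh` for the concordant decrease, `short`/`long` analogously
for week 10 versus weeks 1 and 19. The photoperiod and salinity labels are
independent. In tabular output the pairwise-change columns follow the
published convention that a positive change means more binding in the
first-named (earlier) week; the in-memory operation returns
later-over-earlier changes (antisymmetric under week swap) and the table
writer negates.

## Binding-pattern enrichment

Bound flags over the four weeks are encoded as 4-character patterns; the
two constant patterns are uninformative, leaving 14. For each (motif,
pattern, cluster) combination the 2×2 is built over the motif's own
DEG-linked sites: [pattern = P vs ≠ P] × [gene in cluster C vs other
clusters]. Restricting the background to the motif's own sites (rather
than pooling all motifs) controls for per-motif site abundance; the
pooled alternative is a one-line change in the caller. An editable
assumed-pattern map flags each cluster's primary/secondary expected
pattern (e.g. cluster 1, peaking at sea, expects `0001`); the defaults are
display conventions, not tested claims. Within each (cluster, pattern)
family the most significant motifs (top quantile, default 0.1) are marked
for labelling.

## Methylation-expression correlation

Each DMC's four per-week mean methylation scores are correlated (Pearson)
with its nearest gene's four per-week mean CPM values — per-week means,
not individual samples, because the RRBS fish are not the RNA-seq fish. A
pair is "significant" at p < 0.05 and |r| > 0.95; with n = 4 this sits
near the feasibility boundary (|r| > 0.95 gives p ≈ 0.05) and the
thresholds are applied literally. The null distribution draws uniformly
random (DMC, gene) pairs with a recorded seed, and observed vs null r
distributions are compared by a two-sample Kolmogorov-Smirnov test (the
comparison test was an open choice; KS is assumption-free on 4-point
correlations).

## Synthetic data

The generator (`smoltreg.synthio`) emulates, at desk scale, everything
downstream of read alignment:

* **Annotation**: coordinate-skeleton genomes (no sequence), default 2
  chromosomes × 1 Mb holding 200 genes with exon/intron structure.
* **Expression**: negative-binomial counts (dispersion 0.1, base mean 100,
  per-gene log-normal size factors, library sizes ±20%). Planted genes
  follow one of seven archetype trends encoded as per-week mean
  multipliers (e.g. cluster 1 = (1,1,1,8), an 8× seawater induction;
  cluster 7 = (8,4,2,1), steady decline). The multiplier vectors keep the
  qualitative shapes of the study's clusters while staying mutually
  distinguishable (max pairwise profile correlation ≈ 0.74). The
  developmental program is shared by all groups — the freshwater control
  holds its week-19 state at week 25 — so contrasts isolate the planted
  contrast-responsive genes.
* **ATAC**: peaks are flat plateaus (promoter peaks at every TSS plus
  intergenic peaks), coverage is piecewise-constant per sample with
  gamma replicate noise (CV 0.1) at 4 replicates per week; planted DA
  peaks scale their plateau by fold 2 from the later week of their
  contrast onward; footprint dips drop coverage over the motif span to
  0.3× the plateau in weeks where the site's planted pattern digit is 1.
  Some motifs are "coupled": their bound sites sit at promoter peaks of
  one expression cluster's genes, planting the pattern × cluster
  association.
* **Methylation**: binomial CpG calls around per-site base proportions
  (log-normal coverage, mean 30, heavy tail to exercise the percentile
  filter); planted DMCs shift by 40 percentage points at weeks 19/25.
* **Binding-change table**: the published global TF-binding table and its
  classification are not redistributable, so a synthetic stand-in of the
  same shape is generated with the published memberships planted (33
  photoperiod-associated motifs, 35 salinity-associated of which 30 lose
  and 5 gain binding at sea); per-week mean scores are drawn so the
  implied pairwise changes respect the classification cutoff with margin,
  and the change columns are computed from the scores.

What the generator does **not** model: read-level artefacts (GC and
mapping bias, duplicates, insertion bias), genuine genomic sequence,
correlated gene programs beyond the planted archetypes, compositional
library distortions, or SNP-confounded CpGs. Passing recovery tests
therefore demonstrates the pipeline's correctness and calibration on data
matching its assumptions, not robustness to alignment-level artefacts.

## Numerical and procedural choices

* Coverage is emitted as 1 bp-resolution (run-length encoded) bedGraph;
  window means are exact integrals over piecewise-constant segments.
* The coverage percentile filter uses the "higher" order statistic with a
  strict `>` comparison, so a sample of identical coverages loses nothing.
* Zero-variance features get p = 1 (keeps the BH test count stable);
  zero within-group variance with non-zero between-group variance gets
  p = 0.
* Fisher p-values under the null are discrete and conservative, so
  enrichment-calibration checks use a one-sided KS test against uniform
  (excess of small p-values is the only informative direction).
* All randomness flows through integer seeds; fixed seed gives
  byte-identical generator output and bit-identical permutation and
  random-pair nulls.
* Acceptance problem sizes: the expression recovery study uses 2000 genes
  (700 planted across 7 archetypes) on a 4-week × 4-replicate design;
  ATAC recovery uses the 200-gene design with 72 planted DA peaks and 12
  motifs × 40 sites; DMC recovery plants 500 of 2000 CpGs at coverage
  100; null calibrations use 1500–2300 features per layer.

## Known limitations

* The Welch-based DA test at 2 replicates per week (the study's ATAC
  depth) is underpowered; the generator defaults to 4 replicates, within
  the study's 2–4 replicate range.
* Bound/unbound counts depend on the fixed footprint threshold; only the
  classification from pairwise changes, not absolute bound counts, is
  expected to be reproducible.
* Nearest-TSS assignment is a heuristic; distal regulatory elements are
  attributed to the wrong gene when an unrelated TSS is closer.
* With n = 4 week means, correlation p-values are coarse and the
  significant-pair definition is near its feasibility boundary by design.
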