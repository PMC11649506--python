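# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `lymphtraj`. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Study design being modeled

The pipeline targets droplet scRNA-seq of peripheral blood lymphocytes
from four cohorts: healthy subjects (HS), acute sepsis at day 4 ± 1 (D4),
and late sepsis (day 14–21) split into rapid recovery (RAP) and chronic
critical illness (CCI). Cells are nested within donors and donors within
cohorts; all cross-cohort inference must respect that hierarchy. RAP is
the reference and CCI the comparison group throughout.

## Synthetic-data generator

`synthdata.simulate_cohort` draws, for a singlet of donor *d* (cohort *c*)
and cell type *t*:

    η_g = log b_g + m_{t,g} + β_{t,g}·I(c = CCI)
          + s_g·δ·I(c = CCI, t targeted) + u_d·I(g donor-variable)
    p   = shares: exp(η) normalized, with the cell's mitochondrial
          fraction f ~ Beta(a, b) fixing the summed mito-gene share
    X_g ~ NB(mean = L·p_g, size θ),   L ~ LogNormal(meanlog, sdlog)

* **Baselines** `b_g` are log-normal (log-mean SD 1), giving a realistic
  mean–variance span for bin-matched control-gene sampling. The 15 named
  exhaustion-panel genes sit high in the expression range (log-mean 2.5)
  so that planted log-fold shifts survive the log1p transform; the 13
  mito genes sit at log-mean 1.
* **Markers** are 20 disjoint background genes per cell type at log-fold
  +2.0 — enough to make types separable by clustering and annotation
  without being trivially one-gene.
* **Condition effects** default to 8 up- and 4 down-regulated genes at
  |β| = 1 (natural-log units) in CD8 TEM and NK cells, the types the
  analysis focuses on; an explicit `(cell type, gene) → β` map overrides.
* **Exhaustion shift** δ (default 1) is applied sign-aware to the signed
  panel genes in CCI cells of the targeted types; FCGR3A carries sign 0
  and acts as a planted negative control.
* **Donor intercepts** u_d ~ N(0, τ²), τ = 0.5 by default, are shared
  across a fixed 30% "donor-variable" gene subset and zero elsewhere, so
  DE tests can be benchmarked on both exchangeable and pseudoreplicated
  genes. Because one intercept is shared across genes, the estimable
  quantity at D donors is the realized variance of the D draws; the
  generator test recovers it from pseudobulk log-means (log of per-donor
  mean counts) with a reduced donor-variable fraction, since
  library-share renormalization otherwise leaks part of the shift.
* **Dispersion** θ = 2 (var = μ + μ²/θ), desk-realistic overdispersion;
  verified against the closed-form NB moments over ≥5000 cells.
* **Library sizes** LogNormal(log 2500, 0.35); the study-scale target of
  5000 cells per donor is configurable but desk defaults are 300.
* **Composition** per cohort follows the published cohort pattern
  renormalized over the six simulated subtypes (CD4 TCM dominance at D4,
  CD8 TEM and NK expansion in CCI).
* **Empties** draw totals uniformly in [10, 150] from the ambient profile
  (library-size-weighted average of all cell profiles, i.e. pooled count
  proportions); **doublets** (5%) are elementwise sums of two singlets of
  the same donor; **layers** split total counts by binomial thinning at
  fixed (0.75, 0.20, 0.05), so spliced+unspliced+ambiguous equals total
  exactly.
* **Randomness**: one global seed with named substreams per stage
  (`_rng.substream`), so adding draws in one stage never perturbs another.

What the generator does *not* emulate: UMI/read-level error, gene–gene
correlation beyond the type programs, continuous cell states, batch
chemistry effects, or empirical dropout curves. Passing tests therefore
demonstrate correctness of the algorithms under the stated hierarchical
NB model, not performance on any particular real dataset.

## Droplet QC

**Cell calling.** The ambient profile is the pooled counts of barcodes
with total ≤ 100 plus a 0.5 pseudocount per gene (avoiding zero-probability
genes in the null). Each barcode between the ambient pool and the knee of
the log-rank/log-total curve is tested for multinomial goodness of fit:
the statistic is the multinomial log-likelihood under the ambient
proportions, its null distribution simulated by Monte Carlo with the
add-one estimator p = (1 + #{T_sim ≤ T_obs})/(n_mc + 1), so the smallest
attainable p is 1/(n_mc+1). Simulated droplets grow incrementally from one
tested total to the next, making the overall cost O(n_mc · max total)
category draws. P-values are BH-adjusted and barcodes kept at FDR < 0.01;
barcodes at or above the knee (maximum negative second difference of the
smoothed log-log rank curve) are always called, and their p-values are not
computed since no decision depends on them. No Good–Turing ambient
estimation or beta-binomial overdispersion is attempted.

**Doublets.** Artificial doublets (sums of random cell pairs) are embedded
jointly with real cells (log1p CP10K, 30 PCs); a cell's score is the
fraction of artificial doublets among its 25 nearest neighbors rescaled by
the real:simulated count ratio. Without an explicit threshold the top 5%
(the expected doublet rate) is flagged.

**Mito filter.** Fraction = spliced mitochondrial counts / total spliced
counts; cells kept iff fraction < 0.05 (strict: exactly 5% is removed).
Cells with zero spliced counts are removed with a warning. The
spliced-layer denominator is used as specified; whether the original
workflow used total counts instead is unknowable from the text.

## Normalization, embedding, clustering

Two size-factor flavors: plain library-size, and pooled deconvolution
factors within Ward-linkage pre-clusters (ring pools of sizes 21–33,
least-squares deconvolution with a low-weight library-size anchor to keep
the system full rank, per-cluster rescaling to a common reference). The
phrase motivating pool-based normalization in the source workflow is
ambiguous, so library-size is the default and the pooled path is provided
and tested (planted factors 1 vs 2 recovered within 5%).

PCA uses randomized SVD with 10 power iterations and a fixed seed, tested
to 1e-6 against dense SVD on a well-conditioned matrix. Integration first
aligns per-batch global centroids (removing embedding-wide additive batch
offsets exactly), then iterates soft k-means with a batch-diversity
penalty ((E+1)/(O+1))^θ on expected-vs-observed batch counts per cluster
and a per-cluster per-batch linear centroid correction; the soft-kmeans
bandwidth defaults to the mean squared distance to the nearest centroid.
A single batch returns the input unchanged.

Louvain runs on a shared-nearest-neighbor graph (k = 100, Jaccard weights,
pruned below 1/15) at resolution 0.1. The modularity optimization itself
is delegated to igraph's multilevel implementation with a seeded RNG for
determinism; resolution-scaled modularity is recomputed independently in
`modularity()` for validation, and on ≤8-node graphs the returned
partition attains the exhaustive-enumeration optimum.

## Annotation and consensus

The correlation annotator scores each cell against each reference label by
the 0.8 quantile of Spearman correlations with the label's sample
profiles, over marker genes chosen as the union of top-30 profile
differences for every ordered label pair; labels within 0.05 of the top
are re-scored on markers recomputed for that subset (two rounds). This is
a rank-correlation reading of reference-based annotation; the exact
scoring of the tools it stands in for is out of scope by design. The kNN
annotator transfers the majority label of the 15 nearest labeled anchors
in a shared embedding and provides the sixth independent vote.

Consensus assigns the modal harmonized label when the vote fraction
strictly exceeds 0.80 — so 5 of 6 assigns (0.833) while 4 of 6 (0.667) and
4 of 5 (exactly 0.80) do not — with ties unassigned. Unassigned cells are
excluded downstream. Harmonization maps panel vocabularies onto the
20-subtype vocabulary plus lineage parents; a coarse panel votes at
lineage level and simply cannot match fine-grained votes, which mirrors
how mixed-granularity references behave.

## Composition statistics

Cross-tab percents are 100·count/column-total rounded half-away-from-zero
to 2 dp. The packaged reference count table reproduces every printed
healthy and day-4 percent and the overall total of 18,851 cells; the
remaining two columns of the printed table are internally inconsistent
(their counts and percents correspond to swapped totals) and are not used
as exact fixtures. Frequency comparisons are per-subtype one-way ANOVA
with cohort factor plus Tukey HSD (the "two-way" description in the
source legend most plausibly refers to the subtype × cohort layout);
functional-assay comparisons use Kruskal–Wallis with tie correction. The
division index is total divisions / starting cells.

## Mixed-model DE

REML estimation profiles β and σ² analytically per donor block
(Woodbury), leaving a 1-D bounded search over log λ ∈ [−18, 18] with
xatol 1e-8; a boundary comparison snaps λ to 0 when the boundary value is
as good (OLS limit). The Wald statistic for β₁ uses a Student t reference
with containment degrees of freedom `n_donors − 2`: the condition contrast
is donor-constant, and at cohort-realistic donor counts a standard-normal
reference is measurably anti-conservative while t(D−2) calibrates to the
nominal level (verified by simulation in the acceptance suite). A
normal reference remains available (`df=inf`). Genes expressed in <5% of
the stratum's cells are excluded before fitting; BH adjustment is within
stratum; per-cell-type thresholds are 0.5 (B), 0.1 (CD8 T), 0.01 (CD4 T,
NK). A pseudobulk Welch t-test on donor means is provided as a
cross-check, and a donor-ignoring pooled t-test exists only to
demonstrate pseudoreplication. Degenerate responses (all values equal)
return a flagged fit with p = 1; a single donor raises.

## Exhaustion scoring

Genes are ranked into 24 equal-size bins by mean expression; each panel
gene draws 100 bin-matched controls without replacement, excluding the
panel genes themselves — with desk-scale gene counts the panel would
otherwise dominate its own bin and cancel real signal (at genome scale
this exclusion is nearly a no-op). If a bin is exhausted the nearest
nonempty bin is borrowed. The signed score is score(plus arm) −
score(minus arm), antisymmetric under flipping the panel; an unsigned
pooled mode matches the additive-module convention. Control draws are
keyed by seed and panel name, reproducible bit-for-bit, and the score's
across-seed variability is small relative to its biological spread at
nctrl = 100. Recovery of a planted δ = 1 shift is validated with donor
variance switched off and balanced type proportions (≥500 target cells
per cohort) — the check isolates the scorer; with few donors and τ > 0
the cohort contrast is donor-confounded by design, which is exactly why
the downstream test is a mixed model.

## Enrichment

One-sided hypergeometric upper-tail p per set against the DE list, with
the universe defaulting to the genes actually tested in the stratum
(post-filter) rather than the genome — a deliberately conservative
choice. BH across sets within a collection, kept at p_adj < 0.05;
optional split by DE direction; depletion behind a flag. The p-value
matches an exact combinatorial enumeration to 1e-12 (exhaustively for
all tables with N ≤ 25 and on 2000 sampled tables up to N = 200). No
gene-set databases are bundled.

## Problem sizes

Desk-scale defaults keep any single check within seconds to ~1 minute:
500–2000 simulated genes for calibration, 50 genes for oracle and power
comparisons, ~2000 cells for clustering/annotation runs, 2000 empty
droplets for cell-calling, two replicate simulations for module-score
recovery. All are configurable upward.

## Known limitations

* The mixed model is Gaussian on log-normalized expression; no NB GLMM,
  no multi-condition contrasts, no Satterthwaite/Kenward–Roger df (the
  containment df is exact only for balanced donor-constant contrasts).
* The cell caller is a simplified ambient Monte-Carlo test, not a
  re-implementation of any specific published caller's numerics.
* The integration step corrects linear per-cluster batch offsets only.
* The annotators are deliberately simplified stand-ins with matching
  contracts; real reference atlases will expose vocabulary and platform
  effects the synthetic panels do not.
* Real-data quantities from the motivating study (post-QC cell counts,
  DE gene counts per cell type, reported exhaustion p-values) require the
  deposited cohort data and are not reproduced or asserted here.
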