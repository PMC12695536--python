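# Methods

## Scope

`pitdeconv` implements a complete composition-analysis workflow for bulk
pituitary-tumor RNA-seq: reference preparation from annotated single-nucleus
counts, marker and marker-free signature construction, two deconvolution
engines, pseudobulk benchmarking with a fixed validation rule, and
quantification plus expression-level flagging of residual normal tissue.
Read-level processing, graph-based clustering/embedding and automated cell
annotation of real references are out of scope; the package starts from an
annotated count matrix.

## Synthetic reference model

The generator emulates the statistical structure the estimators rely on,
not pituitary biology per se.

* **Atlas.** 13 cell types: 7 endocrine (somatotroph, lactotroph,
  thyrotroph, gonadotroph, corticotroph, stem, progenitor), 3 stromal
  (endothelial, pericyte, smooth muscle), 3 immune (T cell, macrophage, NK)
  at lower abundance (60 cells vs 160/100) — enough to stay above the
  50-cell exclusion while exercising minority-population behaviour.
* **Expression.** Gene baselines are log-normal (σ = 1). Each type owns a
  disjoint block of `markers_per_type = 120` genes whose mean is
  `marker_fold = 8` × baseline within the type. Donor effects are
  per-(subject, gene) log-normal factors (σ = 0.2) shared by all of a
  subject's cells; 3 subjects by default, assigned round-robin within type
  so every (subject, type) stratum is populated. This cross-subject
  variation is what the weighted-NNLS engine weights on.
* **Counts.** Negative-binomial via gamma–Poisson with dispersion
  α = 0.25 (variance μ + αμ²), per-cell library size log-normal around
  `libsize_mean = 6000` (log-SD 0.25). A designated set of 13 `MT-` genes
  receives a per-cell mitochondrial fraction drawn uniformly from
  (0.005, 0.04). With 2000 genes and this depth, per-cell detected-gene
  counts land inside the QC window 1000 < n_features < 5000, so the
  standard thresholds apply unmodified.
* **Bulk cohorts.** A tumor sample with planted residue fraction `f` is a
  multinomial draw of `reads_per_sample` reads from
  `(1−f)·profile(tumor) + f·profile(residue)`, where type profiles are the
  pooled CPM of the reference's cells. The default residue is spread
  uniformly over endocrine types *outside* the tumor's lineage, so `f` is
  the sample's true cross-lineage residual-normal fraction; any split can
  be passed explicitly.

What the generator does **not** model: transcriptome-wide co-expression,
ambient RNA, doublets, platform/batch noise beyond the donor effect, and
real marker-gene overlap between related types (blocks are disjoint).
Passing tests therefore demonstrate correctness of the estimators under the
assumed mixture model, not performance on real tissue, where marker
bleed-through and unmodelled populations will lower recovery.

## Reference preparation

* **QC.** Cells are kept when `min_features < n_features < max_features`,
  `n_counts > min_counts`, `pct_mito < max_mito` (strict inequalities;
  defaults 1000 / 5000 / 200 / 5%). The filter is idempotent and an empty
  result is returned with a warning, not raised.
* **Normalization.** CPM scales each column to 1e6; log transforms are
  `log(x+1)` natural (reference prep) or base-10 (bulk heatmap/clustering
  input).
* **Marker test.** One-vs-rest per type on log-CPM. A gene is testable when
  detected in ≥ `min_pct = 0.25` of cells in the type or the rest. Each
  group is modelled as a zero point mass (probability 1−π) plus a normal on
  nonzero log values; the likelihood-ratio statistic against a shared-
  parameter null is referred to χ²(3) — the alternative frees (π, μ, σ) per
  group. The normal SD is floored at 1e−3, and groups with no detected
  cells degrade to the point-mass limit rather than NaN. Fold change is
  `ln((mean CPM_in + 1)/(mean CPM_out + 1))` on the linear scale, which is
  stable for zero-heavy genes. Bonferroni correction over all genes in the
  matrix is the default (configurable to none). Types with fewer than 50
  cells are excluded before testing.
* **GES signatures.** Significant markers (adj. p ≤ 0.05, logFC > 1) are
  ranked per type by within-type mean CPM, descending, ties broken by
  smaller adj. p then gene id; the top N (50–300) form the member set, and
  the union forms the gene axis with per-type mean CPM values. Genes ≤ 1
  CPM in every type are dropped. Member sets are nested across N by
  construction. Ranking by within-type mean expression (not by fold change)
  was a genuinely open choice; it favours high-signal genes that dominate
  mixture least squares.

## Deconvolution engines

* **ν-SVR.** Per sample, on genes shared with the signature: the signature
  block is z-scored with its global mean/SD and the sample vector with its
  own; a linear ν-SVR (C = 1) is fit for ν ∈ {0.25, 0.5, 0.75}; the ν with
  the smallest RMSE between the standardized mixture and its reconstruction
  from clipped-and-renormalized coefficients is kept. Proportions are
  reported in relative mode (sum to one); no absolute-score mode. The
  permutation p-value is the fraction of random pseudo-mixtures — gene
  values resampled with replacement from the full mixture matrix — whose
  reconstruction Pearson R reaches the observed R (100 permutations by
  default; 0 disables and reports NaN). The libsvm stopping tolerance is
  set to 1e−2: coefficient movement below that level is ~1e−3 in proportion
  units, far below the estimator's own error, at a large solver-time
  saving. The proprietary batch-correction mode of the reference web
  implementation is not reproduced; an optional per-gene location/scale
  alignment is available and off by default, with quantile normalization
  likewise disabled.
* **Marker-free signature.** Types with ≥ 50 cells contribute pooled-CPM
  profiles; genes are ranked per type by fold change over the maximum of
  the other types; for each candidate per-type size G ∈ {50 … 300} the
  union-of-top-G signature is scored by its 2-norm condition number and
  the minimizer selected — ill-conditioned signatures amplify noise in the
  mixture inversion. If every candidate exceeds the conditioning cap the
  signature is declared singular (e.g. duplicated type profiles).
* **Weighted NNLS.** The design matrix holds mean type profiles (relative
  expression) scaled by per-type mean library size, so coefficients are
  proportional to cell-count — not RNA-mass — fractions. Iteration:
  solve NNLS with per-gene weights `w_g = 1/(ε + σ²_g)`, where σ²_g is the
  cross-subject variance of the reconstructed expression under the current
  coefficients and ε = 1e−8 × mean variance; stop when the largest
  proportion change < 1e−6 or after 100 iterations (non-convergence is
  flagged, not raised). With zero cross-subject variance the weights are
  constant and the result equals unweighted NNLS; a single-subject
  reference triggers a warning and the unweighted path.

True pseudobulk proportions are cell-count fractions while the SVR engine
estimates RNA-mass fractions; with the default equal per-type library
sizes these coincide in expectation, and with unequal sizes the per-type
correlation validation is largely insensitive to the monotone distortion.
This discrepancy is a documented property of the design.

## Pseudobulk benchmarking

Random mixing: per sample a composition is drawn from a flat Dirichlet over
available types, a 500-cell budget is allocated multinomially, cells are
sampled with replacement within type, raw counts are summed without
per-cell scaling, and the result is CPM-normalized; true proportions are
the realized allocated-cell fractions. 150 samples of 500 cells is the
default benchmark. Whether the upstream convention draws compositions
uniformly or census-weighted is not fixed anywhere; the uniform simplex was
chosen and seeded. Validation per type uses Pearson r across samples with
the two-sided t-transform p-value; `validated ⇔ r > 0.70 and p < 0.05`;
constant vectors or fewer than 3 samples give reason "degenerate", types
missing from an engine's output reason "absent". Engine failures inside
`benchmark_matrix` become report rows, not crashes.

## Contamination analysis

Given a deconvolved composition and a histotype, fractions partition into
tumor (the histotype's tumor cell types), same-lineage (other endocrine
types of the tumor's lineage), residual-normal (endocrine types outside the
lineage, plus an optional posterior pseudo-type), and TME (stromal +
immune). Stem/progenitor signal counts as same-lineage for PIT1 tumors by
default (configurable), reflecting that such signal in tumors frequently
represents tumor-intrinsic de-differentiation rather than residue. TME is
deliberately *not* counted as contamination. A sample is flagged
contaminated when residual-normal ≥ 0.20 — a tool parameter sitting between
empirically observed high- and low-contamination groups, not a literature
constant. The cohort summary reports mean ± SD of the residual fraction
over flagged samples and over all samples.

Expression-level flagging is deconvolution-free: log10(CPM+1) profiles,
optionally batch-aligned (per-gene location/scale standardization within
batch to the pooled moments — a deliberate simplification of empirical-
Bayes batch correction, swappable behind the same interface; size-1 batches
are centered only), top-500 variance-ranked genes, Euclidean distances,
complete-linkage clustering, cut into k clusters (k ≥ number of lineages).
A sample is flagged when its cluster's majority (> 50%) lineage differs
from its own, when its cluster has no majority, **or** when its cluster is
not its lineage's home cluster (the cluster holding the plurality of that
lineage's samples; ties to the larger cluster, then the lower label). The
third condition captures contaminated samples that segregate as a
*distinct group* of their own — a pure majority-vote rule can never flag a
cluster composed entirely of mislabeled-looking samples of one histotype.
Choose k near the number of expected sample groups: k far above it splits
tight clean clusters and the home-cluster rule then flags the smaller
fragments.

## Numerical and degenerate-input choices

* Ranking ties anywhere are broken deterministically (gene id, cluster
  size, label order); all randomness flows through explicit integer seeds,
  and two runs of the pipeline with the same config are byte-identical.
* Zero-sum columns in CPM, unknown histotypes/cell types, axis mismatches
  and sub-2-gene overlaps raise labelled errors naming the offender.
* Duplicate gene ids on input are summed with a logged warning.
* `batch_adjust` floors zero within-batch SDs (constant genes pass through
  centered).

## Problem sizes

Default study-scale conditions: 2000-gene, 1600-cell reference; 150
pseudobulk samples × 500 cells; bulk cohorts of 30–35 samples at 1–5M
reads. The test suite exercises the full default benchmark once and uses
a 4-type, 400-gene miniature of the same generative model elsewhere.

## Known limitations

* The bimodal LRT assumes normal nonzero log-expression; heavy tails
  inflate the statistic slightly (the null-calibration test bounds the
  practical effect).
* Recovery figures from disjoint marker blocks are optimistic relative to
  real references with overlapping programs.
* The permutation null resamples genes independently, ignoring gene-gene
  correlation, as in the published SVR-deconvolution convention it follows.
* Batch alignment matches first and second moments only; strong
  batch-by-gene interactions are not removed.
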