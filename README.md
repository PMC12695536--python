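# pitdeconv

Cell-type deconvolution of bulk pituitary-tumor RNA-seq against a
single-nucleus reference, with built-in benchmarking and quantification of
residual normal tissue.

Pituitary neuroendocrine tumors (PitNETs) arise from one anterior-pituitary
lineage (PIT1: somatotroph/lactotroph/thyrotroph; TPIT: corticotroph; SF1:
gonadotroph), but surgical specimens routinely carry residual normal gland
and tumor-microenvironment (TME) cells. In bulk RNA-seq this contamination
distorts expression profiles and clustering. `pitdeconv` estimates the
cellular composition `p` of each bulk sample from a reference of cell-type
expression profiles and partitions it into tumor, same-lineage,
cross-lineage residual-normal, and TME fractions.

## The model

A bulk profile is treated as a non-negative mixture of cell-type profiles.
For a CPM-scale mixture vector `m` over genes and a signature matrix `S`
(genes × cell types):

```
m ≈ S p,   p ≥ 0,   Σ_k p_k = 1
```

Two estimators of `p` are provided:

* **ν-SVR** — a linear ν-support-vector regression of the z-scored mixture
  on the z-scored signature columns, fit over ν ∈ {0.25, 0.5, 0.75}; the ν
  minimizing reconstruction RMSE wins, negative coefficients are clipped and
  the rest renormalized ("relative" mode). Significance comes from a
  permutation null of random pseudo-mixtures. The signature is either a
  marker-based GES matrix (top-N markers per type by within-type mean CPM
  from a one-vs-rest bimodal likelihood-ratio test, adj. p ≤ 0.05 and
  ln-fold-change > 1) or a marker-free signature built directly from cells
  with a condition-number-minimizing gene-set size.
* **weighted NNLS** — iterative non-negative least squares against
  multi-subject type profiles scaled by per-type cell size factors, with
  per-gene weights `1/(ε + σ²_g)` where `σ²_g` is the cross-subject variance
  of the reconstruction; donor-inconsistent genes are down-weighted.

Accuracy is validated on pseudobulk mixtures of known composition: per cell
type, Pearson `r` between true and estimated proportions across samples,
with `r > 0.70` and `p < 0.05` required for a "validated" call. A synthetic
single-nucleus atlas (13 pituitary cell types, negative-binomial counts,
marker blocks, donor effects) makes the whole workflow runnable offline.

## Worked example

```python
from pitdeconv import (SimConfig, SVRConfig, generate_reference, qc_filter,
                       build_signature_from_cells, simulate_pseudobulk,
                       svr_deconvolve, evaluate)

ref = qc_filter(generate_reference(SimConfig(seed=1)))       # 2000 genes x 1573 cells
sig = build_signature_from_cells(ref)                        # 1300 genes x 13 types
mix = simulate_pseudobulk(ref, n_samples=150, cells_per_sample=500, seed=2)
res = svr_deconvolve(mix.mixtures, sig, SVRConfig(n_permutations=0), seed=3)
rep = evaluate(mix.true_proportions, res.proportions)
print(rep[["r", "validated"]].round(3).head())
```

prints

```
               r  validated
cell_type
somatotroph  0.999       True
lactotroph   0.998       True
thyrotroph   0.999       True
gonadotroph  0.999       True
corticotroph 0.999       True
```

i.e. every pituitary cell type's planted proportions across the 150
simulated samples are recovered with near-perfect correlation, and each
passes the `r > 0.70`, `p < 0.05` validation rule.

Contamination quantification works the same way on bulk counts:
`bulk_cpm` → `svr_deconvolve` → `contamination_report` yields per-sample
tumor / same-lineage / residual-normal / TME fractions and the cohort mean ±
SD of residual normal tissue over flagged samples, and
`hvg_select` → `hcluster` → `flag_discordant` flags samples that cluster
apart from their annotated lineage using expression alone.

The same steps are available from the shell:

```
pitdeconv simulate-reference --seed 1 --out ref/
pitdeconv build-signature --reference ref/ --n 300 --out ges300.tsv
pitdeconv simulate-pseudobulk --reference ref/ --n-samples 150 --cells 500 --out pb/
pitdeconv deconvolve --mixtures pb/pseudobulk.tsv --signature ges300.tsv --out est.tsv
pitdeconv run-all --seed 1 --out run/
```

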