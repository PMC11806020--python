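# tauvuln

Cell-type-based selective vulnerability to tau pathology: a tested,
seed-deterministic pipeline that asks *which cell types make a brain region
vulnerable (or resilient) to tau deposition?* and answers it with spatial
deconvolution, spatially aware null models, and model selection — all
exercised against a synthetic-data generator with known ground truth.

## Who this is for

Computational neuroscientists and bioinformaticians studying regional
vulnerability in mouse tauopathy models (e.g. PS19 lines), and anyone who
needs the building blocks: signature-based deconvolution of spatial gene
expression, variogram-matched surrogate nulls for regional maps, or
correlation-ranked BIC model selection.

## The methods

**MISS (Matrix Inversion and Subset Selection).** Given a gene signature
matrix `C` (genes × cell types, trimmed-mean cluster profiles) and a spatial
expression volume `E` (genes × voxels), cell-type densities solve, voxel by
voxel,

```
d_k = argmin_{d ≥ 0} || e_k − C_red · d ||²        (NNLS)
```

on an informative gene subset chosen by **MRx3**: (1) prune the 10% of genes
that add the most reconstruction noise (scored by rank-one updates of the
least-squares normal equations), (2) greedily add genes maximizing
`V_i = F_i / Redund(i|S)` where `F_i` is the variance of gene *i*'s
type-normalized signature row and `Redund` is its mean |Pearson r| with
already-selected genes, (3) pick the subset size at the elbow of the
residual-versus-size curve.

**Univariate association.** Each cell type's regional density is correlated
(Pearson or Spearman) with each tauopathy dataset's regional tau burden
after matching region spaces and removing injection-seed regions. The mean
correlation across datasets is tested against autocorrelation-preserving
surrogate maps (permute → kernel-smooth + nugget → rank-remap, bandwidth
fitted on binned variograms), with add-one empirical p-values
`p = (1 + #{|null| ≥ |obs|}) / (n + 1)` and Bonferroni correction
`p_corr = min(1, p · N_tests)`.

**Spectral embedding.** Cell-type similarity (reciprocal correlation
distance, min-max normalized) feeds the unnormalized graph Laplacian
`L = Δ − S`; types are embedded on the second and third eigenvectors, and
embedding coordinates or dissimilarity from a reference type are regressed
against tau association.

**Multivariate models.** Features are ranked by correlation with tau, the
weakest pruned (lower 75% of cell types; lower 50% of gene panels), and
nested models scored by `BIC = −2 ln L̂ + k ln n`; the minimum-BIC rung is
selected, alongside a fixed top-5 model and seeded 10-fold cross-validation.
Class representation among selected types is tested by a χ² goodness-of-fit.

**Gene sets.** SV-G / SR-G are the top 10% of genes by |mean correlation|
split by sign; SV-C / SR-C are size-matched unions of the top differential
genes (row z-scores of the column-normalized signature) of the vulnerable /
resilient cell types. Lists are exported as plain text for external
enrichment tools.

## Worked example

```python
from tauvuln import assoc, miss, synth

world = synth.generate_world(rng_seed=1)   # 60 regions, 300 genes, 12 types,
                                           # 12 tau datasets at SNR 2
print(world.truth.vulnerable_types)        # {'T09': 1.0, 'T11': 0.7}
print(world.truth.resilient_types)         # {'T01': -0.7}

_, density, _ = miss.run_miss(world.signatures, world.expression, n_genes=120)
sig = assoc.surrogate_significance(density.values, world.tau_datasets,
                                   world.atlas, n_surrogates=500, rng_seed=1)
print(sig.sort_values("mean_R", ascending=False).round(4).to_string())
```

```
         mean_R       p  ci_low  ci_high  ci_excludes_observed  p_corr
feature
T09      0.7940  0.0020 -0.4119   0.4621                  True  0.0240
T11      0.6795  0.0020 -0.4234   0.4439                  True  0.0240
T03     -0.0056  0.9800 -0.3879   0.4205                 False  1.0000
...
T01     -0.3488  0.0599 -0.3651   0.3405                 False  0.7186
T00     -0.4006  0.1437 -0.4572   0.4616                 False  1.0000
T07     -0.4527  0.0319 -0.4591   0.3910                 False  0.3832
```

The two planted vulnerable types (T09, T11) top the ranking and survive
Bonferroni correction (`p_corr ≈ 0.024`); the planted resilient type (T01)
trends negative. T07 illustrates why the spatial nulls matter: its mean
correlation (−0.45) is larger in magnitude than the planted resilient
effect, purely through chance spatial overlap — and the surrogate test
correctly leaves it unconvincing after correction.

A command-line interface wraps the same stages:

```bash
tauvuln run-all --seed 1 --outdir results/run1
tauvuln simulate --seed 7 --outdir results/world7
```

## Layout

```
src/tauvuln/
  synth.py      synthetic atlases, signatures, densities, expression, tau
  miss.py       MRx3 gene selection + NNLS deconvolution + aggregation
  coreg.py      region matching and seed removal
  assoc.py      correlations, surrogate nulls, class tests, eigengene
  spectral.py   similarity, Laplacian embedding, tau regressions
  models.py     BIC ladder, top-k models, cross-validation, selection stats
  genesets.py   SV/SR gene sets, DE z-scores, overlaps
  pipeline.py   config + end-to-end driver with manifest
  cli.py        command-line interface
docs/methods.md   modelling assumptions, parameter choices, limitations
```
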