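# Methods

This note records the modelling assumptions, parameter choices, and numerical
conventions of the `tauvuln` pipeline, and what its synthetic-data tests do
and do not establish about real data.

## The synthetic world

Every stage is validated against worlds generated by `tauvuln.synth`, whose
defaults define the study conditions used throughout the tests and the
acceptance script:

| parameter | default | meaning |
|---|---|---|
| `n_regions` / `grid_shape` | 60 / (12, 12, 10) | contiguous regions tiling 1440 voxels (grid spacing semantically 200 µm) |
| `n_genes` / `n_types` | 300 / 12 | signature matrix size |
| `markers_per_type` | 10 | genes folded up 10× in their own type |
| `smoothness` | 1.5 voxels | Gaussian kernel width of density and tau noise fields |
| `expression_noise` | 0.1 | additive expression noise sd relative to mean(C·D) |
| `n_datasets` | 12 | tau experiments (10 seeded, 2 unseeded) |
| `n_timepoints` | 3 | tau scaled up linearly over time points |
| `snr` | 2.0 | regional tau signal sd / noise sd |
| planted effects | 2 vulnerable (+1.0, +0.7), 1 resilient (−0.7) | weights of cell-type densities in the tau signal |

Construction choices:

* **Atlas** — regions grow from random seed voxels by breadth-first accretion
  with a randomized frontier; this guarantees contiguity and a complete
  tiling cheaply. Coarse region groups are assigned by the seed voxel's
  spatial quadrant.
* **Signatures** — each gene has a shared log-normal baseline (µ=0, σ=1)
  across types times bounded multiplicative jitter (log-sd 0.25, clipped at
  e±1); markers multiply by 10 in their own type. The clipping bounds the
  jitter ratio below the fold-up, so a marker's argmax provably lies in its
  own type. Heavy-tailed baselines mimic trimmed-mean cluster profiles.
* **Density truth** — per type, white noise of mean 1 smoothed by an
  isotropic Gaussian kernel and rectified at zero. Smoothing is not
  re-standardized, so the smoothing-width limit behaves correctly (large
  widths give near-constant maps).
* **Tau** — regional tau is a rectified, noisy linear combination of planted
  cell-type densities, shifted (by default) so the noise-free signal's
  minimum is zero; this keeps rectification from erasing planted *negative*
  (resilience) effects while keeping tau a nonnegative burden. Noise fields
  use the same kernel scheme as the densities so surrogate-null calibration
  is meaningful. Tau units are arbitrary and per-dataset, matching the fact
  that each real experiment has its own quantification scale. Seed regions
  get a burden above the map maximum and are excluded from analysis.

What the generator does **not** emulate: ISH imaging artifacts, read-depth
or dropout models, anatomically realistic geometry, or inter-dataset
differences in parcellation granularity (mapping tables are identity by
default; the coregistration module handles arbitrary tables when given
them). Passing tests therefore demonstrate correctness of the machinery and
recoverability under idealized-but-noisy conditions, not performance on real
atlases.

## Normalization and deconvolution

Expression rows are scaled to unit maximum per gene; signature columns to
unit sum per type. Because a row-rescaled `E` is inconsistent with an
unscaled `C`, the per-gene multipliers applied to `E` are recorded
(`gene_scale`) and reapplied to the signature design rows in every
reconstruction step (noise scoring, subset-size residuals, NNLS). The
deconvolution is therefore a per-gene weighted NNLS of the raw problem —
scale-free in both gene and type units — and in the noise-free case recovers
the true densities exactly up to a per-type scale (the inverse column sum),
which leaves all downstream correlation-based statistics untouched.

Voxels are independent by contract; all-zero voxels return zero densities
and zero residual. Both raw and expression-magnitude-normalized residuals
are available (`residual_summary`), since either convention is defensible
for judging regional fit quality.

## MRx3 details

* **Noise scoring** visits genes in id order and scores each by the change
  in total reconstruction error when its row joins the running unconstrained
  least-squares design (rank-one normal-equation updates, Cholesky solves,
  minimum-norm fallback on singular designs). The score is a function of the
  gene's rows and the design state; identical rows presented to an identical
  state score identically. NNLS-exact incremental scoring would be
  combinatorial; the unconstrained proxy is verified against full re-solves
  in the tests.
* **Pruning** keeps `round(0.9 · |G|)` genes; ties at the cutoff break by
  gene id (lexicographically last removed first).
* **Greedy selection** defines `Redund(i|∅) = 1` (the criterion is otherwise
  undefined on an empty set), gives constant rows zero relevance and zero
  correlation, and floors the redundancy divisor at 1e−12.
* **Subset size** — the residual for a candidate size is the reconstruction
  error of the *entire pruned pool* from densities fitted on the subset
  alone, so the curve falls as the subset gains information. The elbow is
  the point of maximum perpendicular distance to the endpoint chord after
  min-max normalization of both axes; ties and flat curves resolve to the
  smaller size, and a curve that ends above its start falls back to the
  global argmin with a warning.

## Surrogate nulls

Surrogate maps preserve the source map's value multiset and (approximately)
its variogram: permute → smooth with a row-normalized Gaussian distance
kernel → add a white-noise nugget → rank-remap onto the sorted source
values. Per surrogate, 20 log-spaced bandwidths × 5 nugget weights are
scanned and the candidate minimizing the relative squared discrepancy
between its binned variogram and the source's (25 equal-count bins) wins.
The nugget term matters: smoothing alone cannot restore short-range
variance, and without it worst-bin variogram deviations roughly double.

Bin-level variogram comparisons are only meaningful where bins are
statistically stable. At 60 regions (1770 dependent pairs) the 25-bin
empirical variogram of a single map realization jitters by tens of percent
— even surrogates drawn from the true generative process deviate ~50% in
the worst 25-quantile bin — so fidelity checks use 5 equal-count bins
(~350 pairs each), where the implemented surrogates stay within 20% of the
source while naive permutation fails by 40% or more.

Empirical p-values use the add-one correction (never exactly zero at finite
ensemble size); the null 95% interval is reported alongside, since
CI-exclusion and tail-probability conventions can disagree near the
boundary. Bonferroni correction is implemented as
`p_corr = min(1, p · N_tests)`, which reproduces the accept/reject decisions
of comparing p to α/N.

## Spectral embedding

Similarity is the reciprocal of correlation distance with distances clipped
at 1e−6 before inversion (perfectly correlated profiles would otherwise
divide by zero); min-max normalization runs over off-diagonal entries only,
leaving the diagonal at zero. If every off-diagonal distance is equal the
normalization is degenerate and all similarities are set to 1 with a
warning. Eigenvector signs are fixed by the nonnegative-sum rule with a
first-nonzero-positive tie-break; note that nontrivial Laplacian
eigenvectors sum to exactly zero, so their orientation rests on the
tie-break and is equivariant under type permutation only up to sign.

## Model selection

BIC uses the Gaussian likelihood at the MLE variance RSS/n with
`k = 1 + n_slopes` (intercept counted, σ² not), matching the common
regression-package convention; this convention is what makes BIC values
comparable across implementations and is recorded here because ladder
comparisons depend on it. Candidate pools keep `ceil(fraction · n)` features
(25% of cell types, 50% of a gene panel), which makes pools of 42 types and
24 genes land at 11 and 12. Collinear candidates are skipped at their rung
with a warning. Cross-validation shuffles regions into seeded folds, pools
out-of-fold predictions, and reports R² (possibly negative out of sample),
an F-test p, and a BIC built from the pooled out-of-fold log-likelihood with
the refit model's k — the exact CV-BIC construction is a package convention,
as there is no single standard.

## Gene sets

The top-|mean R| slice (`round(fraction · n)` genes, default 10%) splits by
sign into vulnerability and resilience gene sets; ties at the threshold
break by gene id. Contributing cell types require a positive (resp.
negative) mean correlation *and* at least one selection in the multivariate
models; the per-type differential-expression budget is
`ceil(|gene set| / n_types)` — the ceiling guarantees each type contributes
enough genes for the deduplicated union to reach the target size (e.g. a
277-gene target over 16 types gives 18 per type). Differential expression is
the row z-score of the column-normalized signature matrix; it is scale-free,
so it rewards type-specific expression, not absolute magnitude. Class-level
sets fill to 100 genes round-robin over member types' ranked lists.
Enrichment statistics are deliberately out of scope; the sets are exported
as plain-text lists for external tools.

## Determinism and problem sizes

Every stochastic step takes an explicit seed and derives sub-seeds from a
single generator, so whole-pipeline reruns are byte-identical (the run
manifest records per-file checksums). The test suite and the acceptance
script run the pipeline at desk scale — 60-region, 1440-voxel worlds,
300 genes, 12 types, 12 datasets, hundreds of surrogates, and 20-seed
recovery ensembles — chosen so the full validation battery completes in a
few minutes while keeping every stage's statistics meaningful at that scale.

## Known limitations

* Recovery rates at SNR 2 sit near their acceptance thresholds (≈90%); a
  12-type world with kernel-smoothed density fields has enough chance
  spatial correlation that an unplanted type occasionally outranks a weakly
  planted one. This is a property of the conditions, not a bug — the worked
  example in the README shows such a confound being correctly discounted by
  the surrogate test.
* The class-DE construction cannot distinguish class-shared expression from
  noise after row standardization; it recovers *type-specific* markers
  collected per class, which is also the regime the real signature data
  occupy.
* Mapping tables between dataset and atlas parcellations are inputs; the
  package does not attempt to reconstruct the manual region matching of any
  particular study.
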