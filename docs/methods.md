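# Methods

This note records the models, conventions and design choices behind
`histoharm`, in the spirit of a statistical software methods appendix.
It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Feature extraction

Each RGB patch (any size ≥ 8×8; 50×50 is the nominal tile size) yields
195 named features in a fixed order, `group_channel_descriptor`:

* **Histogram-signal features (27 × 3).** The 256-bin intensity
  histogram of each channel is treated as a 1-D signal and summarized
  by 27 canonical time-series descriptors (absolute energy, absolute
  sum of changes, Benford correlation, counts above/below mean,
  first locations of max/min, CID-CE without normalization, min, max,
  median, kurtosis, longest strikes above/below mean, mean absolute
  change, mean change, central mean second derivative, variance,
  variation coefficient, reoccurrence percentages and sums, skewness,
  unique-value ratio, standard deviation, sum). Population (n-divisor)
  variance/std; bias-corrected skewness/kurtosis; degenerate
  denominators (zero mean, zero digit-frequency variance) map to 0 so
  the pipeline stays total.
* **GLCM texture (4 × 3).** 256-level symmetric normalized
  co-occurrence matrix at offset distance 1, angle 0° (configurable);
  contrast, correlation, energy, homogeneity via scikit-image.
  Correlation of a zero-variance channel is 1 by convention.
* **Entropies (3 × 3).** Shannon entropy (base 2) and "simple" entropy
  (the same quantity in nats — a global definition was chosen since a
  neighborhood version is equally defensible) of the normalized
  intensity distribution, plus the sample entropy of the 256-length
  histogram signal with m = 2, r = 0.2·std, Chebyshev distance; both
  template lengths are counted over the first N−m windows
  (Richman–Moorman), so a constant signal gives exactly 0; if either
  template count is zero the value is capped (default 10).
* **Moments (31 × 3).** Raw spatial moments m_pq (p+q ≤ 3), 7 central,
  7 scale-normalized central, and the 7 Hu invariants per channel. An
  all-zero channel has undefined normalized/Hu moments; they are set
  to 0. Hu moments are invariant under proper rotations; under
  improper symmetries (transposition/reflection) hu7 flips sign by
  construction, which the tests acknowledge by comparing |hu7|.

The original feature set this package descends from cannot be
reconstructed positionally (its published importance plots imply ≥ 225
features with opaque positional names), so this canonical 195-feature
set is documented as the package's own definition.

## Scaling and splitting

Robust scaling maps x → (x − median)/IQR with linearly interpolated
quartiles; standard scaling maps x → (x − mean)/std with the population
divisor. Both are fit on training rows only. NaN cells are excluded
from fitting and become 0 after scaling (imputation at the fitted
location); zero-scale (constant) features map to 0 rather than raising.
The NaN-before-vs-after-scaling order is a documented package choice,
not an inferred intent. Splits are stratified on the label and
reproducible by seed.

## ComBat engine

Parametric empirical-Bayes ComBat, as in the canonical microarray
formulation and the Bioconductor `sva` implementation (against which
one test cross-checks the output to < 1e-4 on a small fixture):

1. least-squares fit of batch indicators plus optional dummy-coded
   biological covariates (rank-deficient designs raise a confounding
   error);
2. standardization by the pooled residual variance (n divisor over all
   samples); the intercept is the sample-size-weighted mean of batch
   means — there is **no reference batch**, so with two symmetric
   batches the recoverable additive effect is the batch *contrast*
   γ*₂ − γ*₁, and that is what recovery tests measure;
3. per-batch means and variances of the standardized data, shrunk by
   iterated conditional posterior means (convergence when the maximum
   relative change of γ*, δ* drops below 1e-4, capped at 100
   iterations); hyperparameters by method of moments across features
   (undefined with < 2 features, in which case shrinkage is disabled
   with a warning);
4. adjustment; constant features pass through untouched with a
   warning.

`delta_star_data` reports the multiplicative effect on the sd scale of
the original data (√δ*·σ̂), which is the scale on which a generative
δ = 2 is recovered. With `eb=False` the engine reduces to an exact
per-batch location/scale correction — the brute-force oracle tests
exploit this. Covariates are off by default for all pseudo-batch
harmonizations (nothing indicates the original design preserved them);
passing the class label as a covariate preserves class-mean separation,
which a test verifies on a class/batch-orthogonal simulation.

Models serialize to JSON so a training-time fit can harmonize new data
later; transform on the fitting data is bit-identical to the fit-time
output because it is the same deterministic code path.

## Pseudo-batch derivation

* **Atypical masks.** Four detectors (isolation forest; LOF with 20
  neighbors, novelty mode so the frozen detector can flag new rows;
  elliptic envelope; RBF one-class SVM with ν = contamination), default
  contamination 0.05. Selection: for each detector, drop its flagged
  rows, split the remainder 80/20 stratified (seeded), fit logistic
  regression, and score the MSE between predicted class-1 probabilities
  and the 0/1 labels on the held-out 20%; minimum wins, ties break by
  fixed method order, and a mask that removes an entire class
  disqualifies its method. Whether this MSE should be computed on
  training or held-out rows was an open question; the held-out choice
  is the conservative one.
* **Clusters.** Ward agglomerative clustering for k in 2..10; k
  maximizes the silhouette score with Calinski-Harabasz as
  tie-breaker. Singleton clusters are merged into the nearest-centroid
  cluster so every ComBat batch has ≥ 2 members. Held-out rows are
  assigned by nearest training centroid. On unimodal data the argmax-k
  is still returned (documented behavior; the silhouette column lets
  callers detect the situation).
* **Per-class clusters.** The cluster flow is run inside each class
  and rows are re-assembled in the original order. Applying the frozen
  per-class transforms to held-out rows requires the row's class: this
  mirrors the label-indexed double-harmonization design and is only
  usable where test labels are available for transformation; classes
  too small to cluster pass through with a warning.
* **Centers.** Concatenated per-center tables are harmonized with the
  center as the batch.

## Resampling

SMOTE interpolates synthetic minority points uniformly on segments
between a minority sample and one of its k = 5 nearest minority
neighbors (k is reduced with a warning for tiny classes); ENN then
removes any sample — original or synthetic, either class — whose 3
nearest neighbors majority-vote against its label, except that a class
is never emptied. Random undersampling subsamples majority classes to
the minority count without replacement. Resampling is applied to
training partitions only; synthetic row indices are reported for audit.

## Classifier

A numpy MLP: input → Dense(256) → ReLU → Dropout(0.2) → Dense(256) →
ReLU → Dropout(0.2) → Dense(2) → softmax. Elastic-net penalties
(default l1 = l2 = 1e-5, an undocumented constant chosen small) on
kernels, biases and activations (activity terms normalized per batch);
categorical cross-entropy; Adam at 1e-3 (community defaults for the
unstated optimizer); minibatch 32; at most 100 epochs. After 3 epochs
without validation-loss improvement the learning rate is multiplied by
0.25; 3 further flat epochs after a reduction stop training; the best
validation-loss weights are always restored. The 10% validation split
is stratified and seeded. Runs are bit-deterministic for a seed
(single-threaded; one generator drives initialization, shuffling and
dropout). A 256-unit width is the default; a width-equals-feature-count
variant is available by override since both appear in the lineage of
this design. The pipeline accepts any object with `fit`/`predict_proba`.

Metrics: per-class precision/recall, F-score as their harmonic mean,
balanced accuracy as the mean per-class recall, and the confusion
matrix.

## Pipeline and presets

`run_intra`: split → scale (fit on train) → optional outlier-mask
ComBat → optional resampling → optional cluster harmonization → MLP →
evaluation, with every fitted object applied frozen to the held-out
partition, and a machine-readable manifest (config + seed + library
versions) sufficient to replay the run. Leakage safety is enforced by
construction and audited by a poisoning test: running the pipeline with
the held-out partition's features replaced by garbage must leave every
train-fitted artifact bit-identical.

Presets `Configuration1..10` name block combinations studied with this
pipeline family. 1 (robust scaling only), 2 (standard + outlier ComBat
with the default detector, no MSE selection), 3 (2 + detector
selection), 6 (3 + SMOTENN) and 8 (6 + by-patch harmonization) follow
the documented glosses; 4, 5, 7, 9, 10 cannot be read unambiguously
from the source material and are best-effort reconstructions
(4 = standard + downsample, 5 = standard + SMOTENN, 7 = 5 + by-patch,
9 = 8 with by-patch-by-class, 10 = 5 with by-patch-by-class).

`run_multicenter` applies the per-center intra flow, pools the training
partitions, optionally ComBat-harmonizes with the center batch, trains
one classifier and reports held-out metrics per center. An honest
structural observation: because each center is standard-scaled on its
own training rows first, any per-feature affine center effect is
already removed before the inter-database ComBat step, whose fitted
batch effects on such synthetic shifts are numerically zero — the
harmonized-versus-not comparison then ties. The step earns its keep as
a safeguard against residual moment mismatches, and the multicenter
phenomenon proper is the collapse of a *single-center* model on
cross-center data versus the pooled harmonized model, which the
acceptance script measures.

## Synthetic data

`generate_feature_table` draws exactly from the ComBat generative model
(ε ~ N(0,1); per-batch γ drawn per feature from a stated Normal; δ a
stated sd-scale factor; a binary class covariate entering through Xβ on
the first half of the features, assigned independently of batch so
class/batch orthogonality is controllable). `generate_patches` renders
50×50 H&E-like tiles: eosin-pink textured background
(230,180,200 ± noise), hematoxylin-dark elliptical nucleus-like blobs
(90,60,130 ± noise) — dense for the malignant class, sparse for benign
— and, for border tiles, a white background band covering roughly half
the tile; center effects are per-channel affine intensity maps. The
palette is chosen for visual plausibility only and makes no biological
claim. `plant_outliers` shifts a seeded row subset by a constant
offset.

What this does *not* emulate: real stain chemistry and its nonlinear,
spatially structured variation; nuclear morphology beyond ellipses;
correlated center effects that are not per-feature affine; label
noise from imperfect annotation. Passing tests therefore demonstrate
that the machinery recovers planted location/scale structure and
behaves leakage-safely — not that any particular accuracy level will
transfer to real slides.

## Numerical choices and problem sizes

EB convergence 1e-4 / 100 iterations (matching the reference
implementation); quartiles by linear interpolation; population divisor
for scaling, ddof = 1 for per-batch standardized variances (again
matching the reference); detector contamination 0.05; LOF neighbors
20; k-range 2..10; SMOTE k = 5, ENN k = 3. Test and acceptance
simulations use a few hundred to two thousand samples with 10–100
features — sizes at which the planted effects are estimated to within
a few percent while the full suite runs in about a minute — and every
simulated condition is fixed by an explicit seed.

## Known limitations

* By-patch-by-class transformation of new data needs the class label,
  so it cannot be applied to truly unlabeled samples.
* ComBat corrects the first two moments per feature; rotational or
  higher-order batch effects are out of model.
* The non-parametric EB variant, longitudinal ComBat and covariance
  harmonization are out of scope.
* The preset mapping for configurations 4/5/7/9/10 is a documented
  reconstruction, not ground truth.
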