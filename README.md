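# histoharm

Batch-effect harmonization for histopathology patch classification.

Machine-learning models that classify benign versus malignant tissue
patches from H&E-stained slides degrade badly in the presence of
non-biological variability: slide-border tiles that mix tissue with
white background, staining differences between clusters of patches,
and systematic shifts between acquisition centers. `histoharm`
implements a feature-engineering pipeline that attacks this variability
with ComBat empirical-Bayes harmonization driven by *pseudo-batches* —
batch vectors derived computationally (outlier masks, unsupervised
cluster labels, per-class cluster labels) rather than read from
acquisition metadata — plus the surrounding machinery: feature
extraction, robust/standard scaling, class-imbalance resampling, an MLP
classifier, and leakage-safe train/test orchestration.

It is written for researchers in computational pathology and radiomics
who want a tested, reusable implementation of pseudo-batch ComBat
harmonization, and ships synthetic-data generators with known ground
truth so every claim is checkable without external image downloads.

## The model

For feature *g*, sample *j* in batch *i*, the measured value is modelled
as

    Y_ijg = α_g + X β_g + γ_ig + δ_ig ε_ijg ,      ε_ijg ~ N(0, σ_g²)

with additive (γ) and multiplicative (δ) batch effects. Fitting follows
the parametric empirical-Bayes recipe: feature-wise least squares for
α, β and batch means; standardization by the pooled residual variance;
per-batch location/scale estimates shrunk toward Normal / Inverse-Gamma
priors whose hyperparameters are estimated across features by the
method of moments, via iterated conditional posterior means; and the
adjustment

    Y*_ijg = σ_g / δ*_ig · (Z_ijg − γ*_ig) + α_g + X β_g .

The engine has strict fit/transform separation (a fitted `CombatModel`
serializes to JSON and applies frozen to held-out or future data) and
is verified in the test suite against the Bioconductor `sva::ComBat`
reference and against a brute-force location/scale oracle.

Pseudo-batches come from three sources:

* **atypical masks** — isolation forest, local outlier factor, elliptic
  envelope, or one-class SVM; the detector is chosen by the MSE of a
  downstream logistic-regression label classifier on detector-cleaned
  data;
* **cluster labels** — Ward agglomerative clustering with k chosen by
  silhouette score (ties: Calinski-Harabasz), applied to all samples
  ("by patch") or inside each class ("by patch by class");
* **acquisition centers** — for inter-database (multicenter)
  harmonization.

The classifier is a 2×256-unit ReLU MLP with dropout 0.2, elastic-net
regularization, Adam on minibatches of 32, learning-rate quartering
after 3 flat validation epochs and early stopping (any
`fit`/`predict_proba` estimator can be substituted).

## Worked example

```python
from histoharm import (generate_feature_table, plant_outliers, preset,
                       PipelineConfig, run_intra)

# a 600-patch feature table with a planted atypical cluster (15% of rows
# shifted by +3 on every feature) and 1:3 class imbalance
table, _ = generate_feature_table(
    n_per_batch=(600,), p=40, gamma_params=((0.0, 0.0),),
    delta_params=(1.0,), class_effect=0.8, class_frac=0.25, seed=5)
table, mask = plant_outliers(table, fraction=0.15, offset=3.0, seed=5)

baseline = PipelineConfig(scaling="standard", seed=5)
config6 = preset("Configuration6", seed=5)  # standard + outlier ComBat + SMOTENN

for name, cfg in [("baseline", baseline), ("Configuration6", config6)]:
    rep = run_intra(cfg, table)["reports"]["test"]
    print(f"{name:15s} test balanced accuracy = {rep.balanced_accuracy:.3f}  "
          f"recall(malignant) = {rep.recall['malignant']:.3f}")
```

prints

```
baseline        test balanced accuracy = 0.879  recall(malignant) = 0.796
Configuration6  test balanced accuracy = 0.938  recall(malignant) = 0.959
```

The baseline model is dragged down by the planted atypical cluster and
the class imbalance; adding outlier-mask ComBat harmonization and
SMOTE+ENN resampling recovers most of the lost minority-class recall.

There is also a CLI for shell use:

```sh
histoharm simulate patches --n 200 --seed 1 --out sim/
histoharm extract --manifest sim/manifest.csv --out features.parquet
histoharm run --table features.parquet --preset Configuration6 --seed 1 --out report.json
```

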