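"""Pseudo-batch derivation and harmonization flows.

Batch effects inside one dataset have no acquisition labels, so batch
vectors are derived computationally and fed to the ComBat engine:

* atypical/typical masks from unsupervised outlier detectors (border
  tiles mixing tissue and background behave as a separate batch);
* cluster labels from Ward agglomerative clustering with the number of
  clusters chosen by silhouette (ties: Calinski-Harabasz), applied to
  the whole set ("by patch") or inside each class ("by patch by
  class");
* acquisition-center labels for multicenter (inter-database)
  harmonization.

All operations preserve row count, order, metadata and feature names,
and every fitted object (detector, cluster centroids, ComBat model) can
be applied frozen to held-out data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.covariance import EllipticEnvelope
from sklearn.decomposition import PCA
from sklearn.ensemble import IsolationForest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import LocalOutlierFactor
from sklearn.svm import OneClassSVM

from .combat import CombatModel, combat_fit, combat_transform
from .table import FeatureTable

DETECTORS = ("isolation_forest", "lof", "elliptic_envelope", "ocsvm")


# --------------------------------------------------------------------------
# atypical-sample detection
# --------------------------------------------------------------------------

@dataclass
class AtypicalMask:
    """Per-sample atypicality flags plus the frozen detector."""

    mask: np.ndarray
    method: str
    params: dict
    estimator: object = None

    def apply(self, table: FeatureTable) -> np.ndarray:
        """Flag new rows with the frozen detector (no refitting)."""
        if self.estimator is None:
            raise ValueError("no fitted detector stored in this mask")
        return self.estimator.predict(table.matrix) == -1


def _make_detector(method: str, contamination: float, seed: int):
    if method == "isolation_forest":
        return IsolationForest(contamination=contamination, random_state=seed)
    if method == "lof":
        return LocalOutlierFactor(
            n_neighbors=20, contamination=contamination, novelty=True
        )
    if method == "elliptic_envelope":
        return EllipticEnvelope(contamination=contamination, random_state=seed)
    if method == "ocsvm":
        return OneClassSVM(kernel="rbf", nu=contamination, gamma="scale")
    raise ValueError(f"unknown detector {method!r}; choose from {DETECTORS}")


def detect_atypical(
    table: FeatureTable,
    method: str = "isolation_forest",
    contamination: float = 0.05,
    seed: int = 0,
) -> AtypicalMask:
    """Flag atypical rows of a standardized table (True = atypical)."""
    if not 0 < contamination < 0.5:
        raise ValueError("contamination must lie in (0, 0.5)")
    if table.n_samples < 10:
        raise ValueError("need at least 10 samples for outlier detection")
    est = _make_detector(method, contamination, seed)
    x = table.matrix
    est.fit(x)
    mask = est.predict(x) == -1
    return AtypicalMask(
        mask=mask,
        method=method,
        params={"contamination": contamination, "seed": seed},
        estimator=est,
    )


@dataclass
class DetectorReport:
    """Per-detector masks and downstream-classifier MSEs; one chosen."""

    masks: dict[str, AtypicalMask]
    mses: dict[str, float]
    chosen: str

    @property
    def chosen_mask(self) -> AtypicalMask:
        return self.masks[self.chosen]


def select_detector(
    table: FeatureTable,
    labels: np.ndarray,
    methods: tuple[str, ...] = DETECTORS,
    contamination: float = 0.05,
    seed: int = 0,
) -> DetectorReport:
    """Choose the detector whose atypical-free data best supports a
    logistic-regression label classifier.

    For each method: compute the mask, drop flagged rows, split the
    remainder 80/20 stratified (seeded), fit logistic regression on the
    80% and score the MSE between predicted class probabilities and the
    0/1 labels on the 20%.  The minimal-MSE method wins; ties break by
    the fixed order of ``methods``.  A mask that removes an entire class
    disqualifies its method.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("select_detector needs binary labels")
    y01 = (labels == classes[1]).astype(float)

    masks: dict[str, AtypicalMask] = {}
    mses: dict[str, float] = {}
    for method in methods:
        am = detect_atypical(table, method, contamination, seed)
        masks[method] = am
        keep = ~am.mask
        y_keep = y01[keep]
        if len(np.unique(y_keep)) < 2:
            warnings.warn(f"{method}: mask removes an entire class; disqualified")
            mses[method] = np.inf
            continue
        x_keep = table.matrix[keep]
        xtr, xte, ytr, yte = train_test_split(
            x_keep, y_keep, train_size=0.8, random_state=seed, stratify=y_keep
        )
        clf = LogisticRegression(max_iter=1000)
        clf.fit(xtr, ytr)
        p = clf.predict_proba(xte)[:, 1]
        mses[method] = float(np.mean((p - yte) ** 2))

    chosen = min(methods, key=lambda m: (mses[m], methods.index(m)))
    if not np.isfinite(mses[chosen]):
        raise ValueError("every detector removed an entire class")
    return DetectorReport(masks=masks, mses=mses, chosen=chosen)


def harmonize_atypical(
    table: FeatureTable,
    mask: np.ndarray | AtypicalMask,
    covariates: list[str] | None = None,
) -> tuple[FeatureTable, CombatModel | None, np.ndarray]:
    """ComBat with the two-level typical/atypical pseudo-batch vector."""
    m = mask.mask if isinstance(mask, AtypicalMask) else np.asarray(mask, dtype=bool)
    if len(m) != table.n_samples:
        raise ValueError("mask length must equal n_samples")
    n_aty = int(m.sum())
    if n_aty < 2 or (len(m) - n_aty) < 2:
        warnings.warn(
            "atypical/typical group with < 2 samples: identity transform"
        )
        return table.copy(), None, m
    batch = np.where(m, "atypical", "typical")
    model = combat_fit(table, batch, covariates)
    return combat_transform(model, table, batch), model, m


def apply_atypical(
    model: CombatModel | None, detector: AtypicalMask, table: FeatureTable
) -> FeatureTable:
    """Frozen-detector + frozen-ComBat application to held-out rows."""
    if model is None:
        return table.copy()
    mask = detector.apply(table)
    batch = np.where(mask, "atypical", "typical")
    return combat_transform(model, table, batch)


# --------------------------------------------------------------------------
# cluster pseudo-batches
# --------------------------------------------------------------------------

@dataclass
class ClusterBatch:
    """Cluster pseudo-batch labels with the k-selection score table."""

    labels: np.ndarray
    k: int
    scores: pd.DataFrame  # columns: k, silhouette, calinski_harabasz
    centroids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def assign(self, table: FeatureTable) -> np.ndarray:
        """Nearest-centroid cluster assignment for new rows."""
        if self.centroids is None:
            raise ValueError("no centroids stored")
        d = np.linalg.norm(
            table.matrix[:, None, :] - self.centroids[None, :, :], axis=2
        )
        return d.argmin(axis=1)


def find_optimal_k(
    table: FeatureTable, k_range: range = range(2, 11), seed: int = 0
) -> ClusterBatch:
    """Ward agglomerative clustering with k maximizing the silhouette
    score (ties broken by Calinski-Harabasz)."""
    ks = list(k_range)
    if not ks or min(ks) < 2 or max(ks) > table.n_samples - 1:
        raise ValueError(f"k_range must lie within [2, {table.n_samples - 1}]")
    x = table.matrix
    rows = []
    all_labels = {}
    for k in ks:
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(x)
        all_labels[k] = labels
        rows.append(
            {
                "k": k,
                "silhouette": silhouette_score(x, labels),
                "calinski_harabasz": calinski_harabasz_score(x, labels),
            }
        )
    scores = pd.DataFrame(rows)
    best = scores.sort_values(
        ["silhouette", "calinski_harabasz"], ascending=False, kind="stable"
    ).iloc[0]
    k = int(best["k"])
    labels = _merge_singletons(x, all_labels[k])
    k_eff = len(np.unique(labels))
    centroids = np.stack([x[labels == c].mean(axis=0) for c in range(k_eff)])
    return ClusterBatch(labels=labels, k=k_eff, scores=scores, centroids=centroids)


def _merge_singletons(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Merge clusters with < 2 members into the nearest-centroid cluster
    (ComBat requires >= 2 samples per batch), then relabel 0..k-1."""
    labels = labels.copy()
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        small = uniq[counts < 2]
        if len(small) == 0 or len(uniq) <= 1:
            break
        c = small[0]
        others = [u for u in uniq if u != c]
        centroids = np.stack([x[labels == u].mean(axis=0) for u in others])
        pt = x[labels == c].mean(axis=0)
        labels[labels == c] = others[
            int(np.linalg.norm(centroids - pt, axis=1).argmin())
        ]
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def harmonize_by_patch(
    table: FeatureTable,
    covariates: list[str] | None = None,
    k_range: range = range(2, 11),
    seed: int = 0,
) -> tuple[FeatureTable, CombatModel, ClusterBatch]:
    """ComBat over cluster pseudo-batches from :func:`find_optimal_k`."""
    cb = find_optimal_k(table, k_range, seed)
    model = combat_fit(table, cb.labels, covariates)
    return combat_transform(model, table, cb.labels), model, cb


def apply_by_patch(
    model: CombatModel, cb: ClusterBatch, table: FeatureTable
) -> FeatureTable:
    """Frozen cluster harmonization of held-out rows: nearest-centroid
    batch assignment, then frozen ComBat transform."""
    return combat_transform(model, table, cb.assign(table))


def harmonize_by_patch_by_class(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    covariates: list[str] | None = None,
    k_range: range = range(2, 11),
    seed: int = 0,
    min_class_size: int = 20,
) -> tuple[FeatureTable, dict]:
    """Cluster harmonization run independently inside each class;
    original row order preserved on re-assembly."""
    y = np.asarray(labels) if labels is not None else table.labels()
    if len(y) != table.n_samples:
        raise ValueError("labels length must equal n_samples")
    out = table.matrix
    models: dict = {}
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        sub = table.take(idx)
        if len(idx) < min_class_size or len(idx) <= max(k_range):
            warnings.warn(f"class {cls!r} too small to cluster: passed through")
            models[cls] = None
            continue
        harm, model, cb = harmonize_by_patch(sub, covariates, k_range, seed)
        out[idx] = harm.matrix
        models[cls] = (model, cb)
    return table.with_matrix(out), models


# --------------------------------------------------------------------------
# multicenter
# --------------------------------------------------------------------------

def harmonize_multicenter(
    tables: list[FeatureTable] | FeatureTable,
    covariates: list[str] | None = None,
) -> tuple[FeatureTable, CombatModel]:
    """ComBat with the acquisition center as the batch (inter-database
    harmonization).  Accepts a list of per-center tables (concatenated)
    or one table whose ``center`` metadata has >= 2 levels."""
    table = (
        FeatureTable.concat(tables)
        if isinstance(tables, (list, tuple))
        else tables
    )
    centers = table.meta["center"].to_numpy()
    if len(pd.unique(centers)) < 2:
        raise ValueError("multicenter harmonization needs >= 2 centers")
    model = combat_fit(table, centers, covariates)
    return combat_transform(model, table, centers), model


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

@dataclass
class PCAProjection:
    coordinates: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray


def pca_project(table: FeatureTable, n_components: int = 2) -> PCAProjection:
    """Project a standardized table onto its top principal components."""
    if n_components > table.n_features:
        raise ValueError("n_components exceeds n_features")
    pca = PCA(n_components=n_components, random_state=0)
    coords = pca.fit_transform(table.matrix)
    return PCAProjection(coords, pca.explained_variance_ratio_, pca.components_)
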