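"""Class-imbalance correction for the training partition.

Two strategies:

* :func:`smote_enn` — SMOTE oversampling of the minority class (new
  points interpolated uniformly on segments between a minority sample
  and one of its k nearest minority neighbours) followed by Edited
  Nearest Neighbours cleaning (samples whose 3-NN majority vote
  disagrees with their own label are removed, for all classes);
* :func:`random_undersample` — majority classes subsampled without
  replacement down to the minority count.

Resampling is only ever applied to training data; the pipeline enforces
this.  Synthetic row indices are reported so they can be audited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .table import FeatureTable


@dataclass
class BalanceResult:
    table: FeatureTable
    counts_before: dict
    counts_after: dict
    synthetic_indices: np.ndarray  # positions of synthetic rows in `table`


def _class_counts(y: np.ndarray) -> dict:
    uniq, counts = np.unique(y, return_counts=True)
    return {str(u): int(c) for u, c in zip(uniq, counts)}


def _smote_points(
    x_min: np.ndarray, n_new: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Interpolate n_new points on segments between minority neighbours."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)
    _, idx = nn.kneighbors(x_min)  # column 0 is the point itself
    base = rng.integers(0, len(x_min), size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    neigh = idx[base, pick]
    lam = rng.uniform(0.0, 1.0, size=(n_new, 1))
    return x_min[base] + lam * (x_min[neigh] - x_min[base])


def smote_enn(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    seed: int = 0,
    k_neighbors: int = 5,
    enn_neighbors: int = 3,
) -> BalanceResult:
    """SMOTE to parity, then ENN cleaning of the combined set."""
    y = np.asarray(labels) if labels is not None else table.labels()
    counts = _class_counts(y)
    if len(counts) < 2:
        raise ValueError("need >= 2 classes to balance")
    rng = np.random.default_rng(seed)
    x = table.matrix

    majority = max(counts, key=counts.get)
    n_max = counts[majority]

    new_rows, new_labels = [], []
    for cls, n_cls in counts.items():
        if n_cls >= n_max:
            continue
        k = k_neighbors
        if n_cls <= k:
            k = max(1, n_cls - 1)
            warnings.warn(
                f"minority class {cls!r} has {n_cls} samples; k reduced to {k}"
            )
        x_min = x[y.astype(str) == cls]
        pts = _smote_points(x_min, n_max - n_cls, k, rng)
        new_rows.append(pts)
        new_labels.extend([cls] * len(pts))

    n_orig = len(x)
    if new_rows:
        x_all = np.vstack([x] + new_rows)
        y_all = np.concatenate([y.astype(str), np.array(new_labels)])
    else:
        x_all, y_all = x, y.astype(str)
    synthetic = np.arange(n_orig, len(x_all))

    # ENN: remove any sample whose `enn_neighbors` nearest neighbours
    # (excluding itself) vote for a different class.
    nn = NearestNeighbors(n_neighbors=enn_neighbors + 1).fit(x_all)
    _, idx = nn.kneighbors(x_all)
    neigh_labels = y_all[idx[:, 1:]]
    agree = (neigh_labels == y_all[:, None]).sum(axis=1)
    keep = agree > enn_neighbors / 2.0

    # never empty a class entirely
    for cls in np.unique(y_all):
        if not keep[y_all == cls].any():
            keep[y_all == cls] = True
            warnings.warn(f"ENN would remove all of class {cls!r}; kept")

    keep_idx = np.flatnonzero(keep)
    meta_synth = pd.DataFrame(
        {
            "sample_id": [f"synthetic_{i}" for i in range(len(synthetic))],
            "label": new_labels,
        }
    )
    for col in table.meta.columns:
        if col not in meta_synth.columns:
            meta_synth[col] = "synthetic"
    meta_all = pd.concat([table.meta, meta_synth[table.meta.columns]],
                         ignore_index=True)
    data_all = pd.DataFrame(x_all, columns=table.feature_names)
    out = FeatureTable(
        data_all.iloc[keep_idx].reset_index(drop=True),
        meta_all.iloc[keep_idx].reset_index(drop=True),
    )
    out.meta["label"] = y_all[keep_idx]
    synth_kept = np.flatnonzero(np.isin(keep_idx, synthetic))
    return BalanceResult(
        table=out,
        counts_before=counts,
        counts_after=_class_counts(y_all[keep_idx]),
        synthetic_indices=synth_kept,
    )


def random_undersample(
    table: FeatureTable, labels: np.ndarray | None = None, seed: int = 0
) -> BalanceResult:
    """Subsample majority classes without replacement to minority size."""
    y = np.asarray(labels) if labels is not None else table.labels()
    counts = _class_counts(y)
    if len(counts) < 2:
        raise ValueError("need >= 2 classes to balance")
    n_min = min(counts.values())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in counts:
        idx = np.flatnonzero(y.astype(str) == cls)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    keep_idx = np.sort(np.concatenate(keep))
    out = table.take(keep_idx)
    return BalanceResult(
        table=out,
        counts_before=counts,
        counts_after=_class_counts(y[keep_idx]),
        synthetic_indices=np.array([], dtype=int),
    )
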