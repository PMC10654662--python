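"""Feature-table normalization and leakage-safe train/test splitting.

Two scalers are provided, both fit on training rows only and applied
with frozen parameters to held-out data:

* ``standard``: (x - mean) / std (population std, n divisor);
* ``robust``:  (x - median) / IQR with IQR = Q3 - Q1 under the
  linear-interpolation quartile convention.

NaN cells are ignored when fitting and become 0 after scaling (i.e. they
are imputed at the fitted location).  Degenerate features (zero scale)
map to 0 rather than raising, keeping the pipeline total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .table import FeatureTable


@dataclass
class ScalerModel:
    """Frozen per-feature location/scale parameters."""

    kind: str
    location: np.ndarray
    scale: np.ndarray
    feature_names: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kind": self.kind,
                    "location": self.location.tolist(),
                    "scale": self.scale.tolist(),
                    "feature_names": self.feature_names,
                }
            )
        )

    @staticmethod
    def from_json(path: str | Path) -> "ScalerModel":
        d = json.loads(Path(path).read_text())
        return ScalerModel(
            d["kind"], np.array(d["location"]), np.array(d["scale"]), d["feature_names"]
        )


@dataclass
class SplitSpec:
    """Stratified split specification (reproducible by seed)."""

    train_fraction: float = 0.7
    seed: int = 0
    stratify_on: str = "label"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def scaler_fit(table: FeatureTable, kind: str = "robust") -> ScalerModel:
    """Fit location/scale on the supplied (training) rows only."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to fit a scaler")
    x = table.matrix
    with np.errstate(all="ignore"):
        if kind == "standard":
            loc = np.nanmean(x, axis=0)
            scale = np.nanstd(x, axis=0)  # population divisor
        elif kind == "robust":
            loc = np.nanmedian(x, axis=0)
            q1 = np.nanpercentile(x, 25, axis=0)  # linear interpolation
            q3 = np.nanpercentile(x, 75, axis=0)
            scale = q3 - q1
        else:
            raise ValueError(f"unknown scaler kind {kind!r}")
    loc = np.where(np.isfinite(loc), loc, 0.0)
    scale = np.where(np.isfinite(scale), scale, 0.0)
    return ScalerModel(kind, loc, scale, table.feature_names)


def scaler_transform(model: ScalerModel, table: FeatureTable) -> FeatureTable:
    """(x - location) / scale; NaN -> 0; zero-scale features -> 0."""
    if table.feature_names != model.feature_names:
        raise ValueError("feature names do not match the fitted scaler")
    x = table.matrix
    safe = np.where(model.scale == 0, 1.0, model.scale)
    z = (x - model.location) / safe
    z[:, model.scale == 0] = 0.0
    z = np.nan_to_num(z, nan=0.0)
    return table.with_matrix(z)


def scaler_inverse_transform(model: ScalerModel, table: FeatureTable) -> FeatureTable:
    """Undo scaling for non-degenerate features (degenerate -> location)."""
    if table.feature_names != model.feature_names:
        raise ValueError("feature names do not match the fitted scaler")
    x = table.matrix * np.where(model.scale == 0, 0.0, model.scale) + model.location
    return table.with_matrix(x)


def stratified_split(
    table: FeatureTable, spec: SplitSpec
) -> tuple[FeatureTable, FeatureTable]:
    """Disjoint stratified partition; per-class proportions preserved
    within rounding; reproducible given the seed."""
    strat = table.meta[spec.stratify_on].to_numpy()
    classes, counts = np.unique(strat, return_counts=True)
    if (counts < 2).any():
        bad = classes[counts < 2]
        raise ValueError(f"stratification classes with a single sample: {bad}")
    idx = np.arange(table.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=strat,
        shuffle=True,
    )
    return table.take(np.sort(train_idx)), table.take(np.sort(test_idx))
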