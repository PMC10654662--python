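"""End-to-end orchestration of the harmonization pipeline.

A :class:`PipelineConfig` names which blocks are active: the scaler,
outlier-mask ComBat, the resampling strategy, cluster ("by patch")
harmonization and multicenter ComBat.  :func:`run_intra` executes the
single-dataset flow

    split -> scale -> [outlier ComBat] -> [balancing]
          -> [patch harmonization] -> train MLP -> evaluate

fitting every stage on the training partition only and applying frozen
parameters to the held-out partition.  :func:`run_multicenter` runs the
per-center flow, pools the training partitions, optionally applies
center-batch ComBat, trains a single classifier and reports held-out
metrics per center.

:func:`preset` provides named block combinations ("Configuration1" ..
"Configuration10") matching the configurations studied with this
pipeline; see the docstring for the mapping caveats.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .balance import random_undersample, smote_enn
from .combat import combat_transform
from .harmonize import (
    apply_atypical,
    apply_by_patch,
    detect_atypical,
    harmonize_atypical,
    harmonize_by_patch,
    harmonize_by_patch_by_class,
    harmonize_multicenter,
    select_detector,
)
from .model import build_mlp, evaluate, train_mlp
from .preprocess import SplitSpec, scaler_fit, scaler_transform, stratified_split
from .table import FeatureTable

SCALINGS = ("standard", "robust")
BALANCINGS = ("none", "smotenn", "downsample")
PATCH_HARMONIZATIONS = ("none", "bypatch", "bypatchbyclass")


@dataclass
class PipelineConfig:
    """One combination of pipeline blocks."""

    scaling: str = "standard"
    combat_outliers: bool = False
    detector_selection: bool = True
    detector: str = "isolation_forest"
    contamination: float = 0.05
    balancing: str = "none"
    patch_harmonization: str = "none"
    multicenter: bool = False
    split_fraction: float = 0.7
    seed: int = 0
    k_min: int = 2
    k_max: int = 10
    model_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scaling not in SCALINGS:
            raise ValueError(f"scaling must be one of {SCALINGS}")
        if self.balancing not in BALANCINGS:
            raise ValueError(f"balancing must be one of {BALANCINGS}")
        if self.patch_harmonization not in PATCH_HARMONIZATIONS:
            raise ValueError(
                f"patch_harmonization must be one of {PATCH_HARMONIZATIONS}"
            )
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        bal = [b for b in ("smotenn", "downsample") if d.pop(b, False)]
        if len(bal) > 1:
            raise ValueError("at most one balancing block may be active")
        if bal:
            if d.get("balancing", "none") not in ("none", bal[0]):
                raise ValueError("conflicting balancing settings")
            d["balancing"] = bal[0]
        return PipelineConfig(**d)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


_PRESETS: dict[str, dict] = {
    "Configuration1": {"scaling": "robust"},
    "Configuration2": {"scaling": "standard", "combat_outliers": True,
                       "detector_selection": False},
    "Configuration3": {"scaling": "standard", "combat_outliers": True},
    "Configuration4": {"scaling": "standard", "balancing": "downsample"},
    "Configuration5": {"scaling": "standard", "balancing": "smotenn"},
    "Configuration6": {"scaling": "standard", "combat_outliers": True,
                       "balancing": "smotenn"},
    "Configuration7": {"scaling": "standard", "balancing": "smotenn",
                       "patch_harmonization": "bypatch"},
    "Configuration8": {"scaling": "standard", "combat_outliers": True,
                       "balancing": "smotenn", "patch_harmonization": "bypatch"},
    "Configuration9": {"scaling": "standard", "combat_outliers": True,
                       "balancing": "smotenn",
                       "patch_harmonization": "bypatchbyclass"},
    "Configuration10": {"scaling": "standard", "balancing": "smotenn",
                        "patch_harmonization": "bypatchbyclass"},
}


def preset(name: str, **overrides) -> PipelineConfig:
    """Named block combinations Configuration1..Configuration10.

    1 = robust scaling only; 2 = standard + outlier ComBat with the
    default detector (no MSE-based selection); 3 = standard + outlier
    ComBat with detector selection; 6 = 3 + SMOTENN; 8 = 6 + by-patch
    harmonization.  Configurations 4/5/7/9/10 cannot be read
    unambiguously from the source material; they are best-effort
    reconstructions (4 = standard + downsample, 5 = standard + SMOTENN,
    7 = 5 + by-patch, 9 = 8 with by-patch-by-class, 10 = 5 with
    by-patch-by-class) consistent with the published narrative.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(_PRESETS)}")
    return PipelineConfig(**{**_PRESETS[name], **overrides})


def _run_manifest(config: PipelineConfig) -> dict:
    import sklearn

    return {
        "config": asdict(config),
        "histoharm_version": __version__,
        "numpy_version": np.__version__,
        "sklearn_version": sklearn.__version__,
    }


# --------------------------------------------------------------------------
# single-dataset flow
# --------------------------------------------------------------------------

def _fit_apply_intra(
    config: PipelineConfig, train: FeatureTable, test: FeatureTable
) -> tuple[FeatureTable, FeatureTable, dict]:
    """Shared fit-on-train / frozen-apply-to-test stages (scaling,
    outlier ComBat, balancing, patch harmonization)."""
    artifacts: dict = {}

    scaler = scaler_fit(train, config.scaling)
    train = scaler_transform(scaler, train)
    test = scaler_transform(scaler, test)
    artifacts["scaler"] = scaler

    if config.combat_outliers:
        if config.detector_selection:
            report = select_detector(
                train, train.labels(), contamination=config.contamination,
                seed=config.seed,
            )
            detector = report.chosen_mask
            artifacts["detector_report"] = report
        else:
            detector = detect_atypical(
                train, config.detector, config.contamination, config.seed
            )
        train, cb_model, _ = harmonize_atypical(train, detector)
        test = apply_atypical(cb_model, detector, test)
        artifacts["detector"] = detector
        artifacts["outlier_combat"] = cb_model

    if config.balancing == "smotenn":
        res = smote_enn(train, seed=config.seed)
        train = res.table
        artifacts["balance"] = res
    elif config.balancing == "downsample":
        res = random_undersample(train, seed=config.seed)
        train = res.table
        artifacts["balance"] = res

    k_range = range(config.k_min, min(config.k_max, train.n_samples - 1) + 1)
    if config.patch_harmonization == "bypatch":
        train, model, cb = harmonize_by_patch(train, k_range=k_range,
                                              seed=config.seed)
        test = apply_by_patch(model, cb, test)
        artifacts["patch_combat"] = (model, cb)
    elif config.patch_harmonization == "bypatchbyclass":
        train, models = harmonize_by_patch_by_class(
            train, k_range=k_range, seed=config.seed
        )
        test = _apply_by_patch_by_class(models, test)
        artifacts["patch_combat_by_class"] = models

    return train, test, artifacts


def _apply_by_patch_by_class(models: dict, test: FeatureTable) -> FeatureTable:
    """Frozen per-class cluster harmonization of held-out rows.

    The class-conditional transform requires the class of each row
    (this mirrors the label-indexed double harmonization design); rows
    of classes without a fitted model pass through.
    """
    y = test.labels()
    out = test.matrix
    for cls, entry in models.items():
        if entry is None:
            continue
        model, cb = entry
        idx = np.flatnonzero(y == cls)
        if len(idx) == 0:
            continue
        sub = test.take(idx)
        out[idx] = apply_by_patch(model, cb, sub).matrix
    return test.with_matrix(out)


def _train_and_report(
    config: PipelineConfig, train: FeatureTable, test: FeatureTable
) -> tuple[dict, dict]:
    spec = build_mlp(train.n_features, **config.model_overrides)
    clf, hist = train_mlp(spec, train, seed=config.seed)
    reports = {
        "train": evaluate(clf, train),
        "test": evaluate(clf, test),
    }
    return reports, {"model": clf, "history": hist, "spec": spec}


def run_intra(config: PipelineConfig, table: FeatureTable) -> dict:
    """Run the single-dataset pipeline; returns reports + artifacts +
    a machine-readable run manifest."""
    spec = SplitSpec(config.split_fraction, config.seed)
    train, test = stratified_split(table, spec)
    train, test, artifacts = _fit_apply_intra(config, train, test)
    reports, model_art = _train_and_report(config, train, test)
    artifacts.update(model_art)
    return {
        "reports": reports,
        "artifacts": artifacts,
        "manifest": _run_manifest(config),
    }


# --------------------------------------------------------------------------
# multicenter flow
# --------------------------------------------------------------------------

def run_multicenter(config: PipelineConfig, tables: list[FeatureTable]) -> dict:
    """Per-center intra flow, optional center-batch ComBat on the pooled
    training data, one classifier, per-center held-out reports."""
    if len(tables) < 2:
        raise ValueError("run_multicenter needs >= 2 datasets")
    names = tables[0].feature_names
    for t in tables[1:]:
        if t.feature_names != names:
            raise ValueError("feature names mismatch between datasets")

    trains, tests, centers = [], [], []
    artifacts: dict = {"per_center": {}}
    for t in tables:
        center = str(t.meta["center"].iloc[0])
        centers.append(center)
        split = SplitSpec(config.split_fraction, config.seed)
        tr, te = stratified_split(t, split)
        tr, te, art = _fit_apply_intra(
            PipelineConfig(
                scaling=config.scaling,
                combat_outliers=config.combat_outliers,
                detector_selection=config.detector_selection,
                detector=config.detector,
                contamination=config.contamination,
                balancing="none",              # balance after pooling
                patch_harmonization=config.patch_harmonization,
                seed=config.seed,
                k_min=config.k_min,
                k_max=config.k_max,
            ),
            tr,
            te,
        )
        trains.append(tr)
        tests.append(te)
        artifacts["per_center"][center] = art

    pooled = FeatureTable.concat(trains)
    if config.multicenter:
        pooled, mc_model = harmonize_multicenter(pooled)
        tests = [
            combat_transform(mc_model, te, te.meta["center"].to_numpy())
            for te in tests
        ]
        artifacts["multicenter_combat"] = mc_model

    if config.balancing == "smotenn":
        pooled = smote_enn(pooled, seed=config.seed).table
    elif config.balancing == "downsample":
        pooled = random_undersample(pooled, seed=config.seed).table

    spec = build_mlp(pooled.n_features, **config.model_overrides)
    clf, hist = train_mlp(spec, pooled, seed=config.seed)
    artifacts["model"], artifacts["history"] = clf, hist

    reports = {"train": evaluate(clf, pooled)}
    for center, te in zip(centers, tests):
        reports[f"test_{center}"] = evaluate(clf, te)
    return {
        "reports": reports,
        "artifacts": artifacts,
        "manifest": _run_manifest(config),
    }


def run_repeated(
    config: PipelineConfig, table: FeatureTable, repeats: int = 20
) -> pd.DataFrame:
    """Repeat run_intra over ``repeats`` split seeds; one row per run
    with train/test balanced accuracy (mean +/- SD is then a summary of
    split-to-split stability)."""
    rows = []
    for r in range(repeats):
        cfg = PipelineConfig(**{**asdict(config), "seed": config.seed + r})
        out = run_intra(cfg, table)
        rows.append(
            {
                "repeat": r,
                "seed": cfg.seed,
                "train_balanced_accuracy":
                    out["reports"]["train"].balanced_accuracy,
                "test_balanced_accuracy":
                    out["reports"]["test"].balanced_accuracy,
            }
        )
    return pd.DataFrame(rows)


def save_reports(out: dict, path: str | Path) -> None:
    """Write the reports + manifest of a run as JSON."""
    payload = {
        "manifest": out["manifest"],
        "reports": {k: v.to_dict() for k, v in out["reports"].items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))
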