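"""Synthetic data generators with known ground truth.

Two families of generators stand in for real histopathology datasets:

* :func:`generate_patches` — 50x50 H&E-like RGB patches.  Central
  patches are a textured eosin-pink field with hematoxylin-dark
  nucleus-like blobs (dense for the malignant class, sparse for
  benign); border patches additionally contain a white background band
  (the "atypical" morphology of slide-edge tiles).  Acquisition-center
  effects are per-channel affine intensity shifts.
* :func:`generate_feature_table` — feature tables drawn exactly from
  the ComBat generative model Y = alpha + X beta + gamma_i +
  delta_i * eps with eps ~ N(0,1), so additive/multiplicative batch
  parameters are known and recoverable.

Every generator is a pure function of its seed and parameters, and
returns a :class:`SyntheticTruth` recording everything that was
planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import PatchRecord
from .table import FeatureTable

#: H&E-like palette (visual plausibility only)
EOSIN_PINK = np.array([230.0, 180.0, 200.0])
HEMATOXYLIN_DARK = np.array([90.0, 60.0, 130.0])
BACKGROUND_WHITE = np.array([246.0, 244.0, 247.0])


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator."""

    seed: int
    labels: np.ndarray = field(default=None)      # type: ignore[assignment]
    regions: np.ndarray = field(default=None)     # type: ignore[assignment]
    centers: np.ndarray = field(default=None)     # type: ignore[assignment]
    center_shift: dict = field(default_factory=dict)
    center_scale: dict = field(default_factory=dict)
    batch: np.ndarray = field(default=None)       # type: ignore[assignment]
    gamma: np.ndarray = field(default=None)       # type: ignore[assignment]
    delta: np.ndarray = field(default=None)       # type: ignore[assignment]
    alpha: np.ndarray = field(default=None)       # type: ignore[assignment]
    beta: np.ndarray = field(default=None)        # type: ignore[assignment]
    planted_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


# --------------------------------------------------------------------------
# image patches
# --------------------------------------------------------------------------

def _draw_blob(img: np.ndarray, cy: float, cx: float, ry: float, rx: float,
               color: np.ndarray, rng: np.random.Generator) -> None:
    h, w, _ = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    img[inside] = color + rng.normal(0, 8, size=(int(inside.sum()), 3))


def _render_patch(label: str, region: str, size: int,
                  rng: np.random.Generator) -> np.ndarray:
    img = EOSIN_PINK + rng.normal(0, 12, size=(size, size, 3))
    # nucleus-like blobs: dense for malignant, sparse for benign
    n_blobs = rng.integers(12, 20) if label == "malignant" else rng.integers(2, 5)
    for _ in range(n_blobs):
        _draw_blob(
            img,
            cy=rng.uniform(0, size),
            cx=rng.uniform(0, size),
            ry=rng.uniform(2, 5),
            rx=rng.uniform(2, 5),
            color=HEMATOXYLIN_DARK,
            rng=rng,
        )
    if region == "border":
        # white background band covering roughly half the tile
        frac = rng.uniform(0.35, 0.6)
        band = int(frac * size)
        side = rng.integers(0, 4)
        white = BACKGROUND_WHITE + rng.normal(0, 3, size=img.shape)
        sl = {
            0: (slice(0, band), slice(None)),
            1: (slice(size - band, size), slice(None)),
            2: (slice(None), slice(0, band)),
            3: (slice(None), slice(size - band, size)),
        }[int(side)]
        img[sl] = white[sl]
    return img


def generate_patches(
    n: int = 200,
    class_probs: dict | None = None,
    border_frac: float = 0.1,
    centers: tuple[str, ...] = ("center0",),
    center_shift: dict | None = None,
    center_scale: dict | None = None,
    size: int = 50,
    seed: int = 0,
) -> tuple[list[PatchRecord], SyntheticTruth]:
    """Generate H&E-like RGB patches with known structure.

    ``border_frac`` of the patches get the border morphology (exact
    count, deterministic rounding).  ``center_shift``/``center_scale``
    map center name -> length-3 per-channel affine parameters applied as
    ``clip(scale * x + shift)``.
    """
    class_probs = class_probs or {"benign": 0.5, "malignant": 0.5}
    if not np.isclose(sum(class_probs.values()), 1.0) or not 0 <= border_frac < 1:
        raise ValueError("class_probs must sum to 1 and border_frac lie in [0,1)")
    center_shift = center_shift or {}
    center_scale = center_scale or {}
    rng = np.random.default_rng(seed)

    classes = list(class_probs)
    labels = rng.choice(classes, size=n, p=[class_probs[c] for c in classes])
    n_border = int(round(border_frac * n))
    regions = np.array(["central"] * n)
    regions[rng.choice(n, size=n_border, replace=False)] = "border"
    center_labels = np.array([centers[i % len(centers)] for i in range(n)])

    records = []
    for i in range(n):
        img = _render_patch(str(labels[i]), str(regions[i]), size, rng)
        shift = np.asarray(center_shift.get(center_labels[i], (0.0, 0.0, 0.0)))
        scale = np.asarray(center_scale.get(center_labels[i], (1.0, 1.0, 1.0)))
        img = np.clip(img * scale + shift, 0, 255).astype(np.uint8)
        records.append(
            PatchRecord(
                image=img,
                sample_id=f"patch_{i:05d}",
                label=str(labels[i]),
                center=str(center_labels[i]),
                region=str(regions[i]),
            )
        )
    truth = SyntheticTruth(
        seed=seed,
        labels=labels,
        regions=regions,
        centers=center_labels,
        center_shift={c: np.asarray(center_shift.get(c, (0.0, 0.0, 0.0))) for c in centers},
        center_scale={c: np.asarray(center_scale.get(c, (1.0, 1.0, 1.0))) for c in centers},
    )
    return records, truth


# --------------------------------------------------------------------------
# generative feature tables
# --------------------------------------------------------------------------

def generate_feature_table(
    n_per_batch: tuple[int, ...] = (200, 200),
    p: int = 100,
    alpha_sd: float = 1.0,
    gamma_params: tuple[tuple[float, float], ...] = ((0.0, 0.0), (1.5, 0.3)),
    delta_params: tuple[float, ...] = (1.0, 2.0),
    class_effect: float = 0.0,
    class_frac: float = 0.5,
    seed: int = 0,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Draw a table from Y = alpha + X beta + gamma_i + delta_i * eps.

    Per batch i, gamma_ig ~ N(mean_i, sd_i) and delta_ig is the fixed
    multiplicative (sd-scale) factor delta_params[i]; eps ~ N(0,1).
    A binary class covariate enters through X beta with beta_g =
    ``class_effect`` on the first half of the features, assigned
    independently of batch (orthogonal by construction).
    """
    if p < 10:
        raise ValueError("p must be >= 10")
    if min(n_per_batch) < 20:
        raise ValueError("each batch needs n >= 20")
    nb = len(n_per_batch)
    if len(gamma_params) != nb or len(delta_params) != nb:
        raise ValueError("gamma_params/delta_params must match n_per_batch")
    rng = np.random.default_rng(seed)
    n = int(sum(n_per_batch))

    alpha = rng.normal(0.0, alpha_sd, size=p)
    beta = np.zeros(p)
    beta[: p // 2] = class_effect
    gamma = np.stack(
        [rng.normal(mu, sd, size=p) if sd > 0 else np.full(p, mu)
         for mu, sd in gamma_params]
    )
    delta = np.asarray(delta_params, dtype=float)

    batch = np.concatenate(
        [np.full(k, i) for i, k in enumerate(n_per_batch)]
    )
    cls = (rng.random(n) < class_frac).astype(int)
    eps = rng.normal(0.0, 1.0, size=(n, p))
    y = alpha + cls[:, None] * beta + gamma[batch] + delta[batch, None] * eps

    meta = pd.DataFrame(
        {
            "sample_id": [f"sim_{i:05d}" for i in range(n)],
            "label": np.where(cls == 1, "malignant", "benign"),
            "batch": batch.astype(str),
        }
    )
    table = FeatureTable(
        pd.DataFrame(y, columns=[f"f{g}" for g in range(p)]), meta
    )
    truth = SyntheticTruth(
        seed=seed, labels=meta["label"].to_numpy(), batch=batch,
        gamma=gamma, delta=delta, alpha=alpha, beta=beta,
    )
    return table, truth


def plant_outliers(
    table: FeatureTable, fraction: float = 0.05, offset: float = 5.0, seed: int = 0
) -> tuple[FeatureTable, np.ndarray]:
    """Shift a random ``fraction`` of rows by ``offset`` on all features."""
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    n = table.n_samples
    k = int(round(fraction * n))
    idx = rng.choice(n, size=k, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    x = table.matrix
    x[mask] += offset
    return table.with_matrix(x), mask
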