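"""Per-patch feature extraction for H&E histopathology tiles.

Four feature groups are computed on each RGB patch and concatenated into
a single named vector of 195 values:

* 27 signal descriptors of each channel's 256-bin intensity histogram,
  treated as a 1-D signal (canonical time-series feature definitions),
  x3 channels = 81;
* 4 gray-level co-occurrence matrix (GLCM) statistics per channel
  (contrast, correlation, energy, homogeneity) = 12;
* 3 entropies per channel (Shannon, simple, sample entropy of the
  histogram signal) = 9;
* 31 image moments per channel (10 raw spatial, 7 central, 7 normalized
  central, 7 Hu invariants) = 93.

Feature names follow ``group_channel_descriptor`` (e.g.
``hist_R_minimum``, ``glcm_G_contrast``, ``mom_B_hu3``) and the ordering
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats as sstats
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import moments, moments_central, moments_hu, moments_normalized

from .table import FeatureTable

CHANNELS = ("R", "G", "B")


@dataclass
class PatchRecord:
    """One RGB patch image plus its metadata."""

    image: np.ndarray
    sample_id: str
    label: str = "unknown"
    center: str = "unknown"
    region: str = "unknown"

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"patch image must be HxWx3, got shape {img.shape}")
        if img.shape[0] < 8 or img.shape[1] < 8:
            raise ValueError("patch image must be at least 8x8 pixels")
        if img.min() < 0 or img.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.image = img.astype(np.uint8)


@dataclass
class FeatureVector:
    """Ordered named feature values for one patch."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")

    @property
    def nonfinite(self) -> list[str]:
        """Names of non-finite entries (flagged, never silently dropped)."""
        return [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]


# --------------------------------------------------------------------------
# histogram-signal descriptors
# --------------------------------------------------------------------------

def channel_histogram(image: np.ndarray, channel: str) -> np.ndarray:
    """256-bin intensity histogram of one channel; bins sum to H*W."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be HxWx3")
    try:
        idx = CHANNELS.index(channel)
    except ValueError:
        raise ValueError(f"channel must be one of {CHANNELS}") from None
    return np.bincount(img[:, :, idx].ravel().astype(np.int64), minlength=256)[:256]


_BENFORD = np.log10(1.0 + 1.0 / np.arange(1, 10))


def _leading_digit(x: np.ndarray) -> np.ndarray:
    """First significant decimal digit of |x| (0 for zero entries)."""
    ax = np.abs(np.nan_to_num(x).astype(float))
    out = np.zeros(len(ax), dtype=int)
    nz = ax > 0
    exp = np.floor(np.log10(ax[nz]))
    out[nz] = (ax[nz] / 10.0**exp).astype(int)
    return out


def _longest_strike(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def histogram_signal_features(hist: Sequence[float]) -> dict[str, float]:
    """The 27 signal descriptors of a histogram treated as a 1-D signal.

    Formulas follow the canonical time-series feature definitions these
    descriptor names come from; degenerate denominators (zero mean for
    the variation coefficient, zero digit-count variance for the Benford
    correlation) yield 0 so the pipeline stays total.
    """
    x = np.asarray(hist, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("histogram signal must be 1-D with length >= 2")
    if (x < 0).any():
        raise ValueError("histogram counts must be non-negative")
    n = len(x)
    diff = np.diff(x)
    mean = x.mean()
    std = x.std()  # population
    var = x.var()

    # reoccurrence bookkeeping
    uniq, counts = np.unique(x, return_counts=True)
    reocc = counts > 1
    n_reocc_points = int(counts[reocc].sum())

    # Benford: correlate observed leading-digit frequencies with log10(1+1/d)
    digits = _leading_digit(x)
    digit_freq = np.array([(digits == d).mean() for d in range(1, 10)])
    if digit_freq.std() == 0:
        benford = 0.0
    else:
        benford = float(np.corrcoef(digit_freq, _BENFORD)[0, 1])

    second = x[2:] - 2 * x[1:-1] + x[:-2]

    feats = {
        "absolute_energy": float(np.dot(x, x)),
        "abs_sum_changes": float(np.abs(diff).sum()),
        "benford_correlation": benford,
        "count_above_mean": int((x > mean).sum()),
        "count_below_mean": int((x < mean).sum()),
        "first_location_of_maximum": float(np.argmax(x)) / n,
        "first_location_of_minimum": float(np.argmin(x)) / n,
        "cid_ce": float(np.sqrt(np.dot(diff, diff))),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "median": float(np.median(x)),
        "kurtosis": float(sstats.kurtosis(x, fisher=True, bias=False)) if n > 3 and std > 0 else 0.0,
        "longest_strike_above_mean": _longest_strike(x > mean),
        "longest_strike_below_mean": _longest_strike(x < mean),
        "mean_abs_change": float(np.abs(diff).mean()),
        "mean_change": float((x[-1] - x[0]) / (n - 1)),
        "mean_second_derivative_central": float(second.mean() / 2.0) if n > 2 else 0.0,
        "variance": float(var),
        "variation_coefficient": float(std / mean) if mean != 0 else 0.0,
        "pct_reoccurring_points": n_reocc_points / n,
        "pct_reoccurring_values": float(reocc.sum() / len(uniq)),
        "skewness": float(sstats.skew(x, bias=False)) if n > 2 and std > 0 else 0.0,
        "ratio_value_number_to_length": len(uniq) / n,
        "standard_deviation": float(std),
        "sum_reoccurring_points": float((uniq[reocc] * counts[reocc]).sum()),
        "sum_reoccurring_values": float(uniq[reocc].sum()),
        "sum_values": float(x.sum()),
    }
    return feats


HIST_DESCRIPTORS = list(histogram_signal_features(np.arange(4)).keys())


# --------------------------------------------------------------------------
# GLCM texture
# --------------------------------------------------------------------------

GLCM_PROPS = ("contrast", "correlation", "energy", "homogeneity")


def glcm_features(
    image: np.ndarray, distance: int = 1, angle_deg: float = 0.0
) -> dict[str, float]:
    """Contrast/correlation/energy/homogeneity per channel.

    A 256-level symmetric normalized co-occurrence matrix is built at the
    given offset.  A zero-variance (constant) channel takes correlation 1
    by convention.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be HxWx3")
    if img.shape[0] < 2 and img.shape[1] < 2:
        raise ValueError("image too small for co-occurrence analysis")
    out: dict[str, float] = {}
    for ci, ch in enumerate(CHANNELS):
        glcm = graycomatrix(
            img[:, :, ci].astype(np.uint8),
            distances=[distance],
            angles=[np.deg2rad(angle_deg)],
            levels=256,
            symmetric=True,
            normed=True,
        )
        for prop in GLCM_PROPS:
            out[f"glcm_{ch}_{prop}"] = float(graycoprops(glcm, prop)[0, 0])
    return out


# --------------------------------------------------------------------------
# entropies
# --------------------------------------------------------------------------

def shannon_entropy(channel: np.ndarray, base: float = 2.0) -> float:
    """Entropy of the normalized 256-bin intensity distribution."""
    counts = np.bincount(np.asarray(channel).ravel().astype(np.int64), minlength=256)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum() + 0.0)


def sample_entropy(signal: Sequence[float], m: int = 2, r_factor: float = 0.2,
                   cap: float = 10.0) -> float:
    """SampEn = -ln(A/B) with template length ``m``, Chebyshev distance
    and tolerance ``r = r_factor * std(signal)``.

    Self-matches are excluded.  If A or B is zero the value is capped at
    ``cap`` (perfectly regular signals give 0: every template matches).
    """
    x = np.asarray(signal, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ValueError("signal too short for sample entropy")
    r = r_factor * x.std()

    def _count(mm: int) -> int:
        # both template lengths use the first n-m windows (the standard
        # convention), so a perfectly regular signal gives A/B = 1
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
        nt = len(templ)
        mask = ~np.eye(nt, dtype=bool)
        return int((d[mask] <= r).sum())

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return float(cap)
    return float(-np.log(a / b))


def entropy_features(image: np.ndarray, sampen_cap: float = 10.0) -> dict[str, float]:
    """Per channel: Shannon (base-2) entropy, simple (natural-log)
    entropy, and sample entropy of the 256-bin histogram signal."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be HxWx3")
    out: dict[str, float] = {}
    for ci, ch in enumerate(CHANNELS):
        plane = img[:, :, ci]
        hist = channel_histogram(img, ch)
        out[f"ent_{ch}_shannon"] = shannon_entropy(plane, base=2.0)
        out[f"ent_{ch}_simple"] = shannon_entropy(plane, base=np.e)
        out[f"ent_{ch}_sample"] = sample_entropy(hist, cap=sampen_cap)
    return out


# --------------------------------------------------------------------------
# moments
# --------------------------------------------------------------------------

_RAW_IDX = [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3)]
_CEN_IDX = [(2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3)]


def moments_features(image: np.ndarray) -> dict[str, float]:
    """Raw, central, normalized-central and Hu moments per channel.

    An all-zero channel has m00 = 0, leaving normalized and Hu moments
    undefined; those are set to 0 by convention.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be HxWx3")
    out: dict[str, float] = {}
    for ci, ch in enumerate(CHANNELS):
        plane = img[:, :, ci].astype(float)
        m = moments(plane, order=3)
        for p, q in _RAW_IDX:
            out[f"mom_{ch}_m{p}{q}"] = float(m[p, q])
        if m[0, 0] == 0:
            for p, q in _CEN_IDX:
                out[f"mom_{ch}_mu{p}{q}"] = 0.0
                out[f"mom_{ch}_nu{p}{q}"] = 0.0
            for k in range(7):
                out[f"mom_{ch}_hu{k + 1}"] = 0.0
            continue
        mu = moments_central(plane, order=3)
        nu = moments_normalized(mu, order=3)
        hu = moments_hu(nu)
        for p, q in _CEN_IDX:
            out[f"mom_{ch}_mu{p}{q}"] = float(mu[p, q])
            out[f"mom_{ch}_nu{p}{q}"] = float(nu[p, q])
        for k in range(7):
            out[f"mom_{ch}_hu{k + 1}"] = float(hu[k])
    return out


# --------------------------------------------------------------------------
# full vector / table
# --------------------------------------------------------------------------

def extract_features(
    patch: PatchRecord, glcm_distance: int = 1, glcm_angle: float = 0.0
) -> FeatureVector:
    """Concatenate the four feature groups into the 195-value vector."""
    img = patch.image
    vals: list[float] = []
    names: list[str] = []
    for ch in CHANNELS:
        hist = channel_histogram(img, ch)
        for k, v in histogram_signal_features(hist).items():
            names.append(f"hist_{ch}_{k}")
            vals.append(v)
    for k, v in glcm_features(img, glcm_distance, glcm_angle).items():
        names.append(k)
        vals.append(v)
    for k, v in entropy_features(img).items():
        names.append(k)
        vals.append(v)
    for k, v in moments_features(img).items():
        names.append(k)
        vals.append(v)
    return FeatureVector(np.array(vals), names)


def extract_table(
    patches: Sequence[PatchRecord], glcm_distance: int = 1, glcm_angle: float = 0.0
) -> FeatureTable:
    """Extract features for a batch of patches into a FeatureTable."""
    rows = []
    names: list[str] | None = None
    meta = []
    for p in patches:
        fv = extract_features(p, glcm_distance, glcm_angle)
        if names is None:
            names = fv.names
        rows.append(fv.values)
        meta.append(
            {"sample_id": p.sample_id, "label": p.label, "center": p.center,
             "region": p.region}
        )
    return FeatureTable(pd.DataFrame(np.array(rows), columns=names), pd.DataFrame(meta))


def read_manifest(
    manifest_path: str | Path, root: str | Path | None = None
) -> list[PatchRecord]:
    """Load patches listed in a manifest CSV.

    Columns: ``sample_id, path, label[, center, region]``; paths are
    resolved relative to ``root`` (default: the manifest's directory).
    """
    manifest_path = Path(manifest_path)
    root = Path(root) if root is not None else manifest_path.parent
    df = pd.read_csv(manifest_path)
    records = []
    for _, row in df.iterrows():
        img = np.asarray(Image.open(root / row["path"]).convert("RGB"))
        records.append(
            PatchRecord(
                image=img,
                sample_id=str(row["sample_id"]),
                label=str(row.get("label", "unknown")),
                center=str(row.get("center", "unknown")),
                region=str(row.get("region", "unknown")),
            )
        )
    return records
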