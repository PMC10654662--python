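"""ComBat empirical-Bayes batch-effect harmonization.

The location/scale model for feature g, sample j of batch i is

    Y_ijg = alpha_g + X beta_g + gamma_ig + delta_ig * eps_ijg

with additive (gamma) and multiplicative (delta) site effects.  Fitting
follows the canonical parametric empirical-Bayes procedure: (1) a least
squares fit of the feature-wise linear model with batch indicators and
optional biological covariates; (2) standardization by the pooled
residual variance; (3) per-batch location/scale estimates shrunk toward
normal / inverse-gamma priors whose hyperparameters are estimated across
features by the method of moments, via iterated conditional posterior
means; (4) adjustment removing the shrunk batch effects.

There is no reference batch: the intercept is the sample-size-weighted
mean of the per-batch means, so batch effects are expressed
symmetrically.  Fit and transform are strictly separated; a fitted
:class:`CombatModel` can be serialized and applied to held-out data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .table import FeatureTable

EB_CONVERGENCE = 1e-4
EB_MAX_ITER = 100


class ConfoundingError(ValueError):
    """Batch and covariates are perfectly collinear."""


def _batch_onehot(batch: np.ndarray, levels: list) -> np.ndarray:
    return np.column_stack([(batch == lv).astype(float) for lv in levels])


def build_design_matrix(
    meta: pd.DataFrame, batch: np.ndarray, covariates: list[str] | None = None
) -> pd.DataFrame:
    """Batch indicator columns plus dummy-coded biological covariates.

    Raises :class:`ConfoundingError` if the design is rank deficient
    (a covariate perfectly confounded with batch).
    """
    batch = np.asarray(batch)
    levels = sorted(pd.unique(batch).tolist(), key=str)
    design = pd.DataFrame(
        _batch_onehot(batch, levels), columns=[f"batch_{lv}" for lv in levels]
    )
    for cov in covariates or []:
        dummies = pd.get_dummies(
            meta[cov].reset_index(drop=True), prefix=cov, drop_first=True, dtype=float
        )
        design = pd.concat([design, dummies], axis=1)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ConfoundingError(
            "design matrix is rank deficient: a covariate is confounded with batch"
        )
    return design


def _covariate_matrix(
    meta: pd.DataFrame, covariates: list[str], columns: list[str]
) -> np.ndarray:
    """Dummy matrix for new data using the fit-time covariate columns."""
    if not covariates:
        return np.zeros((len(meta), 0))
    parts = pd.DataFrame(index=range(len(meta)))
    for cov in covariates:
        dummies = pd.get_dummies(
            meta[cov].reset_index(drop=True), prefix=cov, dtype=float
        )
        parts = pd.concat([parts, dummies], axis=1)
    out = np.zeros((len(meta), len(columns)))
    for k, col in enumerate(columns):
        if col in parts.columns:
            out[:, k] = parts[col].to_numpy()
    return out


@dataclass
class CombatModel:
    """Frozen ComBat fit: everything needed to adjust new data."""

    batch_levels: list
    feature_names: list[str]
    grand_mean: np.ndarray          # alpha_g (weighted across batches), (p,)
    beta_cov: np.ndarray            # covariate coefficients, (c, p)
    covariates: list[str]
    covariate_columns: list[str]
    var_pooled: np.ndarray          # sigma_g^2, (p,)
    gamma_star: np.ndarray          # (B, p), standardized scale
    delta_star: np.ndarray          # (B, p), standardized variance scale
    gamma_hat: np.ndarray
    delta_hat: np.ndarray
    gamma_bar: np.ndarray = field(default=None)  # type: ignore[assignment]
    t2: np.ndarray = field(default=None)         # type: ignore[assignment]
    a_prior: np.ndarray = field(default=None)    # type: ignore[assignment]
    b_prior: np.ndarray = field(default=None)    # type: ignore[assignment]
    eb: bool = True

    # ------------------------------------------------------------ data scale
    @property
    def gamma_star_data(self) -> np.ndarray:
        """Additive batch effects on the original data scale, (B, p)."""
        return self.gamma_star * np.sqrt(self.var_pooled)

    @property
    def delta_star_data(self) -> np.ndarray:
        """Multiplicative (sd-scale) batch effects on the data scale."""
        return np.sqrt(self.delta_star) * np.sqrt(self.var_pooled)

    # ------------------------------------------------------------------- io
    def to_json(self, path: str | Path) -> None:
        d = {
            "batch_levels": [str(b) for b in self.batch_levels],
            "feature_names": self.feature_names,
            "covariates": self.covariates,
            "covariate_columns": self.covariate_columns,
            "eb": self.eb,
        }
        for arr in ("grand_mean", "beta_cov", "var_pooled", "gamma_star",
                    "delta_star", "gamma_hat", "delta_hat", "gamma_bar", "t2",
                    "a_prior", "b_prior"):
            v = getattr(self, arr)
            d[arr] = None if v is None else np.asarray(v).tolist()
        Path(path).write_text(json.dumps(d))

    @staticmethod
    def from_json(path: str | Path) -> "CombatModel":
        d = json.loads(Path(path).read_text())
        kw = {
            "batch_levels": d["batch_levels"],
            "feature_names": d["feature_names"],
            "covariates": d["covariates"],
            "covariate_columns": d["covariate_columns"],
            "eb": d["eb"],
        }
        for arr in ("grand_mean", "beta_cov", "var_pooled", "gamma_star",
                    "delta_star", "gamma_hat", "delta_hat", "gamma_bar", "t2",
                    "a_prior", "b_prior"):
            kw[arr] = None if d[arr] is None else np.array(d[arr])
        # an empty covariate block loses its (0, p) shape through JSON
        kw["beta_cov"] = kw["beta_cov"].reshape(
            len(d["covariate_columns"]), len(d["feature_names"])
        )
        return CombatModel(**kw)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a, b,
            conv=EB_CONVERGENCE, max_iter=EB_MAX_ITER):
    """Iterated conditional posterior means for one batch's (gamma*, delta*)."""
    n = z_batch.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            change = max(
                np.nanmax(np.abs(g_new - g_old) / np.abs(g_old)),
                np.nanmax(np.abs(d_new - d_old) / np.abs(d_old)),
            )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_fit(
    table: FeatureTable,
    batch: np.ndarray,
    covariates: list[str] | None = None,
    eb: bool = True,
) -> CombatModel:
    """Fit the ComBat model on ``table`` with per-sample ``batch`` labels.

    With ``eb=False`` the EB shrinkage is disabled: the per-batch sample
    estimates are used directly (gamma* = gamma_hat, delta* = delta_hat),
    reducing the adjustment to a per-batch location/scale correction.
    """
    covariates = covariates or []
    batch = np.asarray(batch)
    if len(batch) != table.n_samples:
        raise ValueError("batch vector length must equal n_samples")
    levels = sorted(pd.unique(batch).tolist(), key=str)
    if len(levels) < 2:
        raise ValueError("ComBat requires at least 2 batches")
    counts = {lv: int((batch == lv).sum()) for lv in levels}
    if min(counts.values()) < 2:
        raise ValueError(f"every batch needs >= 2 samples, got {counts}")

    design_df = build_design_matrix(table.meta, batch, covariates)
    design = design_df.to_numpy()
    n, p = table.n_samples, table.n_features
    if n <= design.shape[1]:
        raise ValueError("need more samples than design columns")
    nb = len(levels)
    y = table.matrix

    b_hat, *_ = np.linalg.lstsq(design, y, rcond=None)
    sizes = np.array([counts[lv] for lv in levels], dtype=float)
    grand_mean = (sizes / n) @ b_hat[:nb]
    beta_cov = b_hat[nb:]

    resid = y - design @ b_hat
    var_pooled = (resid**2).mean(axis=0)  # n divisor over all samples
    constant = var_pooled == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) passed through unadjusted"
        )

    cov_cols = list(design_df.columns[nb:])
    x_cov = design[:, nb:]
    sd = np.sqrt(np.where(constant, 1.0, var_pooled))
    stand_mean = grand_mean + x_cov @ beta_cov
    z = (y - stand_mean) / sd

    gamma_hat = np.zeros((nb, p))
    delta_hat = np.zeros((nb, p))
    for i, lv in enumerate(levels):
        zi = z[batch == lv]
        gamma_hat[i] = zi.mean(axis=0)
        delta_hat[i] = zi.var(axis=0, ddof=1)

    model = CombatModel(
        batch_levels=levels,
        feature_names=table.feature_names,
        grand_mean=grand_mean,
        beta_cov=beta_cov,
        covariates=covariates,
        covariate_columns=cov_cols,
        var_pooled=var_pooled,
        gamma_star=gamma_hat.copy(),
        delta_star=delta_hat.copy(),
        gamma_hat=gamma_hat,
        delta_hat=delta_hat,
        eb=eb,
    )
    if not eb:
        return model
    if p < 2:
        warnings.warn("fewer than 2 features: EB moments undefined, "
                      "falling back to no shrinkage")
        model.eb = False
        return model

    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    m = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2

    gamma_star = np.zeros_like(gamma_hat)
    delta_star = np.zeros_like(delta_hat)
    for i, lv in enumerate(levels):
        if not np.isfinite(a_prior[i]) or not np.isfinite(b_prior[i]):
            # degenerate prior (identical delta_hat across features)
            gamma_star[i], delta_star[i] = gamma_hat[i], delta_hat[i]
            continue
        gamma_star[i], delta_star[i] = _it_sol(
            z[batch == lv], gamma_hat[i], delta_hat[i],
            gamma_bar[i], t2[i], a_prior[i], b_prior[i],
        )
    model.gamma_star, model.delta_star = gamma_star, delta_star
    model.gamma_bar, model.t2 = gamma_bar, t2
    model.a_prior, model.b_prior = a_prior, b_prior
    return model


def combat_transform(
    model: CombatModel, table: FeatureTable, batch: np.ndarray
) -> FeatureTable:
    """Remove the fitted batch effects from ``table``.

    Y* = sigma_g / delta*_ig * (Z_ijg - gamma*_ig) + alpha_g + X beta_g.
    Deterministic; metadata unchanged; unseen batch levels raise.
    """
    if table.feature_names != model.feature_names:
        raise ValueError("feature names do not match the fitted model")
    batch = np.asarray(batch)
    if len(batch) != table.n_samples:
        raise ValueError("batch vector length must equal n_samples")
    seen = set(map(str, model.batch_levels))
    unseen = {str(b) for b in pd.unique(batch)} - seen
    if unseen:
        raise ValueError(f"batch level(s) not present at fit time: {sorted(unseen)}")

    y = table.matrix
    constant = model.var_pooled == 0
    sd = np.sqrt(np.where(constant, 1.0, model.var_pooled))
    x_cov = _covariate_matrix(table.meta, model.covariates, model.covariate_columns)
    stand_mean = model.grand_mean + x_cov @ model.beta_cov
    z = (y - stand_mean) / sd

    out = np.empty_like(y)
    level_index = {str(lv): i for i, lv in enumerate(model.batch_levels)}
    for lv in pd.unique(batch):
        i = level_index[str(lv)]
        rows = batch == lv
        adj = (z[rows] - model.gamma_star[i]) / np.sqrt(model.delta_star[i])
        out[rows] = adj * sd + stand_mean[rows]
    out[:, constant] = y[:, constant]
    return table.with_matrix(out)
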