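"""Batch-effect removal: empirical-Bayes ComBat and SVD component filtering.

ComBat models each feature g in batch i as

    Y_ijg = alpha_g + gamma_ig + delta_ig * eps_ijg,    eps ~ N(0, sigma_g^2)

an additive (location) plus multiplicative (scale) batch effect on top of a
feature-wide mean/variance.  Per-batch effects are estimated on standardized
data and shrunk across features with empirical-Bayes priors — normal on the
location effects, inverse-gamma on the squared scale effects — with
hyperparameters set by the method of moments.  The parametric posterior
means solve a coupled fixed point, iterated to tolerance.  No biological
covariates enter the model: the downstream validation is unsupervised, and
conditioning on class labels would leak them into the correction.

The SVD route z-scores the feature matrix, decomposes it, tests every
principal-component score vector for association with each batch variable
(one-way ANOVA), removes components with p below a threshold (default
0.001), and reconstructs the matrix without them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComBatModel",
    "SVDCorrection",
    "combat_fit",
    "combat_apply",
    "combat",
    "svd_correct",
]


@dataclass
class ComBatModel:
    """Fitted ComBat parameters (all per feature, batch-indexed where noted)."""

    batch_col: str
    feature_cols: list[str]
    batches: list[str]
    alpha: pd.Series  # grand mean
    pooled_sd: pd.Series
    gamma_hat: pd.DataFrame  # raw per-batch location (batches x features)
    delta_hat: pd.DataFrame  # raw per-batch squared scale
    gamma_star: pd.DataFrame  # EB-shrunk location
    delta_star: pd.DataFrame  # EB-shrunk squared scale (> 0)
    gamma_bar: pd.Series  # per-batch normal-prior mean
    tau2: pd.Series  # per-batch normal-prior variance
    a_prior: pd.Series  # per-batch inverse-gamma shape
    b_prior: pd.Series  # per-batch inverse-gamma rate
    mode: str = "parametric"
    constant_features: list[str] = field(default_factory=list)


def _aprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2 if s2 > 0 else np.inf


def _bprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2 if s2 > 0 else np.inf


def _parametric_posterior(
    z: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a: float,
    b: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-point iteration for the conditional posterior means of one batch.

    ``z`` is the (n_i x G) standardized data of the batch.
    """
    n = z.shape[0]
    gamma = gamma_hat.copy()
    delta = delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n * tau2 * gamma_hat + delta * gamma_bar) / (n * tau2 + delta)
        ssq = ((z - gamma_new) ** 2).sum(axis=0)
        delta_new = (2 * b + ssq) / (n + 2 * a - 2)
        change = max(
            np.max(np.abs(gamma_new - gamma) / np.maximum(np.abs(gamma), 1e-12)),
            np.max(np.abs(delta_new - delta) / np.maximum(np.abs(delta), 1e-12)),
        )
        gamma, delta = gamma_new, delta_new
        if change < tol:
            break
    return gamma, delta


def _nonparametric_posterior(
    z: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo empirical prior: weight every other feature's raw estimates
    by the likelihood of this feature's data under them."""
    n, g = z.shape
    gamma_star = np.empty(g)
    delta_star = np.empty(g)
    for j in range(g):
        gh = np.delete(gamma_hat, j)
        dh = np.delete(delta_hat, j)
        resid2 = ((z[:, j][:, None] - gh[None, :]) ** 2).sum(axis=0)
        log_l = -n / 2 * np.log(2 * np.pi * dh) - resid2 / (2 * dh)
        w = np.exp(log_l - log_l.max())
        w_sum = w.sum()
        gamma_star[j] = float((w * gh).sum() / w_sum)
        delta_star[j] = float((w * dh).sum() / w_sum)
    return gamma_star, delta_star


def combat_fit(
    table: pd.DataFrame,
    feature_cols: list[str],
    batch_col: str = "batch",
    mode: str = "parametric",
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ComBatModel:
    """Fit the ComBat location-scale model on a feature table.

    Requires at least two batches with at least two samples each.  Features
    with zero pooled variance cannot be standardized; they are excluded from
    the model and passed through uncorrected by :func:`combat_apply`.
    """
    if mode not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = table[batch_col].astype(str)
    batches = list(pd.unique(labels))
    if len(batches) < 2:
        raise ValueError("ComBat needs at least 2 batches")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"every batch needs >= 2 samples; offending: {sorted(small.index)}"
        )
    y = table[feature_cols].to_numpy(dtype=float)
    n, _ = y.shape
    onehot = np.stack([(labels == b).to_numpy() for b in batches], axis=1).astype(float)
    n_per = onehot.sum(axis=0)
    batch_means = (onehot.T @ y) / n_per[:, None]
    alpha = (n_per / n) @ batch_means
    resid = y - onehot @ batch_means
    var_pooled = (resid**2).sum(axis=0) / n

    constant = var_pooled <= 0
    keep = [f for f, c in zip(feature_cols, constant) if not c]
    dropped = [f for f, c in zip(feature_cols, constant) if c]
    if dropped:
        warnings.warn(
            f"{len(dropped)} constant feature(s) excluded from ComBat: {dropped[:5]}..."
        )
    kmask = ~constant
    pooled_sd = np.sqrt(var_pooled[kmask])
    z = (y[:, kmask] - alpha[kmask]) / pooled_sd

    gamma_hat = np.empty((len(batches), kmask.sum()))
    delta_hat = np.empty_like(gamma_hat)
    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(gamma_hat)
    gamma_bar = np.empty(len(batches))
    tau2 = np.empty(len(batches))
    a_pri = np.empty(len(batches))
    b_pri = np.empty(len(batches))
    for i, b in enumerate(batches):
        zi = z[(labels == b).to_numpy()]
        gamma_hat[i] = zi.mean(axis=0)
        delta_hat[i] = zi.var(axis=0, ddof=1)
        gamma_bar[i] = gamma_hat[i].mean()
        tau2[i] = gamma_hat[i].var(ddof=1)
        a_pri[i] = _aprior(delta_hat[i])
        b_pri[i] = _bprior(delta_hat[i])
        if mode == "parametric":
            gamma_star[i], delta_star[i] = _parametric_posterior(
                zi, gamma_hat[i], delta_hat[i], gamma_bar[i], tau2[i],
                a_pri[i], b_pri[i], tol=tol, max_iter=max_iter,
            )
        else:
            gamma_star[i], delta_star[i] = _nonparametric_posterior(
                zi, gamma_hat[i], delta_hat[i]
            )

    def _df(arr):
        return pd.DataFrame(arr, index=batches, columns=keep)

    return ComBatModel(
        batch_col=batch_col,
        feature_cols=list(feature_cols),
        batches=batches,
        alpha=pd.Series(alpha[kmask], index=keep),
        pooled_sd=pd.Series(pooled_sd, index=keep),
        gamma_hat=_df(gamma_hat),
        delta_hat=_df(delta_hat),
        gamma_star=_df(gamma_star),
        delta_star=_df(delta_star),
        gamma_bar=pd.Series(gamma_bar, index=batches),
        tau2=pd.Series(tau2, index=batches),
        a_prior=pd.Series(a_pri, index=batches),
        b_prior=pd.Series(b_pri, index=batches),
        mode=mode,
        constant_features=dropped,
    )


def combat_apply(model: ComBatModel, table: pd.DataFrame) -> pd.DataFrame:
    """Harmonize a table with a fitted model.

    For each sample in batch i:  Y* = sigma_g / sqrt(delta*_ig) * (Z - gamma*_ig)
    + alpha_g.  Metadata columns and excluded constant features pass through
    unchanged.  Unseen batch labels raise.
    """
    labels = table[model.batch_col].astype(str)
    unseen = sorted(set(labels) - set(model.batches))
    if unseen:
        raise ValueError(f"batch label(s) not in fitted model: {unseen}")
    out = table.copy()
    feats = list(model.alpha.index)
    y = table[feats].to_numpy(dtype=float)
    alpha = model.alpha.to_numpy()
    sd = model.pooled_sd.to_numpy()
    z = (y - alpha) / sd
    for b in model.batches:
        rows = (labels == b).to_numpy()
        if not rows.any():
            continue
        g = model.gamma_star.loc[b].to_numpy()
        d = model.delta_star.loc[b].to_numpy()
        z[rows] = (z[rows] - g) / np.sqrt(d)
    out[feats] = z * sd + alpha
    return out


def combat(
    table: pd.DataFrame,
    feature_cols: list[str],
    batch_col: str = "batch",
    mode: str = "parametric",
) -> pd.DataFrame:
    """Fit-and-apply convenience wrapper."""
    return combat_apply(combat_fit(table, feature_cols, batch_col, mode=mode), table)


@dataclass
class SVDCorrection:
    """Record of an SVD-based correction."""

    mean: pd.Series
    sd: pd.Series
    singular_values: np.ndarray
    loadings: np.ndarray  # components x features
    variance_explained: np.ndarray  # fraction per component
    association_p: pd.DataFrame  # components x batch variables
    removed_components: list[int]


def _anova_p(scores: np.ndarray, labels: pd.Series) -> float:
    """One-way ANOVA p of component scores across batch levels (1 if degenerate)."""
    groups = [scores[(labels == lv).to_numpy()] for lv in pd.unique(labels)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return 1.0
    if np.ptp(scores) < 1e-12 * (1 + np.max(np.abs(scores))):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*groups)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def svd_correct(
    table: pd.DataFrame,
    feature_cols: list[str],
    batch_columns: list[str],
    alpha: float = 0.001,
) -> tuple[pd.DataFrame, SVDCorrection]:
    """Remove batch-associated principal components and reconstruct.

    Features are z-scored (components of the correlation structure), the
    matrix is decomposed by SVD, every component score vector is tested for
    association with each batch variable by one-way ANOVA, and components
    with p < ``alpha`` for any variable are zeroed before reconstruction.
    With an empty removal set the output equals the input to float precision.
    """
    x = table[feature_cols].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd_safe
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u * s
    total_var = float((s**2).sum())
    var_explained = s**2 / total_var if total_var > 0 else np.zeros_like(s)
    pvals = pd.DataFrame(
        {
            bc: [_anova_p(scores[:, c], table[bc].astype(str)) for c in range(len(s))]
            for bc in batch_columns
        }
    )
    removed = sorted(pvals.index[(pvals < alpha).any(axis=1)].tolist())
    s_kept = s.copy()
    s_kept[removed] = 0.0
    z_rec = (u * s_kept) @ vt
    out = table.copy()
    out[feature_cols] = z_rec * sd_safe + mu
    return out, SVDCorrection(
        mean=pd.Series(mu, index=feature_cols),
        sd=pd.Series(sd, index=feature_cols),
        singular_values=s,
        loadings=vt,
        variance_explained=var_explained,
        association_p=pvals,
        removed_components=removed,
    )
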