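"""Library-size normalization and empirical-Bayes batch adjustment.

Size factors use the median-of-ratios estimator: for sample s,
``s_s = median_g c_gs / (prod_t c_gt)**(1/n)`` over features with all-positive
counts, rescaled to geometric mean 1. Values enter downstream analysis as
``log2(count / s_s + pseudocount)``.

Batch adjustment is a parametric empirical-Bayes location/scale model in the
ComBat family: per feature, data are standardized using a covariate-preserving
least-squares fit, per-batch location (gamma) and scale (delta^2) estimates are
shrunk to their EB posteriors under a normal / inverse-gamma prior with
moment-matched hyperparameters, the shrunken effects are removed, and the
covariate fit is restored. The progression group (and any other protected
covariates) is included in the design so the adjustment does not absorb the
biological signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedMatrix",
    "BatchModel",
    "size_factors",
    "normalize_log",
    "combat_adjust",
]


@dataclass
class NormalizedMatrix:
    """Feature x sample matrix on log2 scale with its normalization provenance."""

    values: pd.DataFrame
    size_factors: pd.Series
    pseudocount: float = 1.0
    batch_adjusted: bool = False


@dataclass
class BatchModel:
    """Per-batch EB location/scale estimates from a ComBat-style fit."""

    gamma_star: pd.DataFrame  # batch x feature shrunken locations
    delta2_star: pd.DataFrame  # batch x feature shrunken variances
    hyper: dict = field(default_factory=dict)
    design_columns: list = field(default_factory=list)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors, rescaled to geometric mean 1.

    Only features with strictly positive counts in every sample enter the
    median (otherwise the geometric mean reference is zero). Raises if no such
    feature exists; in that case add a pseudocount upstream.
    """
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "use a pseudocount before computing size factors"
        )
    logx = np.log(x[all_pos])
    log_ratios = logx - logx.mean(axis=1, keepdims=True)
    log_sf = np.median(log_ratios, axis=0)
    log_sf -= log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def normalize_log(
    counts: pd.DataFrame, factors: pd.Series | None = None, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """log2(count / size_factor + pseudocount) transform."""
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.columns)
    vals = np.log2(counts.to_numpy(dtype=float) / factors.to_numpy()[None, :] + pseudocount)
    return NormalizedMatrix(
        values=pd.DataFrame(vals, index=counts.index, columns=counts.columns),
        size_factors=factors,
        pseudocount=pseudocount,
    )


def _design_matrix(covariates: pd.DataFrame | None, index: pd.Index) -> np.ndarray:
    """Intercept + dummy-coded / numeric covariate design (n_samples x p)."""
    cols = [np.ones(len(index))]
    if covariates is not None:
        covariates = covariates.loc[index]
        for name in covariates.columns:
            col = covariates[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
            else:
                dummies = pd.get_dummies(col, drop_first=True)
                for c in dummies.columns:
                    cols.append(dummies[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(ss, n, a_prior, b_prior):
    return (0.5 * ss + b_prior) / (n / 2.0 + a_prior - 1.0)


def combat_adjust(
    norm: NormalizedMatrix,
    batches: pd.Series,
    covariates: pd.DataFrame | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[NormalizedMatrix, BatchModel]:
    """Parametric empirical-Bayes batch adjustment of a log-scale matrix.

    ``batches`` maps sample id -> batch label (every batch needs >= 2
    samples); ``covariates`` are protected biological covariates (e.g. group,
    age, gender) whose fitted contribution is preserved. Raises if a batch is
    confounded with a covariate column (perfect aliasing makes the model
    unidentifiable).

    Returns the adjusted matrix and the fitted :class:`BatchModel`.
    """
    Y = norm.values.to_numpy(dtype=float)
    samples = norm.values.columns
    batches = batches.reindex(samples)
    if batches.isna().any():
        raise ValueError("batch label missing for some samples")
    batch_levels = list(pd.unique(batches))
    if len(batch_levels) == 1:
        model = BatchModel(
            gamma_star=pd.DataFrame(0.0, index=batch_levels, columns=norm.values.index),
            delta2_star=pd.DataFrame(1.0, index=batch_levels, columns=norm.values.index),
        )
        out = NormalizedMatrix(
            values=norm.values.copy(),
            size_factors=norm.size_factors,
            pseudocount=norm.pseudocount,
            batch_adjusted=True,
        )
        return out, model

    n_batch = np.array([(batches == b).sum() for b in batch_levels])
    if (n_batch < 2).any():
        bad = batch_levels[int(np.argmin(n_batch))]
        raise ValueError(f"batch {bad!r} has fewer than 2 samples")

    B = np.column_stack([(batches == b).to_numpy(dtype=float) for b in batch_levels])
    X_cov = _design_matrix(covariates, samples)  # includes intercept
    # full design: batch indicators (no intercept) + covariates without intercept
    X = np.column_stack([B, X_cov[:, 1:]])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "design is singular: a batch is confounded with a covariate "
            "(perfect aliasing between batch and covariate columns)"
        )

    n_samples, n_features = Y.shape[1], Y.shape[0]
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # p x features
    grand_mean = (n_batch / n_samples) @ beta[: len(batch_levels)]
    resid = Y.T - X @ beta
    # unbiased residual variance (denominator n - p) keeps the EB scale
    # estimates consistent with the per-batch ddof=1 variances
    pooled_var = (resid**2).sum(axis=0) / max(n_samples - X.shape[1], 1)
    pooled_var = np.maximum(pooled_var, 1e-12)

    stand_mean = grand_mean[None, :] + X_cov[:, 1:] @ beta[len(batch_levels):]
    Z = (Y.T - stand_mean) / np.sqrt(pooled_var)[None, :]  # samples x features

    gamma_hat = np.zeros((len(batch_levels), n_features))
    delta2_hat = np.zeros_like(gamma_hat)
    for i, b in enumerate(batch_levels):
        mask = (batches == b).to_numpy()
        Zi = Z[mask]
        gamma_hat[i] = Zi.mean(axis=0)
        delta2_hat[i] = Zi.var(axis=0, ddof=1)
    delta2_hat = np.maximum(delta2_hat, 1e-12)

    # moment-matched hyperpriors per batch
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    v = delta2_hat.mean(axis=1)
    s2 = delta2_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = np.where(s2 > 0, (2 * s2 + v**2) / s2, np.inf)
        b_prior = np.where(s2 > 0, (v * s2 + v**3) / s2, 0.0)

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    for i, b in enumerate(batch_levels):
        mask = (batches == b).to_numpy()
        Zi = Z[mask]
        n_i = n_batch[i]
        if tau2[i] == 0 or not np.isfinite(a_prior[i]):
            # degenerate prior: all features share the same batch effect
            gamma_star[i] = gamma_bar[i]
            delta2_star[i] = v[i]
            continue
        g_new = gamma_hat[i].copy()
        d_new = delta2_hat[i].copy()
        for _ in range(max_iter):
            g_old, d_old = g_new, d_new
            g_new = _postmean(gamma_hat[i], gamma_bar[i], n_i, d_old, tau2[i])
            ss = ((Zi - g_new[None, :]) ** 2).sum(axis=0)
            d_new = _postvar(ss, n_i, a_prior[i], b_prior[i])
            if max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max()) < tol:
                break
        gamma_star[i] = g_new
        delta2_star[i] = np.maximum(d_new, 1e-12)

    Z_adj = Z.copy()
    for i, b in enumerate(batch_levels):
        mask = (batches == b).to_numpy()
        Z_adj[mask] = (Z[mask] - gamma_star[i][None, :]) / np.sqrt(delta2_star[i])[None, :]
    Y_adj = (Z_adj * np.sqrt(pooled_var)[None, :] + stand_mean).T

    model = BatchModel(
        gamma_star=pd.DataFrame(gamma_star, index=batch_levels, columns=norm.values.index),
        delta2_star=pd.DataFrame(delta2_star, index=batch_levels, columns=norm.values.index),
        hyper={
            "gamma_bar": dict(zip(batch_levels, gamma_bar)),
            "tau2": dict(zip(batch_levels, tau2)),
            "a_prior": dict(zip(batch_levels, a_prior)),
            "b_prior": dict(zip(batch_levels, b_prior)),
        },
        design_columns=["batch:" + str(b) for b in batch_levels],
    )
    out = NormalizedMatrix(
        values=pd.DataFrame(Y_adj, index=norm.values.index, columns=samples),
        size_factors=norm.size_factors,
        pseudocount=norm.pseudocount,
        batch_adjusted=True,
    )
    return out, model
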