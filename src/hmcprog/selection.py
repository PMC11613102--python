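"""Bootstrapped elastic-net stability selection of a gene panel.

The procedure: repeatedly (default 100x) resample the training samples with
replacement, stratified by class; on each resample run 5-fold cross-validation
over a grid of elastic-net mixing (alpha) and strength (lambda) parameters for
the penalized logistic model; refit at the chosen (alpha, lambda); convert
coefficients to 0-100 importance scores; mark features with importance above a
floor (default 20). Features marked in at least ``freq_min`` (default 80%) of
the bootstrap iterations form the retained panel.

The penalized objective is mean binomial deviance plus
``lambda * (alpha * ||b||_1 + (1 - alpha) * ||b||_2^2 / 2)`` with features
standardized internally and the intercept unpenalized; importance is the
max-scaled standardized coefficient magnitude,
``100 * |b_j| * sd(x_j) / max_k |b_k| * sd(x_k)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._enet import cd_enet_logistic, cd_enet_path

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "enet_logistic_fit",
    "cv_select",
    "importance_scores",
    "stability_select",
]


def _default_alpha_grid() -> np.ndarray:
    return np.round(np.arange(0.05, 1.0 + 1e-9, 0.05), 2)


def _default_lambda_grid() -> np.ndarray:
    return np.logspace(-5, 0, 50)


@dataclass
class SelectionConfig:
    """Stability-selection settings (defaults mirror the published procedure)."""

    n_bootstrap: int = 100
    alpha_grid: np.ndarray = field(default_factory=_default_alpha_grid)
    lambda_grid: np.ndarray = field(default_factory=_default_lambda_grid)
    n_folds: int = 5
    importance_min: float = 20.0
    freq_min: float = 0.80
    seed: int = 0

    def validate(self) -> None:
        a = np.asarray(self.alpha_grid, dtype=float)
        l = np.asarray(self.lambda_grid, dtype=float)
        if a.size == 0 or l.size == 0:
            raise ValueError("parameter grids must be non-empty")
        if a.min() < 0.05 - 1e-9 or a.max() > 1.0 + 1e-9:
            raise ValueError("alpha grid must lie within [0.05, 1.0]")
        if l.min() < 1e-5 - 1e-12 or l.max() > 1.0 + 1e-9:
            raise ValueError("lambda grid must lie within [1e-5, 1.0]")
        if self.freq_min < 0:
            raise ValueError("freq_min must be non-negative")
        if self.n_bootstrap <= 0 or self.n_folds < 2:
            raise ValueError("n_bootstrap must be positive and n_folds >= 2")


@dataclass
class SelectionResult:
    """Selection frequencies, per-iteration records and the retained panel."""

    frequencies: pd.Series
    panel: list
    iterations: list = field(default_factory=list)
    config: SelectionConfig | None = None


class _Standardizer:
    """Per-feature mean-0 sd-1 scaling; zero-variance features are dropped."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        self.sd = X.std(axis=0)
        self.keep = self.sd > 0
        self.n_dropped = int((~self.keep).sum())

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.keep] - self.mean[self.keep]) / self.sd[self.keep]


def enet_logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    max_iter: int = 100,
    tol: float = 1e-7,
) -> tuple[np.ndarray, float]:
    """Elastic-net penalized logistic fit; returns (coefficients, intercept).

    Minimizes mean binomial deviance + lam * (alpha L1 + (1-alpha)/2 L2^2) by
    IRLS + coordinate descent (see :mod:`hmcprog._enet`). Coefficients are on
    the original feature scale (standardization is internal); the intercept is
    unpenalized. Zero-variance features get coefficient 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("y must be binary")
    y01 = (y == classes.max()).astype(int)
    std = _Standardizer(X)
    if std.n_dropped:
        warnings.warn(f"dropped {std.n_dropped} zero-variance feature(s)", stacklevel=2)
    Xs = std.transform(X)
    beta_std, b0 = cd_enet_logistic(
        Xs, y01.astype(float), alpha, lam, tol=tol, max_outer=max_iter
    )
    beta = np.zeros(X.shape[1])
    beta[std.keep] = beta_std / std.sd[std.keep]
    intercept = b0 - float(np.dot(beta[std.keep], std.mean[std.keep]))
    return beta, intercept


def _mean_deviance(beta: np.ndarray, intercept: float, X: np.ndarray, y01: np.ndarray) -> float:
    eta = X @ beta + intercept
    # 2 * mean negative log-likelihood, numerically stable
    return float(2.0 * np.mean(np.logaddexp(0.0, eta) - y01 * eta))


def cv_select(
    X: np.ndarray,
    y: np.ndarray,
    config: SelectionConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, np.ndarray, float]:
    """Stratified K-fold grid search over (alpha, lambda).

    Minimizes mean held-out binomial deviance; ties break toward larger
    lambda, then larger alpha (more parsimonious). Returns
    (alpha*, lambda*, coefficients refit on all data, intercept).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    X = np.asarray(X, dtype=float)
    y01 = (np.asarray(y) == np.max(y)).astype(int)
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    folds = list(skf.split(X, y01))

    alphas = np.asarray(config.alpha_grid, dtype=float)
    lambdas = np.sort(np.asarray(config.lambda_grid, dtype=float))[::-1]  # strong -> weak
    dev = np.zeros((len(alphas), len(lambdas)))
    for tr, te in folds:
        std = _Standardizer(X[tr])
        Xs_tr = std.transform(X[tr])
        Xs_te = std.transform(X[te])
        for ia, a in enumerate(alphas):
            # warm-started path from strongest to weakest penalty
            betas, b0s = cd_enet_path(Xs_tr, y01[tr].astype(float), a, lambdas, tol=1e-5)
            for il in range(len(lambdas)):
                dev[ia, il] += _mean_deviance(betas[il], b0s[il], Xs_te, y01[te])
    dev /= len(folds)

    best = np.inf
    best_a = best_l = None
    best_il = 0
    # iterate so later candidates win only on strict improvement; order encodes
    # the tie-break: larger lambda first, then larger alpha
    for il in range(len(lambdas)):
        for ia in range(len(alphas) - 1, -1, -1):
            if dev[ia, il] < best - 1e-12:
                best = dev[ia, il]
                best_a, best_l = alphas[ia], lambdas[il]
                best_il = il
    # refit on all data, warm-started down the path to the chosen lambda
    std = _Standardizer(X)
    Xs = std.transform(X)
    betas, b0s = cd_enet_path(Xs, y01.astype(float), best_a, lambdas[: best_il + 1], tol=1e-7)
    beta = np.zeros(X.shape[1])
    beta[std.keep] = betas[-1] / std.sd[std.keep]
    b0 = float(b0s[-1]) - float(np.dot(beta[std.keep], std.mean[std.keep]))
    return float(best_a), float(best_l), beta, b0


def importance_scores(coefficients: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Max-scaled standardized coefficient magnitudes on a 0-100 scale."""
    sd = np.asarray(X, dtype=float).std(axis=0)
    raw = np.abs(np.asarray(coefficients, dtype=float)) * sd
    top = raw.max()
    if top == 0:
        return np.zeros_like(raw)
    return 100.0 * raw / top


def _stratified_bootstrap(rng: np.random.Generator, y01: np.ndarray) -> np.ndarray:
    idx = []
    for cls in (0, 1):
        members = np.flatnonzero(y01 == cls)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def stability_select(
    X_train: pd.DataFrame,
    y_train: pd.Series | np.ndarray,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Bootstrapped elastic-net stability selection on the training split.

    ``X_train`` is samples x features. Per-bootstrap seeds derive from the
    master seed by a counter so iterations are independently reproducible.
    """
    config = config or SelectionConfig()
    config.validate()
    feature_ids = list(X_train.columns) if isinstance(X_train, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(X_train).shape[1])
    ]
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    y01 = (y == np.max(y)).astype(int)
    if y01.min() == y01.max():
        raise ValueError("training labels must contain both classes")

    marks = np.zeros(X.shape[1])
    iterations = []
    for b in range(config.n_bootstrap):
        rng = np.random.default_rng((config.seed, b))
        idx = _stratified_bootstrap(rng, y01)
        Xb, yb = X[idx], y01[idx]
        a_star, l_star, beta, b0 = cv_select(Xb, yb, config, rng=rng)
        imp = importance_scores(beta, Xb)
        marked = imp > config.importance_min
        marks += marked
        iterations.append(
            {"alpha": a_star, "lambda": l_star, "importance": imp, "marked": marked}
        )
    freq = pd.Series(marks / config.n_bootstrap, index=feature_ids, name="frequency")
    panel = [f for f, fr in freq.items() if fr >= config.freq_min]
    return SelectionResult(frequencies=freq, panel=panel, iterations=iterations, config=config)
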