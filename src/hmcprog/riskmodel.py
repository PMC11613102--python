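"""Final multivariable logistic risk model, ROC evaluation and cutoff choice.

The model regresses progression status on the selected gene panel plus
clinical covariates (gender, continuous z-scored age, lesion type as two
indicators with inflammation as reference; optionally a fixed-coefficient
cohort log-hazard offset). Fitting is unpenalized maximum likelihood via
iteratively reweighted least squares; detected separation triggers a ridge
(1e-6) refit with a flag.

Performance is summarized by the trapezoidal AUC with stratified-bootstrap
percentile confidence intervals. The decision cutoff is anchored on the
validation split: among thresholds holding specificity >= 0.90 there, the one
maximizing sensitivity (ties to the larger threshold) is chosen and then
applied to all samples pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RiskModelFit",
    "RocCurve",
    "split_train_valid",
    "irls_fit",
    "roc_auc",
    "auc_ci",
    "choose_cutoff",
    "end_to_end",
]


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class RiskModelFit:
    coefficients: pd.Series
    intercept: float
    train_auc: float
    train_auc_ci: tuple[float, float]
    valid_auc: float
    valid_auc_ci: tuple[float, float]
    cutoff: float
    sensitivity_all: float
    specificity_all: float
    separation_flag: bool = False
    scores: pd.Series | None = None
    extras: dict = field(default_factory=dict)


def split_train_valid(meta: pd.DataFrame, ratio: float = 2 / 3, seed: int = 0) -> pd.Series:
    """Stratified train/validation split labels ("train"/"valid").

    Per class, round(ratio * n) samples go to training (21 cases / 48 controls
    at the default ratio give 14/32 train and 7/16 validation).
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    labels = pd.Series("valid", index=meta.index, name="split")
    for _, sub in meta.groupby("group", sort=True):
        idx = np.array(sub.index)
        rng.shuffle(idx)
        n_train = int(round(ratio * len(idx)))
        labels.loc[idx[:n_train]] = "train"
    if (labels == "valid").sum() == 0:
        raise ValueError("validation split is empty at this ratio")
    return labels


def irls_fit(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    ridge_on_separation: float = 1e-6,
) -> tuple[np.ndarray, bool]:
    """Unpenalized ML logistic regression via IRLS.

    ``X`` must include the intercept column if one is wanted. On detected
    separation (diverging coefficients or vanishing working weights with
    perfectly predicted classes) the model is refit with an L2 penalty of
    ``ridge_on_separation`` and flagged.

    Returns (coefficients, separation_flag).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    offset = np.zeros(len(y))
    beta, trouble = _irls_core(X, y, offset, 0.0, tol, max_iter)
    if trouble or np.max(np.abs(beta)) > 1e3:
        beta, _ = _irls_core(X, y, offset, ridge_on_separation, tol, max_iter)
        return beta, True
    return beta, False


def _irls_core(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    ridge: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, bool]:
    """Damped IRLS on the (optionally ridge-penalized) logistic likelihood.

    The intercept-like column (constant, nonzero) stays unpenalized; all-zero
    columns keep the penalty so the Hessian stays invertible. Newton steps are
    halved until the penalized objective does not increase, which keeps the
    unpenalized intercept finite under separation.
    """
    pen = 1.0 - ((np.ptp(X, axis=0) == 0) & (np.abs(X).max(axis=0) > 0)).astype(float)

    def objective(beta: np.ndarray) -> float:
        eta = np.clip(X @ beta + offset, -500, 500)
        return float(
            np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * ridge * np.sum(pen * beta**2)
        )

    beta = np.zeros(X.shape[1])
    obj = objective(beta)
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None]) + ridge * np.diag(pen)
        score = X.T @ (y - mu) - ridge * pen * beta
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            return beta, True
        new_beta = beta + step
        new_obj = objective(new_beta)
        halvings = 0
        while new_obj > obj + 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_obj = objective(new_beta)
            halvings += 1
        beta, obj = new_beta, new_obj
        if np.max(np.abs(step)) < tol:
            return beta, False
    # non-convergence within budget is treated as separation evidence
    return beta, True


def predict_proba(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    eta = np.asarray(X, dtype=float) @ beta
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[RocCurve, float]:
    """Empirical ROC curve and trapezoidal AUC (ties step simultaneously)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr), float(_trapezoid_auc(fpr, tpr))


def auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Stratified-bootstrap percentile CI for the AUC, clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, len(pos), replace=True), rng.choice(neg, len(neg), replace=True)]
        )
        _, stats[b] = roc_auc(scores[idx], labels[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def choose_cutoff(
    validation_scores: np.ndarray,
    validation_labels: np.ndarray,
    min_specificity: float = 0.90,
) -> float:
    """Cutoff holding validation specificity >= ``min_specificity``.

    A sample is called positive when its score >= cutoff. Candidate cutoffs
    are the observed score values; among those meeting the specificity floor
    the one maximizing sensitivity is returned, ties resolved to the larger
    cutoff. Raises when no candidate qualifies (e.g. all scores identical).
    """
    s = np.asarray(validation_scores, dtype=float)
    y = np.asarray(validation_labels).astype(int)
    if len(s) == 0 or y.min() == y.max():
        raise ValueError("validation set must contain both classes")
    best = None  # (sensitivity, cutoff)
    for t in np.unique(s):
        spec = np.mean(s[y == 0] < t)
        if spec < min_specificity:
            continue
        sens = np.mean(s[y == 1] >= t)
        if best is None or sens > best[0] or (sens == best[0] and t > best[1]):
            best = (sens, t)
    if best is None:
        raise ValueError(
            f"no threshold achieves specificity >= {min_specificity:.2f} on the "
            f"validation set (n_controls={int((y == 0).sum())}, "
            f"{len(np.unique(s))} distinct scores)"
        )
    return float(best[1])


def build_design(
    panel_values: pd.DataFrame,
    meta: pd.DataFrame,
    hazard_offset: pd.Series | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + panel features + gender + z-age + lesion indicators.

    ``panel_values`` is samples x panel-features; lesion uses inflammation as
    the reference level. ``hazard_offset`` (a Cox linear predictor per sample)
    is not included here — it enters the linear predictor with coefficient
    fixed at 1 when supplied to :func:`end_to_end`.
    """
    idx = panel_values.index
    cols = [np.ones(len(idx))]
    names = ["intercept"]
    for c in panel_values.columns:
        cols.append(panel_values[c].to_numpy(dtype=float))
        names.append(str(c))
    gender = (meta.loc[idx, "gender"] == "female").to_numpy(dtype=float)
    cols.append(gender)
    names.append("gender_female")
    age = meta.loc[idx, "age"].to_numpy(dtype=float)
    sd = age.std()
    cols.append((age - age.mean()) / (sd if sd > 0 else 1.0))
    names.append("age_z")
    lesion = meta.loc[idx, "lesion"]
    for level in ("atrophy/IM", "dysplasia"):
        cols.append((lesion == level).to_numpy(dtype=float))
        names.append(f"lesion_{level}")
    return np.column_stack(cols), names


def end_to_end(
    panel_values: pd.DataFrame,
    meta: pd.DataFrame,
    split: pd.Series,
    min_specificity: float = 0.90,
    n_boot: int = 2000,
    seed: int = 0,
    hazard_offset: pd.Series | None = None,
) -> RiskModelFit:
    """Fit the risk model on the training split and evaluate it.

    ``panel_values``: samples x panel features (normalized 5hmC levels);
    ``meta``: per-sample group/age/gender/lesion; ``split``: "train"/"valid"
    labels. The optional ``hazard_offset`` adds a fixed-coefficient Cox linear
    predictor to the model's linear predictor (an interpretation of folding
    cohort hazard ratios into the final model; off by default).
    """
    X, names = build_design(panel_values, meta, hazard_offset)
    y = (meta.loc[panel_values.index, "group"] == "case").to_numpy(dtype=int)
    offset = (
        hazard_offset.reindex(panel_values.index).to_numpy(dtype=float)
        if hazard_offset is not None
        else np.zeros(len(y))
    )
    split = split.reindex(panel_values.index)
    tr = (split == "train").to_numpy()
    va = (split == "valid").to_numpy()

    # offset enters with coefficient fixed at 1: fold into the response via
    # IRLS on the shifted linear predictor
    beta, flagged = _irls_with_offset(X[tr], y[tr], offset[tr])
    # risk scores are the linear predictor: the same ROC as the fitted
    # probability (monotone transform) without saturation ties near 0/1
    scores = X @ beta + offset

    _, auc_tr = roc_auc(scores[tr], y[tr])
    _, auc_va = roc_auc(scores[va], y[va])
    ci_tr = auc_ci(scores[tr], y[tr], n_boot=n_boot, seed=seed + 1)
    ci_va = auc_ci(scores[va], y[va], n_boot=n_boot, seed=seed + 2)
    cutoff = choose_cutoff(scores[va], y[va], min_specificity=min_specificity)
    pred_all = scores >= cutoff
    sens = float(np.mean(pred_all[y == 1]))
    spec = float(np.mean(~pred_all[y == 0]))
    return RiskModelFit(
        coefficients=pd.Series(beta, index=names),
        intercept=float(beta[0]),
        train_auc=auc_tr,
        train_auc_ci=ci_tr,
        valid_auc=auc_va,
        valid_auc_ci=ci_va,
        cutoff=cutoff,
        sensitivity_all=sens,
        specificity_all=spec,
        separation_flag=flagged,
        scores=pd.Series(scores, index=panel_values.index, name="score"),
    )


def _irls_with_offset(
    X: np.ndarray, y: np.ndarray, offset: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, bool]:
    if not np.any(offset):
        return irls_fit(X, y, tol=tol, max_iter=max_iter)
    beta, trouble = _irls_core(X, y, offset, 0.0, tol, max_iter)
    if trouble or np.max(np.abs(beta)) > 1e3:
        beta, _ = _irls_core(X, y, offset, 1e-6, tol, max_iter)
        return beta, True
    return beta, False
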