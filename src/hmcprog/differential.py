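"""Per-feature differential hydroxymethylation between sample groups.

Effects are reported as log2 fold changes of size-factor-scaled mean counts
(case minus control orientation). Significance uses the two-sided
Wilcoxon/Mann-Whitney rank-sum p-value together with the "empirical p" — the
two-sided p divided by 2, the convention this analysis path inherits from the
coin::wilcox_test usage it mirrors. Note that under no ties the halved value
equals a one-sided p; it is reported verbatim and both values are kept.

Calls use strict inequalities: hyper if log2FC > lfc_min and empirical
p < p_max; hypo if log2FC < -lfc_min and empirical p < p_max. The default
lfc_min of 0.26 corresponds to a >20% fold change (log2 1.2 ~ 0.263).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "DifferentialThresholds",
    "log2_fold_change",
    "wilcoxon_empirical_p",
    "bh_fdr",
    "differential_table",
    "call_differential",
    "covariate_screen",
    "hierarchical_cluster",
]

#: product of group sizes below which the exact rank-sum null is enumerated
EXACT_LIMIT = 400


@dataclass
class DifferentialThresholds:
    """Calling thresholds: volcano rule (lfc_min, p_max) and clustering rule
    (fdr_max with fold-change fc_min, e.g. 0.2 for >20%)."""

    lfc_min: float = 0.26
    p_max: float = 0.05
    fdr_max: float = 0.05
    fc_min: float = 0.20

    def __post_init__(self):
        if min(self.lfc_min, self.p_max, self.fdr_max, self.fc_min) <= 0:
            raise ValueError("thresholds must be positive")


def log2_fold_change(
    scaled: pd.DataFrame, groups: pd.Series, pseudocount: float = 1.0
) -> pd.Series:
    """log2((mean scaled case + pc) / (mean scaled control + pc)) per feature.

    ``scaled`` holds size-factor-scaled counts (features x samples);
    ``groups`` maps sample -> {"case", "control"}.
    """
    groups = groups.reindex(scaled.columns)
    case_mean = scaled.loc[:, (groups == "case").to_numpy()].mean(axis=1)
    ctrl_mean = scaled.loc[:, (groups == "control").to_numpy()].mean(axis=1)
    lfc = np.log2(case_mean + pseudocount) - np.log2(ctrl_mean + pseudocount)
    lfc.name = "log2fc"
    return lfc


def wilcoxon_empirical_p(values_case: np.ndarray, values_control: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p and the halved "empirical" p.

    Exact null enumeration when n1*n2 <= EXACT_LIMIT and the pooled values are
    tie-free; otherwise the normal approximation with tie and continuity
    correction. Degenerate constant pooled input returns p = 1.
    """
    x = np.asarray(values_case, dtype=float)
    y = np.asarray(values_control, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 values per group")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0, 0.5
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) * len(y) <= EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return p, p / 2.0


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    scaled: pd.DataFrame, groups: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-feature log2FC, raw/empirical rank-sum p and BH q."""
    groups = groups.reindex(scaled.columns)
    case = scaled.loc[:, (groups == "case").to_numpy()].to_numpy()
    ctrl = scaled.loc[:, (groups == "control").to_numpy()].to_numpy()
    lfc = log2_fold_change(scaled, groups, pseudocount)
    raw = np.empty(len(scaled))
    emp = np.empty(len(scaled))
    for i in range(len(scaled)):
        raw[i], emp[i] = wilcoxon_empirical_p(case[i], ctrl[i])
    table = pd.DataFrame(
        {
            "feature_id": scaled.index,
            "log2fc": lfc.to_numpy(),
            "p_raw": raw,
            "p_empirical": emp,
            "q": bh_fdr(emp),
        }
    )
    return table


def call_differential(
    records: pd.DataFrame, thresholds: DifferentialThresholds | None = None
) -> pd.DataFrame:
    """Volcano-rule direction calls; adds a ``direction`` column.

    hyper: log2FC > lfc_min and empirical p < p_max (strict); hypo mirrored;
    otherwise ns.
    """
    thresholds = thresholds or DifferentialThresholds()
    records = records.copy()
    sig = records["p_empirical"] < thresholds.p_max
    direction = np.where(
        sig & (records["log2fc"] > thresholds.lfc_min),
        "hyper",
        np.where(sig & (records["log2fc"] < -thresholds.lfc_min), "hypo", "ns"),
    )
    records["direction"] = direction
    return records


def covariate_screen(
    norm_values: pd.DataFrame,
    case_status: pd.Series,
    age: pd.Series,
    gender: pd.Series,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-feature logistic screen of case status controlled for age and gender.

    For each feature, fit logit(case) ~ feature + age_z + gender and record the
    Wald p of the feature coefficient; features with p < ``p_threshold`` are
    candidates. Perfect separation keeps the feature with p recorded as 0 and
    ``separation`` flagged (the screen only ranks candidates).

    Returns a DataFrame (feature_id, p_wald, separation, candidate).
    """
    samples = norm_values.columns
    y = (case_status.reindex(samples) == "case").to_numpy(dtype=float)
    if set(np.unique(y)) == {0.0} or set(np.unique(y)) == {1.0}:
        raise ValueError("case_status must contain both classes")
    age_v = age.reindex(samples).to_numpy(dtype=float)
    age_z = (age_v - age_v.mean()) / age_v.std()
    gender_bin = (gender.reindex(samples) == gender.reindex(samples).iloc[0]).to_numpy(dtype=float)
    if np.ptp(gender_bin) == 0:
        base = np.column_stack([np.ones(len(samples)), age_z])
    else:
        base = np.column_stack([np.ones(len(samples)), age_z, gender_bin])

    rows = []
    X = norm_values.to_numpy(dtype=float)
    for i, fid in enumerate(norm_values.index):
        design = np.column_stack([base, X[i]])
        sep = False
        try:
            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("error", PerfectSeparationWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
            p = float(fit.pvalues[-1])
            if not np.isfinite(p):
                sep, p = True, 0.0
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            sep, p = True, 0.0
        rows.append((fid, p, sep))
    out = pd.DataFrame(rows, columns=["feature_id", "p_wald", "separation"])
    out["candidate"] = out["p_wald"] < p_threshold
    return out


def hierarchical_cluster(values: pd.DataFrame) -> dict:
    """Average-linkage clustering of samples on 1 - Pearson correlation.

    ``values`` is features x samples (restricted to called features). Samples
    are ordered lexicographically by id before computing the linkage so ties
    resolve deterministically.

    Returns {"linkage": scipy linkage matrix, "order": leaf order (sample
    ids), "samples": input sample ids in the clustered order}.
    """
    cols = sorted(values.columns)
    X = values[cols].to_numpy(dtype=float).T  # samples x features
    n = len(cols)
    if n == 1:
        return {"linkage": np.empty((0, 4)), "order": cols, "samples": cols}
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [cols[i] for i in hierarchy.leaves_list(Z)]
    return {"linkage": Z, "order": order, "samples": cols}


def cluster_cut_labels(result: dict, k: int) -> pd.Series:
    """Flat cluster labels from a hierarchical_cluster result at k clusters."""
    labels = hierarchy.fcluster(result["linkage"], t=k, criterion="maxclust")
    return pd.Series(labels, index=result["samples"], name="cluster")
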