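"""Cohort epidemiology: descriptive tables, incidence, KM, Cox, nomogram, SIR.

Cohort records are one row per patient with lesion type (inflammation,
atrophy/IM, dysplasia), gender, age group, biopsy location, follow-up time in
years and a gastric-adenocarcinoma event indicator.

The Cox model maximizes the log partial likelihood by Newton-Raphson with
Breslow tie handling and step-halving; standard errors come from the inverse
observed information. The standardized incidence ratio divides observed events
by the expected count under stratum-specific reference rates. Nomogram points
rescale each covariate's contribution to the Cox linear predictor to a 0-100
axis anchored at the lowest-risk (reference) level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "CoxFit",
    "cohort_summary",
    "person_years",
    "km_cumulative_incidence",
    "cox_ph_fit",
    "nomogram_points",
    "sir",
    "chi2_2x2",
    "power_two_sample",
    "round_half_up",
    "LESION_ORDER",
]

LESION_ORDER = ["inflammation", "atrophy/IM", "dysplasia"]
AGE_ORDER = ["<50", "50-59", "60-69", "70+"]
LOCATION_ORDER = ["antrum", "corpus", "cardia", "fundus", "angle", "unclear"]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (matches printed tables)."""
    factor = 10**decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)) if x else 0.0


def cohort_summary(records: pd.DataFrame) -> dict:
    """Descriptive baseline and outcome tables by lesion type.

    Returns a dict with:

    - ``baseline``: counts and column percentages of gender, age group and
      location per lesion column (plus "all"); percentage denominators are the
      lesion-column totals, rounded half-up to 2 decimals.
    - ``outcomes``: GAC events total / during first year (time <= 1.0) /
      after first year, plus event splits by gender and age group, as
      percentages of the lesion-column totals.
    - ``times``: median and IQR of time to diagnosis per lesion, for all
      events and excluding first-year events.
    """
    columns = ["all"] + [l for l in LESION_ORDER if (records["lesion"] == l).any()]

    def per_column(fn) -> pd.DataFrame:
        out = {}
        for col in columns:
            sub = records if col == "all" else records[records["lesion"] == col]
            out[col] = fn(sub)
        return pd.concat(out, axis=1)

    def baseline_block(sub: pd.DataFrame) -> pd.DataFrame:
        denom = len(sub)
        rows = {}
        rows["total"] = (denom, 100.0 if denom else 0.0)
        for g in ("male", "female"):
            n = int((sub["gender"] == g).sum())
            rows[f"gender:{g}"] = (n, round_half_up(100.0 * n / denom) if denom else 0.0)
        for a in AGE_ORDER:
            n = int((sub["age_group"] == a).sum())
            rows[f"age:{a}"] = (n, round_half_up(100.0 * n / denom) if denom else 0.0)
        if "location" in sub:
            for loc in LOCATION_ORDER:
                n = int((sub["location"] == loc).sum())
                rows[f"location:{loc}"] = (n, round_half_up(100.0 * n / denom) if denom else 0.0)
        return pd.DataFrame(rows, index=["n", "pct"]).T

    def outcome_block(sub: pd.DataFrame) -> pd.DataFrame:
        denom = len(sub)
        ev = sub[sub["event"] == 1]
        first = ev[ev["time"] <= 1.0]
        later = ev[ev["time"] > 1.0]
        rows = {
            "gac_total": len(ev),
            "gac_first_year": len(first),
            "gac_after_first_year": len(later),
        }
        for g in ("male", "female"):
            rows[f"gac_gender:{g}"] = int((ev["gender"] == g).sum())
        for a in AGE_ORDER:
            rows[f"gac_age:{a}"] = int((ev["age_group"] == a).sum())
        out = pd.DataFrame({"n": pd.Series(rows)})
        out["pct"] = out["n"].apply(lambda c: round_half_up(100.0 * c / denom) if denom else 0.0)
        return out

    def time_block(sub: pd.DataFrame) -> pd.DataFrame:
        ev = sub[sub["event"] == 1]
        later = ev[ev["time"] > 1.0]
        def stats_of(t: pd.Series) -> tuple:
            if len(t) == 0:
                return (np.nan, np.nan, np.nan)
            return (t.median(), t.min(), t.max())
        rows = {
            "all_events": stats_of(ev["time"]),
            "excluding_first_year": stats_of(later["time"]),
        }
        return pd.DataFrame(rows, index=["median", "range_lo", "range_hi"]).T

    return {
        "baseline": per_column(baseline_block),
        "outcomes": per_column(outcome_block),
        "times": per_column(time_block),
    }


def person_years(records: pd.DataFrame, by: list[str] | None = None) -> dict:
    """Total (and optionally per-stratum) person-years and event rates.

    Rate is events per 1000 person-years. ``by`` lists grouping columns for
    the per-stratum table (e.g. ["age_group", "gender"]).
    """
    total_py = float(records["time"].sum())
    events = int(records["event"].sum())
    out = {
        "person_years": total_py,
        "events": events,
        "rate_per_1000": 1000.0 * events / total_py if total_py > 0 else 0.0,
    }
    if by:
        g = records.groupby(by, observed=True).agg(
            person_years=("time", "sum"), events=("event", "sum")
        )
        g["rate_per_1000"] = 1000.0 * g["events"] / g["person_years"]
        out["strata"] = g
    return out


def km_cumulative_incidence(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit cumulative incidence 1 - S(t).

    Censored subjects leave the risk set without a step. Returns a DataFrame
    (time, cumulative_incidence) including the origin (0, 0).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    surv = kmf.survival_function_
    out = pd.DataFrame(
        {"time": surv.index.to_numpy(dtype=float), "cumulative_incidence": 1.0 - surv.iloc[:, 0].to_numpy()}
    )
    return out.reset_index(drop=True)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit: log HRs, ses, Wald tests, baseline hazard."""

    coefficients: pd.Series
    se: pd.Series
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p: pd.Series
    log_likelihood: float
    n_iter: int
    converged: bool
    baseline_cumhaz: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.se,
                "HR": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p,
            }
        )


def _tie_block_last(order_times: np.ndarray) -> np.ndarray:
    """For times sorted descending, index of the last member of each tie block
    (i.e. the cumulative-sum index covering the full risk set at that time)."""
    block_ids = np.cumsum(np.r_[0, np.diff(order_times) != 0])
    return np.searchsorted(block_ids, block_ids, side="right") - 1


def _cox_quantities(beta, X, order_times, order_events, block_last=None):
    """Log partial likelihood, score and information with Breslow ties.

    Arrays must be sorted by descending time so risk sets are cumulative
    prefixes; all per-event sums are vectorized over the cumulative risk-set
    statistics S0, S1, S2.
    """
    if block_last is None:
        block_last = _tie_block_last(order_times)
    eta = np.clip(X @ beta, -500, 500)
    w = np.exp(eta)
    S0 = np.cumsum(w)
    S1 = np.cumsum(X * w[:, None], axis=0)
    S2 = np.cumsum(X[:, :, None] * X[:, None, :] * w[:, None, None], axis=0)

    ev = order_events.astype(bool)
    L = block_last[ev]
    s0 = S0[L]
    xbar = S1[L] / s0[:, None]
    loglik = float(eta[ev].sum() - np.log(s0).sum())
    score = (X[ev] - xbar).sum(axis=0)
    info = (S2[L] / s0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", xbar, xbar)
    return loglik, score, info


def cox_ph_fit(
    time: np.ndarray,
    event: np.ndarray,
    X: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 25,
    compute_baseline: bool = True,
) -> CoxFit:
    """Newton-Raphson Cox partial-likelihood fit with Breslow tie handling.

    ``X`` is a numeric covariate design (no intercept). Step-halving enforces
    a non-decreasing log partial likelihood; monotone likelihood (diverging
    coefficients) raises with the last iterate in the message.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if e.sum() == 0:
        raise ValueError("no events in the data")
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    for j, name in enumerate(names):
        if np.ptp(Xv[e.astype(bool), j]) == 0 and np.ptp(Xv[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant")

    order = np.argsort(-t, kind="stable")
    Xs, ts, es = Xv[order], t[order], e[order]
    block_last = _tie_block_last(ts)

    beta = np.zeros(Xv.shape[1])
    loglik, score, info = _cox_quantities(beta, Xs, ts, es, block_last)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix at iterate beta={beta}") from exc
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_quantities(new_beta, Xs, ts, es, block_last)
        halvings = 0
        while new_ll < loglik and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_quantities(new_beta, Xs, ts, es, block_last)
            halvings += 1
        delta = np.max(np.abs(new_beta - beta))
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(beta)) > 50:
            raise ValueError(
                f"monotone partial likelihood (diverging coefficients); last iterate {beta}"
            )
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ValueError(f"Cox fit did not converge in {max_iter} iterations; last iterate {beta}")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    ci_lo = np.exp(beta - 1.96 * se)
    ci_hi = np.exp(beta + 1.96 * se)

    baseline = None
    if compute_baseline:
        eta = np.clip(Xs @ beta, -500, 500)
        S0 = np.cumsum(np.exp(eta))
        ev = es.astype(bool)
        L = block_last[ev]
        # one increment of 1/S0 per event; tied events add d/S0 at their time
        inc = pd.Series(1.0 / S0[L]).groupby(ts[ev]).sum().sort_index()
        baseline = pd.DataFrame(
            {"time": inc.index.to_numpy(), "cumhaz": inc.cumsum().to_numpy()}
        )

    idx = pd.Index(names)
    return CoxFit(
        coefficients=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        hr=pd.Series(np.exp(beta), index=idx),
        ci_lower=pd.Series(ci_lo, index=idx),
        ci_upper=pd.Series(ci_hi, index=idx),
        p=pd.Series(p, index=idx),
        log_likelihood=loglik,
        n_iter=n_iter,
        converged=converged,
        baseline_cumhaz=baseline,
    )


def nomogram_points(
    fit: CoxFit, covariate_ranges: dict[str, tuple[float, float]]
) -> dict:
    """Nomogram point scaling of a Cox fit.

    ``covariate_ranges`` maps covariate name -> (reference value, extreme
    value). The covariate with the largest |beta * range| spans 0-100 points;
    every covariate's reference value scores 0. Returns per-covariate point
    functions tabulated at the two anchor values plus a ``total_to_lp``
    callable mapping total points back to the Cox linear predictor (relative
    to all-reference).
    """
    betas = fit.coefficients
    spans = {
        name: betas[name] * (hi - lo) for name, (lo, hi) in covariate_ranges.items()
    }
    max_span = max(abs(v) for v in spans.values())
    if max_span == 0:
        raise ValueError("all covariate spans are zero")
    points = {}
    for name, (lo, hi) in covariate_ranges.items():
        points[name] = {
            "reference": lo,
            "points_at_reference": 0.0,
            "points_at_extreme": 100.0 * betas[name] * (hi - lo) / max_span,
            "points_per_unit": 100.0 * betas[name] / max_span,
        }

    def total_to_lp(total_points: float) -> float:
        ref_lp = sum(betas[name] * lo for name, (lo, _) in covariate_ranges.items())
        return ref_lp + total_points * max_span / 100.0

    out = {"points": points, "total_to_lp": total_to_lp, "max_span": max_span}
    if fit.baseline_cumhaz is not None:
        base = fit.baseline_cumhaz

        def survival_at(total_points: float, horizon: float) -> float:
            lp = total_to_lp(total_points)
            h0 = base.loc[base["time"] <= horizon, "cumhaz"]
            H0 = float(h0.iloc[-1]) if len(h0) else 0.0
            return float(np.exp(-H0 * np.exp(lp)))

        out["survival_at"] = survival_at
    return out


def sir(
    observed_events: int,
    rate_table: pd.DataFrame,
    cohort_py: pd.DataFrame,
    strata_cols: list[str] | None = None,
    rate_col: str = "rate",
    py_col: str = "person_years",
) -> dict:
    """Standardized incidence ratio: observed / sum(rate x person-years).

    ``rate_table`` and ``cohort_py`` are joined on ``strata_cols`` (defaults
    to their common non-value columns). Raises when expected is 0 with
    observed > 0.
    """
    if strata_cols is None:
        strata_cols = [c for c in rate_table.columns if c != rate_col]
    merged = cohort_py.merge(rate_table, on=strata_cols, how="left", validate="one_to_one")
    if merged[rate_col].isna().any():
        missing = merged.loc[merged[rate_col].isna(), strata_cols].to_dict("records")
        raise ValueError(f"reference rate missing for strata: {missing}")
    expected = float((merged[rate_col] * merged[py_col]).sum())
    if expected == 0:
        if observed_events > 0:
            raise ValueError("expected count is 0 with observed events > 0")
        return {"sir": np.nan, "observed": observed_events, "expected": 0.0}
    return {"sir": observed_events / expected, "observed": observed_events, "expected": expected}


def chi2_2x2(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (no continuity correction by default)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    a, b, c, d = t.ravel()
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff**2 / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def power_two_sample(n1: int, n2: int, effect_size_d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test via the noncentral t."""
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 per group")
    df = n1 + n2 - 2
    ncp = effect_size_d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
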