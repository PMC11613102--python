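"""Programmatic test fixtures: a cohort matching the published baseline and
outcome table marginals, toy catalogs/fragments and a synthetic reference
rate table.

``table12_cohort`` reconstructs a patient-level cohort whose marginal counts
equal the printed baseline (gender, age group, location per lesion type) and
outcome (events total / first-year / later, event gender and age splits,
median progression times) tables of the 29,176-patient gastritis cohort. The
joint (gender x age) assignment is a greedy transportation fill — only the
margins are constrained by the source tables. Two printed age-group cells
(70+ for inflammation and atrophy/IM) are inconsistent with their own row and
column totals and are reconciled here (1701->1707, 1707->1720), which restores
every margin without touching any other cell. Event patients carry the
diagnosis-age group of the outcome table as their ``age_group``. Censoring
times are chosen so the cohort's total person-years (370,561.99) and median
follow-up (12.2 y) equal the printed values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["make_fixture", "table12_cohort", "toy_catalog", "reference_rate_table", "FIXTURES"]

LESIONS = ["inflammation", "atrophy/IM", "dysplasia"]
AGE_GROUPS = ["<50", "50-59", "60-69", "70+"]
GENDERS = ["male", "female"]
LOCATIONS = ["antrum", "corpus", "cardia", "fundus", "angle", "unclear"]

# baseline margins per lesion (70+ cells reconciled, see module docstring)
TOTALS = {"inflammation": 17948, "atrophy/IM": 10391, "dysplasia": 837}
GENDER_MARGIN = {
    "inflammation": {"male": 7009, "female": 10939},
    "atrophy/IM": {"male": 4412, "female": 5979},
    "dysplasia": {"male": 494, "female": 343},
}
AGE_MARGIN = {
    "inflammation": {"<50": 7510, "50-59": 5584, "60-69": 3147, "70+": 1707},
    "atrophy/IM": {"<50": 2393, "50-59": 3656, "60-69": 2622, "70+": 1720},
    "dysplasia": {"<50": 180, "50-59": 271, "60-69": 219, "70+": 167},
}
LOCATION_MARGIN = {
    "inflammation": {"antrum": 16549, "corpus": 744, "cardia": 73, "fundus": 234, "angle": 317, "unclear": 31},
    "atrophy/IM": {"antrum": 9612, "corpus": 211, "cardia": 20, "fundus": 15, "angle": 522, "unclear": 11},
    "dysplasia": {"antrum": 703, "corpus": 49, "cardia": 5, "fundus": 2, "angle": 77, "unclear": 1},
}

# outcome margins per lesion
EVENTS_TOTAL = {"inflammation": 97, "atrophy/IM": 112, "dysplasia": 31}
EVENTS_FIRST_YEAR = {"inflammation": 11, "atrophy/IM": 11, "dysplasia": 13}
EVENT_GENDER = {
    "inflammation": {"male": 59, "female": 38},
    "atrophy/IM": {"male": 69, "female": 43},
    "dysplasia": {"male": 23, "female": 8},
}
EVENT_AGE = {
    "inflammation": {"<50": 21, "50-59": 22, "60-69": 32, "70+": 22},
    "atrophy/IM": {"<50": 13, "50-59": 17, "60-69": 47, "70+": 35},
    "dysplasia": {"<50": 1, "50-59": 4, "60-69": 14, "70+": 12},
}
#: median / range of time to diagnosis excluding first-year cases
LATER_TIME = {
    "inflammation": (6.68, 1.02, 20.62),
    "atrophy/IM": (6.14, 1.08, 18.93),
    "dysplasia": (4.11, 1.89, 15.91),
}
TOTAL_PERSON_YEARS = 370_561.99
MEDIAN_FOLLOWUP = 12.2


def _greedy_joint(row_margin: dict, col_margin: dict) -> dict:
    """Fill a contingency table greedily from row/column margins (northwest
    corner rule). Margins must have equal totals."""
    rows = dict(row_margin)
    table = {}
    for col, col_n in col_margin.items():
        left = col_n
        for r in rows:
            take = min(rows[r], left)
            table[(r, col)] = take
            rows[r] -= take
            left -= take
        if left:
            raise ValueError("margins do not balance")
    return table


def _times_with_median(n: int, median: float, lo: float, hi: float) -> np.ndarray:
    """n values in [lo, hi] whose sample median is exactly ``median``."""
    if n == 0:
        return np.array([])
    if n == 1:
        return np.array([median])
    n_low = (n - 1) // 2
    n_high = n - n_low - (2 - n % 2)
    low = np.linspace(lo, (lo + median) / 2, n_low) if n_low else np.array([])
    high = np.linspace((median + hi) / 2, hi, n_high) if n_high else np.array([])
    mid = np.array([median]) if n % 2 else np.array([median, median])
    return np.sort(np.concatenate([low, mid, high]))


def table12_cohort() -> pd.DataFrame:
    """Patient-level cohort reproducing the published table marginals.

    Returns a DataFrame with columns patient_id, lesion, gender, age_group,
    location, time (years), event.
    """
    frames = []
    pid = 0
    for lesion in LESIONS:
        n_total = TOTALS[lesion]
        n_events = EVENTS_TOTAL[lesion]
        n_first = EVENTS_FIRST_YEAR[lesion]
        n_later = n_events - n_first

        # events: joint gender x age from the printed event margins
        ev_joint = _greedy_joint(dict(EVENT_GENDER[lesion]), dict(EVENT_AGE[lesion]))
        ev_gender, ev_age = [], []
        for (g, a), k in ev_joint.items():
            ev_gender += [g] * k
            ev_age += [a] * k
        med, lo, hi = LATER_TIME[lesion]
        ev_times = np.concatenate(
            [np.linspace(0.09, 0.99, n_first), _times_with_median(n_later, med, lo, hi)]
        )

        # non-events: remaining margins, greedy joint
        rem_gender = {
            g: GENDER_MARGIN[lesion][g] - EVENT_GENDER[lesion][g] for g in GENDERS
        }
        rem_age = {a: AGE_MARGIN[lesion][a] - EVENT_AGE[lesion][a] for a in AGE_GROUPS}
        cz_joint = _greedy_joint(rem_gender, rem_age)
        cz_gender, cz_age = [], []
        for (g, a), k in cz_joint.items():
            cz_gender += [g] * k
            cz_age += [a] * k

        gender = ev_gender + cz_gender
        age = ev_age + cz_age
        times = np.concatenate([ev_times, np.full(n_total - n_events, np.nan)])
        event = np.r_[np.ones(n_events, dtype=int), np.zeros(n_total - n_events, dtype=int)]

        location = []
        for loc in LOCATIONS:
            location += [loc] * LOCATION_MARGIN[lesion][loc]

        frames.append(
            pd.DataFrame(
                {
                    "patient_id": [f"P{pid + i:06d}" for i in range(n_total)],
                    "lesion": lesion,
                    "gender": gender,
                    "age_group": age,
                    "location": location,
                    "time": times,
                    "event": event,
                }
            )
        )
        pid += n_total
    cohort = pd.concat(frames, ignore_index=True)

    # censoring times: hit the printed total person-years and median follow-up.
    cens = cohort["time"].isna()
    n_cens = int(cens.sum())
    event_py = float(cohort.loc[~cens, "time"].sum())
    n_low = 14_300
    n_mid = 200
    n_high = n_cens - n_low - n_mid
    t_high = (TOTAL_PERSON_YEARS - event_py - n_low * 9.0 - n_mid * MEDIAN_FOLLOWUP) / n_high
    cens_times = np.concatenate(
        [np.full(n_low, 9.0), np.full(n_mid, MEDIAN_FOLLOWUP), np.full(n_high, t_high)]
    )
    # spread censored times across lesions so each lesion keeps a mix
    rng = np.random.default_rng(12)
    rng.shuffle(cens_times)
    cohort.loc[cens, "time"] = cens_times
    return cohort


def toy_catalog() -> pd.DataFrame:
    """10-feature toy catalog on two chromosomes (gene bodies with promoters
    and a pair of enhancer peaks)."""
    rows = []
    for i in range(4):
        start = 10_000 + i * 30_000
        rows.append(("chr1", start, start + 12_000, f"geneA{i}", "gene_body", "+" if i % 2 == 0 else "-", f"GENEA{i}"))
        rows.append(("chr1", start - 2_000, start + 2_000, f"promA{i}", "promoter", "+", f"GENEA{i}"))
    rows.append(("chr2", 5_000, 9_000, "peak1", "H3K27ac", ".", ""))
    rows.append(("chr2", 20_000, 26_000, "peak2", "H3K4me1", ".", ""))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "feature_id", "feature_class", "strand", "gene_symbol"],
    )


def reference_rate_table() -> pd.DataFrame:
    """Synthetic age-gender-calendar reference GAC incidence rates (per
    person-year). Shapes follow the broad age/gender gradient of East-Asian
    gastric cancer incidence; the numbers are synthetic, not a published
    registry table."""
    base = {"<50": 1.0e-4, "50-59": 4.0e-4, "60-69": 9.0e-4, "70+": 1.5e-3}
    rows = []
    for band in ("2001-2007", "2008-2015"):
        for age, r in base.items():
            for gender, mult in (("male", 1.3), ("female", 0.6)):
                rows.append((age, gender, band, r * mult))
    return pd.DataFrame(rows, columns=["age_group", "gender", "year_band", "rate"])


def _write(df: pd.DataFrame, path: Path, **meta) -> None:
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"rows": len(df), **meta}, indent=2))


FIXTURES = {
    "table12_cohort": table12_cohort,
    "toy_catalog": toy_catalog,
    "rate_table": reference_rate_table,
}


def make_fixture(name: str, outdir: str | Path | None = None) -> pd.DataFrame:
    """Build (and optionally write) a named fixture.

    Unknown names raise with the list of available fixtures.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    df = FIXTURES[name]()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write(df, outdir / f"{name}.tsv", fixture=name)
    return df
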