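"""Cohort tables, person-years, KM, Cox (with lifelines cross-check), nomogram,
SIR, chi-square, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hmcprog.epi import (
    chi2_2x2,
    cohort_summary,
    cox_ph_fit,
    km_cumulative_incidence,
    nomogram_points,
    person_years,
    power_two_sample,
    round_half_up,
    sir,
)
from hmcprog.fixtures import reference_rate_table
from hmcprog.simulate import CohortSimConfig, simulate_cohort


class TestCohortSummary:
    def test_overall_and_lesion_outcome_percentages(self, cohort_fixture):
        tables = cohort_summary(cohort_fixture)
        out = tables["outcomes"]
        assert out.loc["gac_total", ("all", "pct")] == 0.82
        assert out.loc["gac_total", ("inflammation", "pct")] == 0.54
        assert out.loc["gac_total", ("atrophy/IM", "pct")] == 1.08
        assert out.loc["gac_total", ("dysplasia", "pct")] == 3.70
        assert out.loc["gac_first_year", ("dysplasia", "pct")] == 1.55
        assert out.loc["gac_first_year", ("all", "pct")] == 0.12
        assert out.loc["gac_after_first_year", ("all", "pct")] == 0.70

    def test_baseline_gender_and_age_percentages(self, cohort_fixture):
        base = cohort_summary(cohort_fixture)["baseline"]
        assert base.loc["gender:male", ("all", "pct")] == 40.84
        assert base.loc["gender:female", ("all", "pct")] == 59.16
        assert base.loc["gender:male", ("dysplasia", "pct")] == 59.02
        assert base.loc["age:<50", ("all", "pct")] == 34.56
        assert base.loc["location:antrum", ("all", "pct")] == 92.08

    def test_median_progression_times(self, cohort_fixture):
        times = cohort_summary(cohort_fixture)["times"]
        assert times.loc["excluding_first_year", ("inflammation", "median")] == pytest.approx(6.68)
        assert times.loc["excluding_first_year", ("atrophy/IM", "median")] == pytest.approx(6.14)
        assert times.loc["excluding_first_year", ("dysplasia", "median")] == pytest.approx(4.11)

    def test_empty_stratum_zero_percentage(self):
        records = pd.DataFrame(
            {
                "lesion": ["inflammation"] * 3,
                "gender": ["male"] * 3,
                "age_group": ["<50"] * 3,
                "location": ["antrum"] * 3,
                "time": [1.0, 2.0, 3.0],
                "event": [0, 0, 0],
            }
        )
        tables = cohort_summary(records)
        assert tables["outcomes"].loc["gac_total", ("all", "n")] == 0
        assert tables["outcomes"].loc["gac_total", ("all", "pct")] == 0.0

    def test_round_half_up_matches_printed_convention(self):
        assert round_half_up(0.825) == 0.83
        assert round_half_up(0.8226) == 0.82
        assert round_half_up(2.748) == 2.75


class TestPersonYears:
    def test_hand_example(self):
        records = pd.DataFrame({"time": [3.0, 7.0], "event": [1, 0]})
        out = person_years(records)
        assert out["person_years"] == 10.0
        assert out["rate_per_1000"] == pytest.approx(100.0)

    def test_censored_only_rate_zero(self):
        records = pd.DataFrame({"time": [2.0, 2.0], "event": [0, 0]})
        assert person_years(records)["rate_per_1000"] == 0.0

    def test_exponential_cohort_rate_matches_hazard(self):
        h = 5e-3
        cfg = CohortSimConfig(
            n_patients=10_000, baseline_hazard=h, log_hazard_ratios={}, seed=11
        )
        rec, _ = simulate_cohort(cfg)
        out = person_years(rec)
        # events ~ Poisson(h * PY): 3 MC SEs
        expected = h * out["person_years"]
        assert abs(out["events"] - expected) < 3 * np.sqrt(expected)


class TestKmCumulativeIncidence:
    def test_hand_worked_product_limit(self):
        km = km_cumulative_incidence([1, 2, 3, 4, 5], [1, 0, 1, 0, 0])
        by_time = km.set_index("time")["cumulative_incidence"]
        assert by_time.loc[1.0] == pytest.approx(1 / 5)
        assert by_time.loc[3.0] == pytest.approx(1 / 5 + (4 / 5) * (1 / 3))

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, size=200)
        km = km_cumulative_incidence(t, np.ones(200, dtype=int))
        grid = km["time"].to_numpy()[1:]
        ecdf = np.searchsorted(np.sort(t), grid, side="right") / 200
        np.testing.assert_allclose(km["cumulative_incidence"].to_numpy()[1:], ecdf, atol=1e-12)

    def test_all_censored_flat_zero(self):
        km = km_cumulative_incidence([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km["cumulative_incidence"] == 0).all()


class TestCoxPhFit:
    def test_matches_lifelines_on_continuous_times(self):
        from lifelines import CoxPHFitter

        cfg = CohortSimConfig(n_patients=800, baseline_hazard=3e-2, seed=21)
        rec, _ = simulate_cohort(cfg)
        X = pd.get_dummies(rec[["lesion", "gender"]], drop_first=True).astype(float)
        fit = cox_ph_fit(rec["time"], rec["event"], X)

        df = pd.concat([X, rec[["time", "event"]]], axis=1)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), cph.params_.to_numpy(), atol=1e-4
        )
        np.testing.assert_allclose(
            fit.se.to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-4
        )

    def test_null_covariate_hazard_ratio_near_one(self):
        rng = np.random.default_rng(1)
        cfg = CohortSimConfig(
            n_patients=2000, baseline_hazard=1e-2, log_hazard_ratios={}, seed=31
        )
        rec, _ = simulate_cohort(cfg)
        X = pd.DataFrame({"noise": rng.normal(size=len(rec))})
        fit = cox_ph_fit(rec["time"], rec["event"], X)
        assert abs(fit.coefficients["noise"]) < 3 * fit.se["noise"]

    def test_score_at_zero_matches_closed_form_single_event(self):
        # two subjects, one event first: score at beta=0 is x1 - (x1+x2)/2
        time = np.array([1.0, 2.0])
        event = np.array([1, 0])
        X = pd.DataFrame({"x": [1.0, 0.0]})
        from hmcprog.epi import _cox_quantities, _tie_block_last

        order = np.argsort(-time)
        Xs, ts, es = X.to_numpy()[order], time[order], event[order]
        _, score, _ = _cox_quantities(np.zeros(1), Xs, ts, es, _tie_block_last(ts))
        assert score[0] == pytest.approx(1.0 - 0.5)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_ph_fit(
                np.array([1.0, 2.0]), np.array([0, 0]), pd.DataFrame({"x": [0.0, 1.0]})
            )

    def test_monotone_likelihood_raises(self):
        # perfectly separating covariate drives beta to infinity
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        X = pd.DataFrame({"x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]})
        with pytest.raises(ValueError):
            cox_ph_fit(time, event, X)


class TestNomogramPoints:
    def _fit(self, betas):
        idx = pd.Index(list(betas))
        vals = pd.Series(betas)
        return type(
            "F",
            (),
            {
                "coefficients": vals,
                "baseline_cumhaz": None,
            },
        )()

    def test_two_covariate_toy_scores_50_and_100(self):
        fit = self._fit({"a": np.log(2), "b": np.log(4)})
        nom = nomogram_points(fit, {"a": (0.0, 1.0), "b": (0.0, 1.0)})
        assert nom["points"]["a"]["points_at_extreme"] == pytest.approx(50.0)
        assert nom["points"]["b"]["points_at_extreme"] == pytest.approx(100.0)

    def test_reference_levels_score_zero(self):
        fit = self._fit({"a": 0.5, "b": 1.0})
        nom = nomogram_points(fit, {"a": (0.0, 1.0), "b": (0.0, 2.0)})
        for cov in nom["points"].values():
            assert cov["points_at_reference"] == 0.0

    def test_total_points_map_back_to_linear_predictor(self):
        fit = self._fit({"a": np.log(2), "b": np.log(4)})
        nom = nomogram_points(fit, {"a": (0.0, 1.0), "b": (0.0, 1.0)})
        # both covariates at their extremes: lp = log2 + log4, points = 150
        assert nom["total_to_lp"](150.0) == pytest.approx(np.log(2) + np.log(4))


class TestSir:
    def test_hand_two_stratum_example(self):
        rates = pd.DataFrame({"stratum": ["a", "b"], "rate": [0.001, 0.002]})
        py = pd.DataFrame({"stratum": ["a", "b"], "person_years": [1000.0, 500.0]})
        out = sir(4, rates, py, strata_cols=["stratum"])
        assert out["expected"] == pytest.approx(2.0)
        assert out["sir"] == pytest.approx(2.0)

    def test_doubling_rates_halves_sir(self):
        rates = pd.DataFrame({"stratum": ["a"], "rate": [0.01]})
        py = pd.DataFrame({"stratum": ["a"], "person_years": [100.0]})
        s1 = sir(3, rates, py, strata_cols=["stratum"])["sir"]
        rates2 = rates.assign(rate=rates["rate"] * 2)
        s2 = sir(3, rates2, py, strata_cols=["stratum"])["sir"]
        assert s2 == pytest.approx(s1 / 2)

    def test_zero_expected_with_events_raises(self):
        rates = pd.DataFrame({"stratum": ["a"], "rate": [0.0]})
        py = pd.DataFrame({"stratum": ["a"], "person_years": [100.0]})
        with pytest.raises(ValueError, match="expected"):
            sir(1, rates, py, strata_cols=["stratum"])

    def test_cohort_simulated_from_reference_rates_gives_sir_one(self):
        # reference rates equal to the generating hazards => SIR centered at 1
        rng = np.random.default_rng(2)
        rates = reference_rate_table().query("year_band == '2001-2007'").drop(columns="year_band")
        n = 40_000
        strata = rates.sample(n, replace=True, random_state=3, weights=None)
        haz = strata["rate"].to_numpy()
        t = rng.exponential(1 / np.maximum(haz, 1e-12))
        event = (t <= 10.0).astype(int)
        time = np.minimum(t, 10.0)
        cohort = strata.assign(time=time, event=event)
        py = cohort.groupby(["age_group", "gender"], as_index=False).agg(
            person_years=("time", "sum")
        )
        out = sir(int(event.sum()), rates, py, strata_cols=["age_group", "gender"])
        se = np.sqrt(out["observed"]) / out["expected"]
        assert abs(out["sir"] - 1.0) < 3 * se


class TestChi2AndPower:
    def test_balanced_table_statistic_zero(self):
        stat, p = chi2_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_closed_form_example(self):
        stat, _ = chi2_2x2([[20, 10], [10, 20]])
        assert stat == pytest.approx(60 * (20 * 20 - 10 * 10) ** 2 / 30**4)
        assert stat == pytest.approx(6.667, abs=1e-3)

    def test_matches_scipy_contingency(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = rng.integers(1, 50, size=(2, 2))
            stat, p = chi2_2x2(table)
            ref_stat, ref_p, _, _ = stats.chi2_contingency(table, correction=False)
            assert stat == pytest.approx(ref_stat)
            assert p == pytest.approx(ref_p)

    def test_power_at_null_effect_is_alpha(self):
        assert power_two_sample(30, 30, 0.0, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_standard_benchmark_64_per_arm(self):
        assert power_two_sample(64, 64, 0.5) == pytest.approx(0.80, abs=0.005)

    def test_power_monotone_in_effect_and_n(self):
        assert power_two_sample(30, 30, 0.8) > power_two_sample(30, 30, 0.4)
        assert power_two_sample(100, 100, 0.4) > power_two_sample(30, 30, 0.4)
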