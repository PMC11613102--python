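"""Fold changes, rank-sum p-values, BH FDR, calls, screening, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmcprog.differential import (
    DifferentialThresholds,
    bh_fdr,
    call_differential,
    cluster_cut_labels,
    covariate_screen,
    differential_table,
    hierarchical_cluster,
    log2_fold_change,
    wilcoxon_empirical_p,
)


def _groups(n_case, n_control):
    labels = ["case"] * n_case + ["control"] * n_control
    idx = [f"S{i}" for i in range(n_case + n_control)]
    return pd.Series(labels, index=idx)


class TestLog2FoldChange:
    def test_equal_group_means_give_zero(self):
        vals = pd.DataFrame(np.tile([5.0, 7.0], (3, 2)), columns=_groups(2, 2).index)
        lfc = log2_fold_change(vals, _groups(2, 2))
        np.testing.assert_allclose(lfc, 0.0)

    def test_twenty_percent_fold_change_is_lfc_0p263(self):
        vals = pd.DataFrame([[12.0, 12.0, 10.0, 10.0]], columns=_groups(2, 2).index)
        lfc = log2_fold_change(vals, _groups(2, 2), pseudocount=0.0)
        assert lfc.iloc[0] == pytest.approx(np.log2(1.2), abs=1e-12)
        assert lfc.iloc[0] == pytest.approx(0.263, abs=5e-4)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.uniform(1, 100, size=(50, 10)), columns=_groups(4, 6).index)
        groups = _groups(4, 6)
        lfc = log2_fold_change(vals, groups, pseudocount=1.0)
        case = vals.iloc[:, :4].to_numpy().mean(axis=1)
        ctrl = vals.iloc[:, 4:].to_numpy().mean(axis=1)
        np.testing.assert_allclose(lfc, np.log2((case + 1) / (ctrl + 1)))

    def test_label_swap_negates_lfc(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.uniform(1, 50, size=(20, 8)), columns=_groups(3, 5).index)
        g = _groups(3, 5)
        swapped = g.map({"case": "control", "control": "case"})
        np.testing.assert_allclose(
            log2_fold_change(vals, g), -log2_fold_change(vals, swapped), atol=1e-12
        )


class TestWilcoxonEmpiricalP:
    def test_complete_separation_two_by_two(self):
        raw, emp = wilcoxon_empirical_p([1.0, 2.0], [3.0, 4.0])
        assert raw == pytest.approx(2 / 6)
        assert emp == pytest.approx(1 / 6)

    def test_identical_multisets_give_p_one(self):
        raw, emp = wilcoxon_empirical_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert raw == 1.0
        assert emp == 0.5

    def test_constant_pooled_values_degenerate(self):
        raw, emp = wilcoxon_empirical_p([2.0, 2.0], [2.0, 2.0])
        assert raw == 1.0

    def test_exact_p_matches_full_enumeration(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=4)
        y = rng.normal(size=4)
        raw, _ = wilcoxon_empirical_p(x, y)
        # oracle: enumerate all C(8,4) assignments of the pooled values
        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        u_obs = ranks[:4].sum() - 4 * 5 / 2
        count = 0
        total = 0
        for combo in itertools.combinations(range(8), 4):
            u = ranks[list(combo)].sum() - 4 * 5 / 2
            # two-sided: as or more extreme in either direction
            if min(u, 16 - u) <= min(u_obs, 16 - u_obs):
                count += 1
            total += 1
        assert raw == pytest.approx(count / total)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_empirical_p([1.0], [2.0, 3.0])


class TestBhFdr:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    @staticmethod
    def _brute_force_bh(p):
        """Step-up definition: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        return q

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=0, max_value=100).map(lambda k: k / 100),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_brute_force_on_grid_vectors(self, p):
        np.testing.assert_allclose(bh_fdr(p), self._brute_force_bh(p), atol=1e-12)


class TestCallDifferential:
    def _records(self, lfc, p):
        return pd.DataFrame(
            {"feature_id": [f"f{i}" for i in range(len(lfc))], "log2fc": lfc, "p_empirical": p}
        )

    def test_hyper_hypo_and_ns(self):
        rec = call_differential(self._records([0.30, -0.40, 0.10], [0.01, 0.01, 0.01]))
        assert list(rec["direction"]) == ["hyper", "hypo", "ns"]

    def test_boundary_lfc_is_ns(self):
        rec = call_differential(self._records([0.26, -0.26], [0.001, 0.001]))
        assert list(rec["direction"]) == ["ns", "ns"]

    def test_boundary_p_is_ns(self):
        rec = call_differential(self._records([1.0], [0.05]))
        assert list(rec["direction"]) == ["ns"]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            DifferentialThresholds(lfc_min=0.0)

    def test_planted_effects_recovered(self):
        # 50 hyper + 50 hypo at |delta|=1 among 500 features, n=21/48
        rng = np.random.default_rng(7)
        n_case, n_ctrl = 21, 48
        base = rng.uniform(3, 6, size=500)
        vals = rng.normal(base[:, None], 0.5, size=(500, n_case + n_ctrl))
        vals[:50, :n_case] += 1.0
        vals[50:100, :n_case] -= 1.0
        scaled = pd.DataFrame(2.0 ** vals, columns=_groups(n_case, n_ctrl).index)
        table = differential_table(scaled, _groups(n_case, n_ctrl))
        rec = call_differential(table)
        called = rec["direction"] != "ns"
        assert called[:100].mean() >= 0.9
        assert called[100:].mean() <= 0.1
        assert (rec.loc[: 49, "direction"] == "hyper").mean() >= 0.9
        assert (rec.loc[50:99, "direction"] == "hypo").mean() >= 0.9


class TestCovariateScreen:
    def _meta(self, n, rng):
        idx = [f"S{i}" for i in range(n)]
        status = pd.Series(["case"] * (n // 3) + ["control"] * (n - n // 3), index=idx)
        age = pd.Series(rng.integers(40, 80, size=n), index=idx)
        gender = pd.Series(rng.choice(["male", "female"], size=n), index=idx)
        return status, age, gender

    def test_near_separating_feature_retained_and_flagged(self):
        rng = np.random.default_rng(0)
        n = 60
        status, age, gender = self._meta(n, rng)
        feat = (status == "case").astype(float) + rng.normal(0, 1e-4, size=n)
        vals = pd.DataFrame([feat.to_numpy()], index=["f0"], columns=status.index)
        out = covariate_screen(vals, status, age, gender)
        assert bool(out.loc[0, "candidate"])
        assert bool(out.loc[0, "separation"])

    def test_age_confounding_controlled(self):
        # age strongly (not perfectly) predicts status; the feature tracks age
        # only, so controlling for age must leave it non-significant
        rng = np.random.default_rng(1)
        n = 80
        idx = [f"S{i}" for i in range(n)]
        age = pd.Series(
            np.r_[rng.normal(66, 8, n // 2), rng.normal(54, 8, n // 2)].round(), index=idx
        )
        status = pd.Series(["case"] * (n // 2) + ["control"] * (n // 2), index=idx)
        gender = pd.Series(rng.choice(["male", "female"], size=n), index=idx)
        feat = age.to_numpy() / 10.0 + rng.normal(0, 0.2, size=n)
        vals = pd.DataFrame([feat], index=["f0"], columns=idx)
        out = covariate_screen(vals, status, age, gender, p_threshold=0.01)
        assert not bool(out.loc[0, "separation"])
        assert not bool(out.loc[0, "candidate"])


class TestHierarchicalCluster:
    def test_duplicate_samples_merge_first_at_zero_height(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        vals = pd.DataFrame(
            {"S0": x, "S1": x, "S2": rng.normal(size=30), "S3": rng.normal(size=30)}
        )
        res = hierarchical_cluster(vals)
        Z = res["linkage"]
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_two_planted_blocks_recovered_at_k2(self):
        rng = np.random.default_rng(2)
        sig = rng.normal(size=40)
        vals = pd.DataFrame(
            {
                "S0": sig + rng.normal(0, 0.1, 40),
                "S1": sig + rng.normal(0, 0.1, 40),
                "S2": -sig + rng.normal(0, 0.1, 40),
                "S3": -sig + rng.normal(0, 0.1, 40),
            }
        )
        labels = cluster_cut_labels(hierarchical_cluster(vals), k=2)
        assert labels["S0"] == labels["S1"]
        assert labels["S2"] == labels["S3"]
        assert labels["S0"] != labels["S2"]

    def test_single_sample_trivial_tree(self):
        vals = pd.DataFrame({"S0": [1.0, 2.0, 3.0]})
        res = hierarchical_cluster(vals)
        assert res["linkage"].shape == (0, 4)
        assert res["order"] == ["S0"]
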