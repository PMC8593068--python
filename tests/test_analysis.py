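import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from clinnet.analysis import (
    bootstrap_control_groups,
    build_trial_observations,
    clustered_choice_model,
    rank_sum_test,
    run_analysis,
    sensitivity_reanalysis,
    signed_rank_test,
)
from clinnet.clinical import DEFAULT_RULE, SENSITIVITY_RULE, CorrectnessRule
from clinnet.errors import MissingDataError
from clinnet.metrics import normalized_accuracy
from conftest import make_cfg, records_from_choices

from clinnet.simulate import simulate_study


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def oracle_rank_sum_p(a, b):
    """Exact two-sided p by enumerating every assignment of the pooled
    values to the two groups (permutation route, independent of the
    implementation's rank-combination route)."""
    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.permutations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


def oracle_signed_rank_p(d):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(ranks[np.array(signs, dtype=bool)].sum())
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# Bootstrap groups
# ---------------------------------------------------------------------------


class TestBootstrapGroups:
    def test_degenerate_pool_of_one(self):
        df = records_from_choices({"black_female": ["C"]})
        groups = bootstrap_control_groups(df, group_size=40, n_groups=1, seed=0)
        assert len(groups) == 1
        assert len(groups[0].members) == 40
        assert set(groups[0].members) == {"black_female-0"}

    def test_seed_determinism(self, small_study):
        a = bootstrap_control_groups(small_study, 40, 2, seed=5)
        b = bootstrap_control_groups(small_study, 40, 2, seed=5)
        assert [g.members for g in a] == [g.members for g in b]

    def test_group_means_concentrate_on_pool_mean(self):
        # bootstrap consistency: the average of many group means approaches
        # the direct pool mean
        rng = np.random.default_rng(0)
        estimates = rng.uniform(0, 100, 20)
        df = records_from_choices({"black_female": ["C"] * 20})
        df["estimate"] = estimates
        groups = bootstrap_control_groups(df, group_size=40, n_groups=400, seed=1)
        lookup = df.set_index("clinician_id")["estimate"]
        group_means = [np.mean([lookup[m] for m in g.members]) for g in groups]
        assert np.mean(group_means) == pytest.approx(estimates.mean(), abs=0.5)

    def test_empty_pool_raises(self, small_study):
        network_only = small_study[small_study["condition"] == "network"]
        with pytest.raises(MissingDataError):
            bootstrap_control_groups(network_only, 40, 1, seed=0)

    def test_one_group_per_cell(self, small_study):
        groups = bootstrap_control_groups(small_study, 40, 1, seed=0)
        cells = {(g.trial_id, g.arm) for g in groups}
        assert len(groups) == len(cells) == 4  # 2 trials x 2 arms


# ---------------------------------------------------------------------------
# Trial observations
# ---------------------------------------------------------------------------


class TestTrialObservations:
    def test_reference_study_gives_28(self, reference_study):
        obs = build_trial_observations(reference_study)
        assert len(obs) == 28

    def test_single_trial_gives_4(self):
        cfg = make_cfg(n_trials=1)
        obs = build_trial_observations(simulate_study(cfg))
        assert len(obs) == 4

    def test_accuracy_mean_matches_brute_force(self, small_study):
        obs = build_trial_observations(small_study)
        row = obs[(obs["trial_id"] == 1) & (obs["condition"] == "network")
                  & (obs["arm"] == "black_female")].iloc[0]
        cell = small_study[
            (small_study["trial_id"] == 1)
            & (small_study["condition"] == "network")
            & (small_study["arm"] == "black_female")
        ]
        expected = np.mean(
            [normalized_accuracy(e) for e in cell.loc[cell["round"] == 1, "estimate"]]
        )
        assert row["accuracy_initial"] == pytest.approx(expected)

    def test_bootstrap_groups_drive_control_observations(self, small_study):
        groups = bootstrap_control_groups(small_study, group_size=40, n_groups=1, seed=3)
        obs = build_trial_observations(small_study, groups=groups)
        g = groups[0]
        row = obs[(obs["trial_id"] == g.trial_id) & (obs["arm"] == g.arm)
                  & (obs["condition"] == "control")].iloc[0]
        cell = small_study[
            (small_study["trial_id"] == g.trial_id)
            & (small_study["condition"] == "control")
            & (small_study["arm"] == g.arm)
            & (small_study["round"] == 1)
        ].set_index("clinician_id")
        expected = np.mean([normalized_accuracy(cell.loc[m, "estimate"]) for m in g.members])
        assert row["accuracy_initial"] == pytest.approx(expected)

    def test_attrition_modes(self):
        cfg = make_cfg(completion_prob=0.6, master_seed=8)
        table = simulate_study(cfg)
        complete = build_trial_observations(table, attrition="complete_case")
        locf = build_trial_observations(table, attrition="locf")
        assert (complete["n"] <= locf["n"]).all()
        assert len(complete) == len(locf) == 8


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------


class TestRankSum:
    def test_identical_samples_p_one(self):
        with pytest.warns(UserWarning):
            _, p = rank_sum_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0

    def test_fully_separated_3v3(self):
        _, p = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)  # 2/20, the 3v3 minimum

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=5),
        st.lists(st.integers(0, 8), min_size=2, max_size=5),
    )
    def test_matches_enumeration_oracle(self, a, b):
        if len(set(a + b)) == 1:
            return
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(oracle_rank_sum_p(a, b), abs=1e-9)

    def test_matches_scipy_exact_when_tie_free(self, rng):
        a = rng.permutation(20)[:5].astype(float)
        b = (rng.permutation(20)[:6] + 100).astype(float)
        _, p = rank_sum_test(a, b)
        expected = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(expected, abs=1e-9)

    def test_large_sample_normal_path(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 30)
        _, p = rank_sum_test(a, b)
        expected = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(expected, rel=1e-6)


class TestSignedRank:
    def test_all_zero_differences_p_one(self):
        with pytest.warns(UserWarning):
            _, p = signed_rank_test([0.0, 0.0, 0.0])
        assert p == 1.0

    def test_seven_positive_differences(self):
        _, p = signed_rank_test([1.0] * 7)
        assert p == pytest.approx(2 / 128)

    def test_paired_form(self):
        _, p1 = signed_rank_test([3.0, 2.0], [1.0, 1.0])
        _, p2 = signed_rank_test([2.0, 1.0])
        assert p1 == p2

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(-6, 6), min_size=1, max_size=10))
    def test_matches_sign_enumeration_oracle(self, d):
        d_arr = np.asarray(d, dtype=float)
        if np.all(d_arr == 0):
            return
        _, p = signed_rank_test(d_arr)
        assert p == pytest.approx(oracle_signed_rank_p(d_arr), abs=1e-9)

    def test_matches_scipy_exact_when_clean(self, rng):
        d = rng.permutation(30)[:12].astype(float) + 1.0
        d[::3] *= -1
        _, p = signed_rank_test(d)
        expected = sps.wilcoxon(d, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(expected, abs=1e-9)

    def test_large_sample_normal_path(self, rng):
        d = rng.normal(0.4, 1, 60)
        d = d[d != 0]
        _, p = signed_rank_test(d)
        assert 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# Clustered logistic contracts
# ---------------------------------------------------------------------------


class TestClusteredChoiceModel:
    def test_null_covariate_or_near_one(self, rng):
        n = 2000
        data = pd.DataFrame(
            {
                "outcome": rng.random(n) < 0.3,
                "x": rng.random(n) < 0.5,
                "trial_id": rng.integers(0, 7, n),
            }
        )
        fit = clustered_choice_model(data, "outcome", ["x"])
        row = fit[fit["term"] == "x"].iloc[0]
        assert row["or_ci_low"] <= 1.0 <= row["or_ci_high"]

    def test_known_slope_recovered_at_study_size(self, rng):
        n = 840
        x = (rng.random(n) < 0.5).astype(float)
        true_or = 1.78
        logit = np.log(0.2 / 0.8) + np.log(true_or) * x
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        data = pd.DataFrame({"outcome": y, "x": x, "trial_id": rng.integers(0, 7, n)})
        fit = clustered_choice_model(data, "outcome", ["x"])
        row = fit[fit["term"] == "x"].iloc[0]
        assert row["or_ci_low"] <= true_or <= row["or_ci_high"]

    def test_clustered_se_exceeds_classical_under_clustering(self, rng):
        # strong positive intra-cluster correlation: cluster-level shocks
        import statsmodels.api as sm

        n_clusters, per = 10, 80
        shock = rng.normal(0, 2.0, n_clusters)
        rows = []
        for c in range(n_clusters):
            x = rng.random(per) < 0.5
            logit = -0.5 + 0.4 * x + shock[c]
            y = rng.random(per) < 1 / (1 + np.exp(-logit))
            rows.append(pd.DataFrame({"outcome": y, "x": x.astype(float), "trial_id": c}))
        data = pd.concat(rows, ignore_index=True)
        clustered = clustered_choice_model(data, "outcome", ["x"])
        X = sm.add_constant(data[["x"]])
        classical = sm.Logit(data["outcome"].astype(float), X).fit(disp=0)
        se_cl = clustered.loc[clustered["term"] == "const", "se"].iloc[0]
        assert se_cl >= classical.bse["const"]

    def test_separation_flagged_and_penalized_fallback(self):
        data = pd.DataFrame(
            {
                "outcome": [0, 0, 0, 1, 1, 1] * 5,
                "x": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0] * 5,
                "trial_id": list(range(6)) * 5,
            }
        )
        fit = clustered_choice_model(data, "outcome", ["x"], penalized=True)
        assert fit["separation"].any()
        assert np.isfinite(fit.loc[fit["term"] == "x", "odds_ratio"]).all()


# ---------------------------------------------------------------------------
# Study battery & sensitivity
# ---------------------------------------------------------------------------


class TestRunAnalysis:
    def test_observation_count_invariant(self, small_study):
        result = run_analysis(small_study)
        assert len(result.observations) == 2 * 4
        assert result.summary["n_observations"] == 8

    def test_deterministic(self, small_study):
        a = run_analysis(small_study, bootstrap_seed=3)
        b = run_analysis(small_study, bootstrap_seed=3)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.tests, b.tests)

    def test_sensitivity_rule_c_matches_default(self, small_study):
        default = run_analysis(small_study)
        same = sensitivity_reanalysis(small_study, CorrectnessRule.from_codes(["C"]))
        pd.testing.assert_frame_equal(default.observations, same.observations)

    def test_sensitivity_bc_rate_is_monotone(self, small_study):
        default = run_analysis(small_study)
        wider = sensitivity_reanalysis(small_study, SENSITIVITY_RULE)
        assert (
            wider.observations["correct_initial"] >= default.observations["correct_initial"] - 1e-12
        ).all()
        assert (
            wider.observations["correct_final"] >= default.observations["correct_final"] - 1e-12
        ).all()

    def test_all_b_dataset_rule_flip(self):
        r1 = records_from_choices({"black_female": ["B"] * 4, "white_male": ["B"] * 4}, round_no=1)
        r3 = records_from_choices({"black_female": ["B"] * 4, "white_male": ["B"] * 4}, round_no=3)
        df = pd.concat([r1, r3], ignore_index=True)
        obs_c = build_trial_observations(df, rule=DEFAULT_RULE)
        obs_bc = build_trial_observations(df, rule=SENSITIVITY_RULE)
        assert (obs_c["correct_final"] == 0.0).all()
        assert (obs_bc["correct_final"] == 1.0).all()
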