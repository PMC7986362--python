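"""Summaries, tests, adjusted means, correlations, profiles and matching."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from dialact.cohort_stats import (
    adjusted_marginal_means,
    group_mean_se,
    match_controls,
    paired_daytype_test,
    questionnaire_correlations,
    summaries_to_frame,
    summarize_participant,
    time_of_day_profile,
)
from dialact.raw_io import ParticipantRecord

from .conftest import make_grid


class TestSummarizeParticipant:
    def test_constant_grid(self):
        grid = make_grid(n_days=4, vm_value=15.5)
        s = summarize_participant(grid)
        assert s.get("dialysis", "vm") == pytest.approx(15.5)
        assert s.get("non-dialysis", "vm") == pytest.approx(15.5)
        assert s.get("overall", "vm") == pytest.approx(15.5)

    def test_walking_hours_unit_conversion(self):
        grid = make_grid(n_days=2, day_types=["non-dialysis"] * 2)
        grid.state[:, 600:660] = "walking"  # 60 min/day
        s = summarize_participant(grid)
        assert s.get("non-dialysis", "hours_walking") == pytest.approx(1.0)
        assert s.get("non-dialysis", "hours_sedentary") == pytest.approx(23.0)

    def test_state_hours_sum_to_24_on_complete_grid(self):
        grid = make_grid(n_days=3)
        grid.state[:, :300] = "sleep"
        grid.state[:, 300:350] = "walking"
        s = summarize_participant(grid)
        for ty in ("dialysis", "non-dialysis", "overall"):
            total = sum(s.get(ty, f"hours_{st}") for st in
                        ("walking", "light_tasks", "moderate", "sedentary", "sleep"))
            assert total == pytest.approx(24.0, abs=1e-9)

    def test_excluded_days_ignored(self):
        grid = make_grid(n_days=3, day_types=["excluded", "dialysis", "non-dialysis"])
        grid.vm[0, :] = 999.0
        s = summarize_participant(grid)
        assert s.get("overall", "vm") == pytest.approx(10.0)

    def test_missing_daytype_missing(self):
        grid = make_grid(n_days=2, day_types=["non-dialysis"] * 2)
        s = summarize_participant(grid)
        assert np.isnan(s.get("dialysis", "vm"))


class TestGroupMeanSe:
    def test_hand_case(self):
        df = pd.DataFrame({"g": ["a", "a"], "y": [10.0, 20.0]})
        out = group_mean_se(df, "g", ["y"])
        assert out.loc[0, "y_mean"] == pytest.approx(15.0)
        # sd = 7.0711, SE = sd / sqrt(2) = 5
        assert out.loc[0, "y_se"] == pytest.approx(5.0)

    def test_single_member_group(self):
        df = pd.DataFrame({"g": ["a"], "y": [3.0]})
        out = group_mean_se(df, "g", ["y"])
        assert out.loc[0, "y_mean"] == 3.0
        assert np.isnan(out.loc[0, "y_se"])

    def test_zero_variance(self):
        df = pd.DataFrame({"g": ["a"] * 4, "y": [2.0] * 4})
        assert group_mean_se(df, "g", ["y"]).loc[0, "y_se"] == 0.0

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"g": rng.choice(["a", "b"], 40), "y": rng.normal(size=40)})
        shuffled = df.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(
            group_mean_se(df, "g", ["y"]).reset_index(drop=True),
            group_mean_se(shuffled, "g", ["y"]).reset_index(drop=True),
        )


class TestPairedTest:
    def test_identical_values_null(self):
        df = pd.DataFrame({"vm_dialysis": [10, 12, 14.0], "vm_non-dialysis": [10, 12, 14.0]})
        res = paired_daytype_test(df, "vm")
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_hand_formula(self):
        # differences {1,2,3}: t = 2 / (1/sqrt(3)) = 2*sqrt(3) = 3.4641...
        df = pd.DataFrame(
            {"vm_dialysis": [11.0, 14.0, 17.0], "vm_non-dialysis": [10.0, 12.0, 14.0]}
        )
        res = paired_daytype_test(df, "vm")
        assert res["t"] == pytest.approx(2 * np.sqrt(3.0), abs=1e-9)

    def test_degenerate_constant_difference(self):
        df = pd.DataFrame({"vm_dialysis": [11.0, 13.0], "vm_non-dialysis": [10.0, 12.0]})
        res = paired_daytype_test(df, "vm")
        assert res["degenerate"]
        assert res["p"] <= np.finfo(float).tiny

    def test_power_against_generator_deficit(self):
        # n = 73 with a true 1.4 mg dialysis deficit and ~1 mg within-person
        # noise on each day-type mean: paired t must reject at p < 0.001
        rng = np.random.default_rng(9)
        rejections = 0
        for _ in range(20):
            person = rng.normal(15.5, 4.2, size=73)
            d = person - 1.4 / 2 + rng.normal(0, 1.0 / np.sqrt(5), size=73)
            n = person + 1.4 / 2 + rng.normal(0, 1.0 / np.sqrt(7), size=73)
            df = pd.DataFrame({"vm_dialysis": d, "vm_non-dialysis": n})
            if paired_daytype_test(df, "vm")["p"] < 0.001:
                rejections += 1
        assert rejections >= 19


class TestAdjustedMarginalMeans:
    @staticmethod
    def _frame(rng, n=200, confounded=False):
        age = rng.uniform(40, 90, size=n)
        if confounded:
            group = np.where(age + rng.normal(0, 5, n) > 65, "a", "b")
        else:
            group = rng.choice(["a", "b"], size=n)
        y = 40 - 0.3 * age + rng.normal(0, 1.0, size=n)
        return pd.DataFrame(
            {"y": y, "group": group, "age": age,
             "sex": rng.choice(["male", "female"], n),
             "leg_weakness": rng.random(n) < 0.5}
        )

    def test_no_confounding_equals_raw_means(self):
        rng = np.random.default_rng(1)
        df = self._frame(rng)
        res = adjusted_marginal_means(df, "y", "group")
        raw = df.groupby("group")["y"].mean()
        for lev, (mm, _) in res["marginal_means"].items():
            assert abs(mm - raw[lev]) < 0.3

    def test_age_confounding_removed(self):
        rng = np.random.default_rng(2)
        df = self._frame(rng, confounded=True)
        res = adjusted_marginal_means(df, "y", "group")
        mms = res["marginal_means"]
        adj_diff = mms["a"][0] - mms["b"][0]
        se = np.hypot(mms["a"][1], mms["b"][1])
        raw_diff = df.groupby("group")["y"].mean().diff().iloc[-1]
        assert abs(adj_diff) < 2.5 * se  # adjusted difference ~ 0
        assert abs(raw_diff) > 1.0  # unadjusted difference is large

    def test_exact_linear_fit(self):
        age = np.linspace(40, 80, 40)
        group = np.asarray(["a", "b"] * 20)
        df = pd.DataFrame(
            {"y": 5 + 0.5 * age, "group": group, "age": age,
             "sex": ["male"] * 40, "leg_weakness": [False] * 40}
        )
        res = adjusted_marginal_means(df, "y", "group", adjust_for=("age",))
        a, b = res["marginal_means"]["a"][0], res["marginal_means"]["b"][0]
        assert abs(a - b) < 1e-8
        assert res["model"].ssr < 1e-16

    def test_rank_deficiency_names_term(self):
        df = pd.DataFrame(
            {"y": [1.0, 2, 3, 4], "group": ["a", "a", "b", "b"],
             "age": [50.0, 50, 60, 60], "dup": [50.0, 50, 60, 60]}
        )
        with pytest.raises(ValueError, match="aliased"):
            adjusted_marginal_means(df, "y", "group", adjust_for=("age", "dup"))

    def test_trend_detects_ordered_gradient(self):
        rng = np.random.default_rng(3)
        n = 150
        group = rng.choice(["t1", "t2", "t3"], size=n)
        effect = pd.Series({"t1": 0.0, "t2": 1.0, "t3": 2.0})
        df = pd.DataFrame(
            {"y": effect[group].to_numpy() + rng.normal(0, 1, n),
             "group": group, "age": rng.uniform(40, 90, n)}
        )
        res = adjusted_marginal_means(
            df, "y", "group", adjust_for=("age",), ordered_levels=["t1", "t2", "t3"]
        )
        assert res["trend_p"] < 1e-6
        assert res["heterogeneity_p"] < 1e-6


class TestSpearman:
    def test_monotone(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4.0], "s": [10, 20, 30, 40.0]})
        out = questionnaire_correlations(df, ["a"], ["s"])
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_antitone(self):
        df = pd.DataFrame({"a": [1, 2, 3.0], "s": [3, 2, 1.0]})
        assert questionnaire_correlations(df, ["a"], ["s"]).loc[0, "rho"] == pytest.approx(-1.0)

    def test_hand_rank_case(self):
        # pairs (1,2),(2,1),(3,3): rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 6*2/24 = 0.5
        df = pd.DataFrame({"a": [1.0, 2, 3], "s": [2.0, 1, 3]})
        assert questionnaire_correlations(df, ["a"], ["s"]).loc[0, "rho"] == pytest.approx(
            0.5, abs=1e-9
        )

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "s": [5.0, 5, 5]})
        out = questionnaire_correlations(df, ["a"], ["s"])
        assert out.loc[0, "constant"]
        assert np.isnan(out.loc[0, "rho"])

    def test_too_few_pairs(self):
        df = pd.DataFrame({"a": [1.0, 2], "s": [2.0, 1]})
        with pytest.raises(ValueError):
            questionnaire_correlations(df, ["a"], ["s"])

    def test_fdr_option_adds_adjusted_p(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=["a1", "a2", "s1", "s2"])
        out = questionnaire_correlations(df, ["a1", "a2"], ["s1", "s2"], fdr=True)
        assert "p_fdr" in out.columns
        assert (out["p_fdr"] >= out["p"] - 1e-12).all()  # BH never lowers p


class TestProfiles:
    def test_constant_grid_flat_curve(self):
        grids = [make_grid(n_days=2, vm_value=10.0, participant_id=f"P{i}") for i in range(3)]
        prof = time_of_day_profile(grids, bin_min=10)
        np.testing.assert_allclose(prof["mean"], 10.0)
        np.testing.assert_allclose(prof["ci_high"] - prof["ci_low"], 0.0, atol=1e-12)

    def test_dialysis_morning_dip(self):
        # morning dialysis block: 08:00-12:00 minutes near zero on dialysis days
        grids = []
        for i in range(5):
            g = make_grid(n_days=4, day_types=["dialysis", "non-dialysis"] * 2,
                          vm_value=20.0, participant_id=f"P{i}")
            for d, (_, ty) in enumerate(g.days):
                if ty == "dialysis":
                    g.vm[d, 480:720] = 2.0
            grids.append(g)
        dial = time_of_day_profile(grids, day_type="dialysis", bin_min=60)
        non = time_of_day_profile(grids, day_type="non-dialysis", bin_min=60)
        assert (dial["mean"][8:12] < non["mean"][8:12] - 10).all()

    def test_state_probabilities_partition(self):
        rng = np.random.default_rng(5)
        grids = []
        for i in range(3):
            g = make_grid(n_days=2, participant_id=f"P{i}")
            g.state[:] = rng.choice(
                ["walking", "light_tasks", "moderate", "sedentary", "sleep"],
                size=g.state.shape,
            ).astype(object)
            grids.append(g)
        total = np.zeros(1440 // 60)
        for st in ("walking", "light_tasks", "moderate", "sedentary", "sleep"):
            total = total + time_of_day_profile(
                grids, bin_min=60, outcome="state", state=st
            )["mean"].to_numpy()
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_bad_bin(self):
        with pytest.raises(ValueError):
            time_of_day_profile([make_grid()], bin_min=7)


def person(pid, age, sex="male", season="winter"):
    return ParticipantRecord(id=pid, age=age, sex=sex, wear_season=season)


class TestMatching:
    def test_saturated_pool_gives_five_each(self):
        cases = [person(f"D{i}", 60 + i) for i in range(4)]
        pool = [
            person(f"C{i}_{j}", 60 + i) for i in range(4) for j in range(6)
        ]
        sets, unmatched = match_controls(cases, pool, k=5, seed=0)
        assert not unmatched
        assert all(len(s.control_ids) == 5 for s in sets)

    def test_out_of_range_case_unmatched(self):
        cases = [person("D1", 90.0)]
        pool = [person(f"C{i}", 60.0 + i % 15) for i in range(30)]
        sets, unmatched = match_controls(cases, pool, k=5, age_caliper=3.0, seed=0)
        assert unmatched == ["D1"]
        assert not sets

    def test_no_control_reused(self):
        rng = np.random.default_rng(1)
        cases = [person(f"D{i}", float(rng.uniform(55, 70))) for i in range(10)]
        pool = [person(f"C{i}", float(rng.uniform(50, 75))) for i in range(40)]
        sets, _ = match_controls(cases, pool, k=5, seed=2)
        used = [c for s in sets for c in s.control_ids]
        assert len(used) == len(set(used))

    def test_exact_sex_and_season(self):
        cases = [person("D1", 60.0, sex="female", season="summer")]
        pool = [
            person("C1", 60.0, sex="male", season="summer"),
            person("C2", 60.0, sex="female", season="winter"),
            person("C3", 61.0, sex="female", season="summer"),
        ]
        sets, _ = match_controls(cases, pool, seed=0)
        assert sets[0].control_ids == ["C3"]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        cases = [person(f"D{i}", float(rng.uniform(55, 70))) for i in range(8)]
        pool = [person(f"C{i}", float(rng.uniform(50, 75))) for i in range(30)]
        a, _ = match_controls(cases, pool, seed=5)
        b, _ = match_controls(cases, pool, seed=5)
        assert [(s.case_id, tuple(s.control_ids)) for s in a] == [
            (s.case_id, tuple(s.control_ids)) for s in b
        ]

    def test_bad_inputs(self):
        cases = [person("D1", 60.0)]
        with pytest.raises(ValueError):
            match_controls(cases, [person("C1", 60.0)], k=0)
        with pytest.raises(ValueError):
            match_controls(cases, [person("D1", 60.0)], k=5)


class TestSummariesFrame:
    def test_flattening(self):
        grid = make_grid(n_days=4, vm_value=12.0)
        df = summaries_to_frame([summarize_participant(grid)])
        assert df.loc[0, "vm_overall"] == pytest.approx(12.0)
        assert df.loc[0, "hours_sedentary_dialysis"] == pytest.approx(24.0)
        assert df.loc[0, "n_days_overall"] == 4
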