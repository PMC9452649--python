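"""Statistical pipeline: transforms, mixed models, bootstrap, effect sizes."""

import numpy as np
import pandas as pd
import pytest

from courtload import stats as st, synth


class TestNormality:
    def test_normal_sample_usually_passes(self):
        passes = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=500)
            _, p, fails = st.normality_check(x)
            passes += not fails
        assert passes >= 18  # ≥90% of reseeded runs

    def test_lognormal_sample_fails(self):
        x = np.random.default_rng(0).lognormal(0, 1, 500)
        _, p, fails = st.normality_check(x)
        assert fails and p < 0.05

    def test_tiny_or_constant_input_rejected(self):
        with pytest.raises(ValueError):
            st.normality_check([1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            st.normality_check([3.0] * 10)


class TestLogTransform:
    def test_offset_variables(self):
        df = pd.DataFrame({"minutes_played": [0.0, np.e - 1],
                           "avf_net_n": [100.0, 200.0]})
        out, offsets = st.log_transform(df, ["minutes_played", "avf_net_n"],
                                        offset_variables=["minutes_played"])
        assert out.minutes_played.tolist() == pytest.approx([0.0, 1.0])
        assert offsets == {"minutes_played": 1.0, "avf_net_n": 0.0}
        np.testing.assert_allclose(np.exp(out.avf_net_n), df.avf_net_n)

    def test_zero_in_non_offset_variable_is_named(self):
        df = pd.DataFrame({"impulse_kns": [0.0, 5.0]})
        with pytest.raises(ValueError, match="impulse_kns"):
            st.log_transform(df, ["impulse_kns"])


class TestEffectSizes:
    @pytest.mark.parametrize("f,df1,df2,expected,cat", [
        (3.25, 2, 342, 0.02, "small"),
        (5.22, 2, 342, 0.03, "small"),
        (0.0, 2, 342, 0.0, "negligible"),
    ])
    def test_partial_eta_squared_values(self, f, df1, df2, expected, cat):
        eta, category = st.partial_eta_squared(f, df1, df2)
        assert round(eta, 2) == expected
        assert category == cat

    def test_discrepant_reported_value_warns(self):
        with pytest.warns(UserWarning, match="disagrees"):
            st.partial_eta_squared(7.74, 2, 462, reported=0.05)

    @pytest.mark.parametrize("eta,cat", [
        (0.01, "small"), (0.04, "small"), (0.041, "medium"),
        (0.14, "medium"), (0.15, "large")])
    def test_eta_category_bins(self, eta, cat):
        assert st.eta_category(eta) == cat

    def test_cohens_d_definition_and_bins(self):
        a = np.array([0.0, 1.0, -1.0, 0.5, -0.5])
        d, cat = st.cohens_d_log(a, a)  # identical groups
        assert d == 0.0 and cat == "trivial"
        # means 0 vs 1, pooled SD 1 -> d = 1, moderate
        r = np.random.default_rng(0)
        x = r.normal(0, 1, 100000)
        d, cat = st.cohens_d_log(x, x + 1.0)
        assert d == pytest.approx(1.0, abs=0.02)
        assert cat == "moderate"
        assert st.d_category(0.2) == "small"  # closed lower bound
        assert st.d_category(2.5) == "very large"

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            st.cohens_d_log([1.0, 1.0], [2.0, 2.0])

    def test_bonferroni(self):
        assert st.bonferroni(0.01, 3) == pytest.approx(0.03)
        assert st.bonferroni(0.5, 4) == 1.0
        assert st.bonferroni(0.04, 1) == 0.04


class TestBootstrap:
    def test_identical_groups_md_zero_ci_straddles(self):
        x = np.random.default_rng(1).normal(0, 1, 80)
        c = st.bootstrap_mean_difference(x, x, seed=0)
        assert c.md == 0.0
        assert c.ci_low <= 0.0 <= c.ci_high

    def test_constant_shift_exact_md_and_shrinking_ci(self):
        x = np.random.default_rng(2).normal(0, 1, 60)
        c = st.bootstrap_mean_difference(x, x + 5.0, seed=0)
        assert c.md == pytest.approx(5.0)
        tight = st.bootstrap_mean_difference(x * 1e-6, x * 1e-6 + 5.0, seed=0)
        assert (tight.ci_high - tight.ci_low) < 1e-4

    def test_deterministic_under_seed_and_warns_on_few_reps(self):
        x = np.random.default_rng(3).normal(0, 1, 50)
        c1 = st.bootstrap_mean_difference(x, x + 1, seed=9)
        c2 = st.bootstrap_mean_difference(x, x + 1, seed=9)
        assert (c1.ci_low, c1.ci_high) == (c2.ci_low, c2.ci_high)
        with pytest.warns(UserWarning, match="resamples"):
            st.bootstrap_mean_difference(x, x, reps=50, seed=0)
        with pytest.raises(ValueError):
            st.bootstrap_mean_difference([], x)

    def test_iid_coverage_quick(self):
        """95% percentile CI covers a planted shift in most replicates
        (full 500-replicate calibration lives in the acceptance suite)."""
        cover = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            a = r.normal(0, 10, 60)
            b = r.normal(5.0, 10, 60)
            c = st.bootstrap_mean_difference(a, b, reps=500, seed=rep)
            cover += c.ci_low <= 5.0 <= c.ci_high
        assert cover >= 85


class TestMixedModel:
    def test_balanced_identical_groups_give_f_near_zero(self):
        # each subject contributes the same values to both periods
        df = pd.DataFrame({
            "y": np.tile([1.0, 2.0, 1.0, 2.0], 10),
            "season_period": ["regular", "regular", "finals", "finals"] * 10,
            "player_id": np.repeat([f"P{i}" for i in range(10)], 4)})
        res = st.fit_lmm(df, "y", fixed=("season_period",))
        assert res.term("season_period").F == pytest.approx(0.0, abs=1e-6)

    def test_planted_effect_detected(self):
        df = synth.simulate_lmm_dataset(effect=1.0, seed=3)
        p = st.lmm_condition_pvalue(df)
        assert p < 1e-6

    def test_single_level_factor_rejected(self):
        df = synth.simulate_lmm_dataset(seed=0)
        df["season_period"] = "regular"
        with pytest.raises(ValueError, match="levels"):
            st.fit_lmm(df, "y", fixed=("season_period",))


class TestDecisionTree:
    @staticmethod
    def _branches(effect_fn, seeds):
        out = []
        for s in seeds:
            df = synth.simulate_factorial_cohort(seed=s,
                                                 period_effect=effect_fn)
            out.append(st.interaction_decision_tree(df, "y", seed=s).branch)
        return out

    def test_planted_three_way_selects_per_role_team(self):
        b = self._branches(
            lambda r, t: 1.5 if (r == "starter") ^ (t == "men") else -1.5,
            range(20))
        assert b.count("per_role_team") >= 18  # ≥90%

    def test_planted_role_interaction_selects_per_role(self):
        shifts = {"starter": 1.2, "in_rotation": 0.0, "out_rotation": -1.2}
        b = self._branches(lambda r, t: shifts[r], range(100, 115))
        assert b.count("per_role") >= 12

    def test_pure_main_effect_selects_main_branch_and_significance(self):
        df = synth.simulate_factorial_cohort(seed=42,
                                             period_effect=lambda r, t: 0.8)
        tree = st.interaction_decision_tree(df, "y", seed=42)
        assert tree.branch == "main_effect"
        assert tree.reduced_model.p("season_period") <= 0.05
        assert len(tree.comparisons) == 1

    def test_null_data_mostly_finds_nothing(self):
        b = self._branches(lambda r, t: 0.0, range(300, 320))
        # under the null every interaction/simple-effect test fires ~5%
        assert b.count("main_effect") >= 14

    def test_branch_log_records_every_decision(self):
        df = synth.simulate_factorial_cohort(seed=1,
                                             period_effect=lambda r, t: 0.0)
        tree = st.interaction_decision_tree(df, "y", seed=1)
        steps = [e["step"] for e in tree.log]
        assert "3-way interaction" in steps and "branch" in steps

    def test_missing_cell_is_named(self):
        df = synth.simulate_factorial_cohort(seed=2)
        df = df[~((df.role == "starter") & (df.season_period == "finals"))]
        with pytest.raises(ValueError, match="starter"):
            st.interaction_decision_tree(df, "y")


class TestSampleSize:
    def test_study_design_reproduced(self):
        d = st.sample_size_lmm(0.40, 0.80, 0.05, 23, 0.05)
        assert d.total_n == 331
        assert d.obs_per_subject == 14

    def test_zero_icc_removes_design_effect(self):
        d = st.sample_size_lmm(0.40, 0.80, 0.05, 23, 0.0)
        assert d.total_n == int(np.ceil(d.base_total_n))

    def test_unsolvable_design_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            st.sample_size_lmm(0.40, 0.80, 0.05, 5, 0.5)


class TestReporting:
    def test_median_iqr_formatting(self):
        assert st.format_median_iqr([1, 2, 3, 4, 5]) == "3.0 (2.0–4.0)"
        assert st.format_median_iqr([7.0]) == "7.0 (7.0–7.0)"
        assert st.format_median_iqr([]) == ""

    def test_report_table_shapes_and_missing_cells(self):
        df = pd.DataFrame({
            "role": ["starter"] * 4 + ["in_rotation"] * 2,
            "season_period": ["regular", "finals"] * 2 + ["regular"] * 2,
            "avf_net_n": [300.0, 310.0, 305.0, 320.0, 220.0, 230.0]})
        tab = st.report_table(df, ["avf_net_n"])
        assert "in_rotation/finals" not in tab.columns
        assert tab.loc[0, "starter/regular"] != ""
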