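"""Missing-data machinery: outcome rule, mean imputation, MICE-PMM,
Rubin pooling, MNAR pattern-mixture adjustment."""

import numpy as np
import pandas as pd
import pytest

from quitcost.imputation import (ImputationPlan, abstinence_missing_rule,
                                 choose_m, mean_impute_baseline, mice_pmm,
                                 mnar_adjust, rubin_pool)
from quitcost.trialgen import default_trial_config, generate_trial


class TestAbstinenceMissingRule:
    def test_all_missing_becomes_not_abstinent(self):
        df = pd.DataFrame({"abstinent_co": [np.nan, np.nan, np.nan]})
        out = abstinence_missing_rule(df)
        assert (out["abstinent_co"] == 0.0).all()

    def test_fully_observed_is_identity(self):
        df = pd.DataFrame({"abstinent_co": [1.0, 0.0, 1.0]})
        assert abstinence_missing_rule(df)["abstinent_co"].tolist() == [1, 0, 1]

    def test_rate_uses_randomized_denominator(self):
        # 20 observed abstainers among 488 including missing -> 4.1%
        col = [1.0] * 20 + [0.0] * 300 + [np.nan] * 168
        df = pd.DataFrame({"abstinent_co": col})
        out = abstinence_missing_rule(df)
        assert out["abstinent_co"].mean() == pytest.approx(20 / 488)
        assert round(100 * out["abstinent_co"].mean(), 1) == 4.1


class TestMeanImputeBaseline:
    def test_two_point_mean(self):
        df = pd.DataFrame({"age": [40.0, np.nan, 44.0]})
        out = mean_impute_baseline(df, ["age"])
        assert out["age"].tolist() == [40.0, 42.0, 44.0]

    def test_fully_observed_identity(self):
        df = pd.DataFrame({"age": [40.0, 44.0]})
        assert mean_impute_baseline(df, ["age"]).equals(df)

    def test_mixed_table_matches_columnwise_oracle(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        df.loc[::7, "a"] = np.nan
        df.loc[::5, "b"] = np.nan
        oracle = {c: df[c].dropna().mean() for c in df}
        out = mean_impute_baseline(df, ["a", "b"])
        for c in df:
            np.testing.assert_allclose(out.loc[df[c].isna(), c], oracle[c])

    def test_followup_variables_untouched(self):
        df = pd.DataFrame({"age": [40.0, np.nan],
                           "utility_6m": [np.nan, 0.5]})
        out = mean_impute_baseline(df, ["age"])
        assert out["utility_6m"].isna().sum() == 1

    def test_all_missing_column_errors(self):
        df = pd.DataFrame({"age": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="age"):
            mean_impute_baseline(df, ["age"])


@pytest.fixture(scope="module")
def prepared_mar(mar_trial):
    base = abstinence_missing_rule(mar_trial)
    return mean_impute_baseline(base)


class TestMicePmm:
    def test_no_missing_gives_identical_copies(self, small_trial):
        plan = ImputationPlan(m=3, n_cycles=2, seed=1)
        imp = mice_pmm(small_trial, plan)
        assert imp.m == 3
        for df in imp.datasets:
            pd.testing.assert_frame_equal(df, small_trial)

    def test_pmm_membership_in_donor_pool(self):
        # single missing cost with observed donors {0, 10, 20}
        df = pd.DataFrame({
            "arm": ["control"] * 4,
            "site": [1, 1, 1, 1],
            "x": [0.1, 0.5, 0.9, 0.4],
            "cost": [0.0, 10.0, 20.0, np.nan],
        })
        plan = ImputationPlan(m=8, pmm_donors=3, n_cycles=3, seed=2,
                              variables={"cost": "pmm"}, predictors=["x"],
                              stratify_by_site=False)
        imp = mice_pmm(df, plan)
        for completed in imp.datasets:
            assert completed.loc[3, "cost"] in {0.0, 10.0, 20.0}

    def test_imputed_values_come_from_observed_pool_within_arm(self,
                                                               prepared_mar):
        plan = ImputationPlan(m=2, n_cycles=3, seed=3)
        imp = mice_pmm(prepared_mar, plan)
        for var in ("cost_secondary", "utility_6m"):
            mask = imp.missing_mask[var]
            for completed in imp.datasets:
                for arm in ("control", "intervention"):
                    in_arm = prepared_mar["arm"] == arm
                    observed = set(prepared_mar.loc[in_arm & ~mask, var])
                    imputed = completed.loc[in_arm & mask, var]
                    assert set(imputed) <= observed

    def test_no_analysis_variable_missing_after_imputation(self, prepared_mar):
        plan = ImputationPlan(m=2, n_cycles=2, seed=4)
        imp = mice_pmm(prepared_mar, plan)
        for completed in imp.datasets:
            assert not completed[list(plan.variables)].isna().any().any()

    def test_seed_determinism(self, prepared_mar):
        plan = ImputationPlan(m=2, n_cycles=2, seed=5)
        a = mice_pmm(prepared_mar, plan)
        b = mice_pmm(prepared_mar, plan)
        for x, y in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(x, y)

    def test_mar_mean_recovery_within_3se(self):
        # complete ground truth, then 30% MAR missingness imposed on the
        # 6-month utility; pooled post-imputation mean must sit within 3
        # pooled standard errors of the complete-data mean
        cfg = default_trial_config(
            seed=6, n_control=800, n_intervention=800,
            followup_prob={"control": 1.0, "intervention": 1.0},
            mar_coefficients={}, item_missing_prob=0.0,
            baseline_missing_prob=0.0)
        complete = generate_trial(cfg).records
        truth = complete["utility_6m"].mean()
        rng = np.random.default_rng(7)
        amputated = complete.copy()
        p_miss = 1 / (1 + np.exp(-(-2.2 + 0.03 * amputated["ftcd"]
                                   + 0.9 * (amputated["utility_baseline"] < 0.5))))
        drop = rng.random(len(amputated)) < p_miss * (0.30 / p_miss.mean())
        amputated.loc[drop, "utility_6m"] = np.nan
        assert 0.2 < drop.mean() < 0.4
        plan = ImputationPlan(m=10, n_cycles=5, seed=8)
        imp = mice_pmm(amputated, plan)
        means = [d["utility_6m"].mean() for d in imp.datasets]
        variances = [d["utility_6m"].var(ddof=1) / len(d) for d in imp.datasets]
        pooled = rubin_pool(means, variances)
        assert abs(pooled.estimate - truth) < 3 * pooled.se

    def test_diagnostics_report_missing_fractions(self, prepared_mar):
        plan = ImputationPlan(m=1, n_cycles=1, seed=9)
        imp = mice_pmm(prepared_mar, plan)
        oracle = prepared_mar[list(plan.variables)].isna().mean()
        for var, frac in imp.diagnostics.items():
            assert frac == pytest.approx(oracle[var])

    def test_write_manifest(self, prepared_mar, tmp_path):
        plan = ImputationPlan(m=2, n_cycles=1, seed=10)
        imp = mice_pmm(prepared_mar, plan)
        imp.write(tmp_path / "imps")
        assert (tmp_path / "imps" / "imp_1.csv").exists()
        assert (tmp_path / "imps" / "manifest.json").exists()


class TestChooseM:
    @pytest.mark.parametrize("fractions,expected", [
        ([0.45], 45),
        ([0.0], 1),
        ([0.10, 0.31], 31),
        ([0.001], 1),
    ])
    def test_rule(self, fractions, expected):
        assert choose_m(fractions) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            choose_m([])


class TestRubinPool:
    def test_identical_estimates_total_equals_within(self):
        pooled = rubin_pool([2.0, 2.0, 2.0], [1.5, 1.5, 1.5])
        assert pooled.estimate == pytest.approx(2.0)
        assert pooled.variance == pytest.approx(1.5)

    def test_hand_computed_two_imputation_case(self):
        pooled = rubin_pool([1.0, 3.0], [1.0, 1.0])
        assert pooled.estimate == pytest.approx(2.0)
        assert pooled.variance == pytest.approx(1.0 + 1.5 * 2.0)

    def test_zero_between_variance_ci_matches_single_dataset(self):
        from scipy import stats
        pooled = rubin_pool([5.0, 5.0], [4.0, 4.0], df_complete=100)
        single_half = stats.t.ppf(0.975, 100) * 2.0
        assert pooled.ci_high - pooled.estimate == pytest.approx(single_half)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            rubin_pool([1.0, 2.0], [1.0])

    def test_barnard_rubin_df_below_classic(self):
        classic = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        corrected = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0],
                               df_complete=50)
        assert corrected.df < classic.df


class TestMnarAdjust:
    @pytest.fixture
    def imputed(self, prepared_mar):
        plan = ImputationPlan(m=2, n_cycles=2, seed=11)
        return mice_pmm(prepared_mar, plan)

    def test_unit_factors_identity(self, imputed):
        out = mnar_adjust(imputed, 1.0, 1.0)
        for a, b in zip(out.datasets, imputed.datasets):
            pd.testing.assert_frame_equal(a, b)

    def test_only_imputed_cells_scaled(self, imputed):
        out = mnar_adjust(imputed, cost_factor=1.3, utility_factor=0.8)
        mask_c = imputed.missing_mask["cost_secondary"]
        mask_u = imputed.missing_mask["utility_6m"]
        for before, after in zip(imputed.datasets, out.datasets):
            np.testing.assert_allclose(
                after.loc[mask_c, "cost_secondary"],
                before.loc[mask_c, "cost_secondary"] * 1.3)
            np.testing.assert_allclose(
                after.loc[mask_u, "utility_6m"],
                before.loc[mask_u, "utility_6m"] * 0.8)
            # observed cells bit-identical
            pd.testing.assert_series_equal(
                after.loc[~mask_c, "cost_secondary"],
                before.loc[~mask_c, "cost_secondary"])
            pd.testing.assert_series_equal(
                after.loc[~mask_u, "utility_6m"],
                before.loc[~mask_u, "utility_6m"])

    def test_single_imputed_cost_scaled_observed_neighbour_unchanged(self):
        df = pd.DataFrame({
            "arm": ["control"] * 4, "site": 1,
            "x": [0.0, 1.0, 2.0, 3.0],
            "cost_secondary": [100.0, 100.0, 50.0, np.nan],
        })
        plan = ImputationPlan(m=1, pmm_donors=2, n_cycles=2, seed=12,
                              variables={"cost_secondary": "pmm"},
                              predictors=["x"], stratify_by_site=False)
        imp = mice_pmm(df, plan)
        imputed_value = imp.datasets[0].loc[3, "cost_secondary"]
        out = mnar_adjust(imp, cost_factor=1.3)
        assert out.datasets[0].loc[3, "cost_secondary"] == pytest.approx(
            1.3 * imputed_value)
        assert out.datasets[0].loc[0, "cost_secondary"] == 100.0

    def test_non_positive_factors_rejected(self, imputed):
        with pytest.raises(ValueError):
            mnar_adjust(imputed, cost_factor=0.0)
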