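"""Mixed-model machinery, effect-size conversions, and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest

from eapipe import (
    EffectSpec,
    MixedEAModel,
    build_analysis_table,
    cohens_d_from_f,
    cohens_d_from_t,
    cronbach_alpha,
    drinking_summaries,
    fit_mixed_model,
    generate_ea_z_table,
    generate_questionnaires,
    one_sample_t,
    score_audit,
    two_sample_t,
)
from eapipe.exceptions import InvalidArgumentError, UndefinedStatisticError


class TestEffectSizeConversions:
    # the full set of printed F/d and t/d pairs from the study report
    @pytest.mark.parametrize(
        "f_stat, df_den, expected_d",
        [(17.86, 53, 1.16), (0.29, 53, 0.15), (0.82, 52, 0.25),
         (0.02, 52, 0.04), (1.53, 52, 0.34)],
    )
    def test_f_to_d_reproduces_reported_values(self, f_stat, df_den, expected_d):
        assert round(cohens_d_from_f(f_stat, df_den), 2) == expected_d

    @pytest.mark.parametrize(
        "t_stat, df, expected_d",
        [(-2.44, 50, 0.69), (1.02, 50, 0.29), (-2.55, 50, 0.72), (0.72, 50, 0.20)],
    )
    def test_t_to_d_reproduces_reported_values(self, t_stat, df, expected_d):
        assert round(cohens_d_from_t(t_stat, df), 2) == expected_d

    def test_zero_statistics_give_zero_d(self):
        assert cohens_d_from_f(0.0, 53) == 0.0
        assert cohens_d_from_t(0.0, 50) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cohens_d_from_f(-1.0, 53)
        with pytest.raises(InvalidArgumentError):
            cohens_d_from_t(1.0, 0)


class TestSummaryTTests:
    @pytest.mark.parametrize(
        "m1, s1, n1, m2, s2, n2, expected_t",
        [
            (24.54, 5.44, 26, 24.64, 7.32, 28, -0.06),  # age row
            (16.31, 9.78, 26, 15.43, 7.37, 28, 0.37),   # social-anxiety row
            (4.88, 2.47, 26, 4.89, 2.60, 28, -0.01),    # urge baseline row
        ],
    )
    def test_pooled_t_reproduces_baseline_table(self, m1, s1, n1, m2, s2, n2, expected_t):
        # printed summary inputs are rounded, so allow the last digit to move
        res = two_sample_t(m1, s1, n1, m2, s2, n2, method="pooled")
        assert res.t == pytest.approx(expected_t, abs=0.01)
        assert res.df == n1 + n2 - 2

    def test_identical_groups_t_zero(self):
        res = two_sample_t(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.t == 0.0

    def test_welch_df_smaller_with_unequal_variances(self):
        pooled = two_sample_t(82.26, 18.10, 26, 78.68, 10.52, 28, method="pooled")
        welch = two_sample_t(82.26, 18.10, 26, 78.68, 10.52, 28, method="welch")
        assert welch.df < pooled.df

    def test_matches_scipy_on_raw_data(self, rng):
        from scipy import stats

        a, b = rng.normal(0, 1, 15), rng.normal(0.4, 1.3, 20)
        res = two_sample_t(a.mean(), a.std(ddof=1), 15, b.mean(), b.std(ddof=1), 20,
                           method="welch")
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_variances_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            two_sample_t(1.0, 0.0, 5, 1.0, 0.0, 5)

    def test_one_sample_reproduces_peak_bac(self):
        res = one_sample_t(0.25, 0.06, 28, 0.0)
        assert round(abs(res.t)) == 22
        assert res.df == 27
        assert res.p < 0.0001

    def test_one_sample_at_null_mean_is_zero(self):
        assert one_sample_t(3.0, 1.5, 10, 3.0).t == 0.0

    def test_one_sample_hand_computation(self):
        res = one_sample_t(1.0, 1.0, 4, 0.0)
        assert res.t == pytest.approx(2.0)
        assert res.df == 3


class TestCronbachAlpha:
    def test_parallel_items_alpha_one(self, rng):
        col = rng.integers(0, 5, 100).astype(float)
        assert cronbach_alpha(np.column_stack([col] * 4)) == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self, rng):
        X = rng.normal(size=(10_000, 8))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_two_items_spearman_brown_identity(self, rng):
        # correlation 0.6, equal variance -> alpha = 2*rho/(1+rho) = 0.75
        rho = 0.6
        n = 200_000
        f = rng.normal(size=n)
        x1 = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(size=n)
        x2 = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(size=n)
        assert cronbach_alpha(np.column_stack([x1, x2])) == pytest.approx(0.75, abs=0.01)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        X = pd.DataFrame(rng.normal(size=(60, 8)) + rng.normal(size=(60, 1)))
        ref = pg.cronbach_alpha(data=X)[0]
        assert cronbach_alpha(X) == pytest.approx(ref, abs=1e-10)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cronbach_alpha(np.tile([1.0, -1.0], (10, 1)))


class TestAuditScoring:
    def test_all_zero(self):
        assert score_audit([0] * 10) == (0, False)

    def test_maximum_revised(self):
        assert score_audit([4] * 8 + [0, 0]) == (32, True)

    def test_items_9_10_excluded_from_revised_total(self):
        assert score_audit([1, 1, 1, 1, 1, 1, 1, 1, 4, 4], revised=True) == (8, True)
        assert score_audit([1, 1, 1, 1, 1, 1, 1, 1, 4, 4], revised=False) == (16, True)

    def test_out_of_range_item_rejected(self):
        with pytest.raises(InvalidArgumentError):
            score_audit([5] + [0] * 9)


def z_table(seed=0, **kwargs):
    return generate_ea_z_table(seed=seed, **kwargs)


class TestMixedModelDF:
    """Containment-df reproduction for the three model shapes at n = 54."""

    def test_between_subject_condition_df(self):
        m = MixedEAModel(fixed=("condition",)).fit(z_table())
        assert m._f_tests["condition"]["df_den"] == 52.0

    def test_within_subject_valence_df(self):
        m = MixedEAModel(fixed=("valence",)).fit(z_table())
        assert m._f_tests["valence"]["df_den"] == 53.0

    def test_moderated_contrast_df(self):
        m = MixedEAModel(fixed=("condition",), moderator="r_audit").fit(z_table())
        slopes = m.simple_slopes()
        assert slopes["low"]["df"] == 50.0
        assert slopes["high"]["df"] == 50.0

    def test_target_sex_within_df(self):
        m = MixedEAModel(fixed=("target_sex",)).fit(z_table())
        assert m._f_tests["target_sex"]["df_den"] == 53.0


class TestMixedModelEstimates:
    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        ea = z_table(seed=7)
        m = MixedEAModel(fixed=("condition",), moderator="r_audit").fit(ea)
        df = ea.copy()
        df["alc"] = (df.condition == "alcohol").astype(float)
        df["mc"] = df.r_audit - df.groupby("perceiver_id").r_audit.first().mean()
        ref = smf.mixedlm("z ~ alc + mc + alc:mc", df, groups=df["perceiver_id"]).fit(
            reml=True
        )
        np.testing.assert_allclose(
            m.params_.to_numpy(),
            ref.params[["Intercept", "alc", "mc", "alc:mc"]].to_numpy(),
            atol=1e-5,
        )
        np.testing.assert_allclose(
            m.bse_.to_numpy(),
            ref.bse[["Intercept", "alc", "mc", "alc:mc"]].to_numpy(),
            atol=1e-4,
        )
        assert m.sigma_residual_ == pytest.approx(np.sqrt(ref.scale), abs=1e-4)

    def test_ols_equivalence_when_no_subject_variance(self):
        # with zero random-intercept variance truth on balanced data, the
        # mixed fit coincides with OLS
        spec = EffectSpec(sd_perceiver=0.0, sd_residual=0.3)
        ea = z_table(seed=3, effects=spec)
        m = MixedEAModel(fixed=("condition",), moderator="r_audit").fit(ea)
        X = np.column_stack(
            [
                np.ones(len(ea)),
                (ea.condition == "alcohol").astype(float),
                ea.r_audit - ea.groupby("perceiver_id").r_audit.first().mean(),
            ]
        )
        X = np.column_stack([X, X[:, 1] * X[:, 2]])
        beta_ols, *_ = np.linalg.lstsq(X, ea["z"].to_numpy(), rcond=None)
        np.testing.assert_allclose(m.params_.to_numpy(), beta_ols, atol=1e-5)

    def test_recovers_generating_betas(self):
        # moderate-size parameter recovery at the z level
        truth = EffectSpec(beta_condition=-0.2, beta_interaction=0.15)
        biases = {"condition": [], "interaction": []}
        for seed in range(60):
            ea = z_table(seed=seed, n_perceivers=200, effects=truth)
            m = MixedEAModel(fixed=("condition",), moderator="r_audit").fit(ea)
            biases["condition"].append(m.params_["condition"] - truth.beta_condition)
            # generator scales the interaction per moderator SD; the model
            # fits per raw moderator unit
            biases["interaction"].append(
                m.params_["condition:r_audit_c"] * 3.90 - truth.beta_interaction
            )
        assert abs(np.mean(biases["condition"])) < 0.05
        assert abs(np.mean(biases["interaction"])) < 0.05

    def test_variance_components_recovered(self):
        truth = EffectSpec(sd_perceiver=0.2, sd_residual=0.4)
        ea = z_table(seed=5, n_perceivers=400, effects=truth)
        m = MixedEAModel(fixed=("condition",)).fit(ea)
        assert m.sigma_perceiver_ == pytest.approx(0.2, abs=0.05)
        assert m.sigma_residual_ == pytest.approx(0.4, abs=0.03)

    def test_excluded_rows_dropped(self):
        ea = z_table(seed=9)
        ea.loc[ea.index[:20], "excluded"] = True
        m = MixedEAModel(fixed=("condition",)).fit(ea)
        assert m.n_obs_ == len(ea) - 20


class TestSimpleSlopes:
    def test_requires_interaction(self):
        m = MixedEAModel(fixed=("condition",)).fit(z_table())
        with pytest.raises(InvalidArgumentError):
            m.simple_slopes()

    def test_zero_moderator_sd_rejected(self):
        ea = z_table(seed=1)
        ea["r_audit"] = 10.0
        with pytest.raises(InvalidArgumentError):
            MixedEAModel(fixed=("condition",), moderator="r_audit").fit(ea)

    def test_sign_recovery_under_interaction_truth(self):
        # alcohol deficit at low moderator, none at high: low contrast
        # negative and significant, high contrast near zero, in >= 80% of
        # replicates
        truth = EffectSpec(beta_condition=-0.3, beta_interaction=0.3)
        low_hits = high_null = 0
        n_rep = 50
        for seed in range(n_rep):
            ea = z_table(seed=300 + seed, effects=truth)
            m = MixedEAModel(fixed=("condition",), moderator="r_audit").fit(ea)
            s = m.simple_slopes()
            if s["low"]["t"] < 0 and s["low"]["p"] < 0.05:
                low_hits += 1
            if s["high"]["p"] > 0.05:
                high_null += 1
        assert low_hits / n_rep >= 0.8
        assert high_null / n_rep >= 0.8

    def test_type_one_error_of_contrasts_under_null(self):
        null = EffectSpec(beta_valence=0, beta_condition=0, beta_moderator=0,
                          beta_interaction=0)
        rej = {"low": 0, "high": 0}
        n_rep = 400
        for seed in range(n_rep):
            ea = z_table(seed=700 + seed, effects=null)
            m = MixedEAModel(fixed=("condition",), moderator="r_audit").fit(ea)
            s = m.simple_slopes()
            for k in rej:
                rej[k] += s[k]["p"] < 0.05
        for k in rej:
            assert 0.02 <= rej[k] / n_rep <= 0.09

    def test_d_attached_via_t_conversion(self):
        m = MixedEAModel(fixed=("condition",), moderator="r_audit").fit(z_table())
        s = m.simple_slopes()
        for k in ("low", "high"):
            assert s[k]["d"] == pytest.approx(cohens_d_from_t(s[k]["t"], s[k]["df"]))


class TestFitMixedModelWrapper:
    def test_returns_model_result_with_contrasts(self):
        res = fit_mixed_model(z_table(), fixed=("condition",), moderator="r_audit")
        assert res.n_subjects == 54
        assert set(res.contrasts) == {"low", "high"}
        assert res.converged

    def test_valence_stratified_refits(self):
        ea = z_table(seed=2)
        pos = fit_mixed_model(ea[ea.valence == "positive"], fixed=("condition",))
        neg = fit_mixed_model(ea[ea.valence == "negative"], fixed=("condition",))
        assert pos.f_tests["condition"]["df_den"] == 52.0
        assert neg.f_tests["condition"]["df_den"] == 52.0


class TestDrinkingSummaries:
    def test_proportional_drinks_give_r_one(self):
        p = generate_questionnaires(30, seed=0)
        p["condition"] = ["placebo", "alcohol"] * 15
        p["avg_daily_drinks"] = p["r_audit"] * 0.4
        p["peak_daily_drinks"] = p["r_audit"] * 0.9
        out = drinking_summaries(p)
        assert out["correlations"]["avg_daily_drinks"]["r"] == pytest.approx(1.0)

    def test_generator_coupling_positive(self):
        p = generate_questionnaires(54, seed=4)
        p["condition"] = ["placebo", "alcohol"] * 27
        out = drinking_summaries(p)
        assert out["correlations"]["avg_daily_drinks"]["r"] > 0
        assert out["correlations"]["peak_daily_drinks"]["r"] > 0

    def test_urge_tests_present_for_all_time_points(self):
        p = generate_questionnaires(40, seed=5)
        p["condition"] = ["placebo", "alcohol"] * 20
        out = drinking_summaries(p)
        assert set(out["urge_tests"]) == {
            "urge_baseline", "urge_pre_drink", "urge_post_drink", "urge_post_task"
        }

    def test_too_few_participants_rejected(self):
        p = generate_questionnaires(2, seed=0)
        p["condition"] = ["placebo", "alcohol"]
        with pytest.raises(InvalidArgumentError):
            drinking_summaries(p)


class TestAnalysisTable:
    def test_join_attaches_condition_and_moderator(self, small_cohort, small_binned):
        from eapipe import score_dataset

        ea = score_dataset(small_binned, small_cohort.clips, small_cohort.assignments)
        table = build_analysis_table(ea, small_cohort.participants)
        assert {"condition", "r_audit"} <= set(table.columns)
        assert len(table) == len(ea)

    def test_missing_participant_rejected(self, small_cohort, small_binned):
        from eapipe import score_dataset

        ea = score_dataset(small_binned, small_cohort.clips, small_cohort.assignments)
        participants = small_cohort.participants.iloc[:-1]
        with pytest.raises(InvalidArgumentError):
            build_analysis_table(ea, participants)
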