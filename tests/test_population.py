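"""Age-trend regression layer: identities, recovery, summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from eeglifespan import population, synth


def users_on_exact_surface(coeffs, ages=range(20, 70, 5), center=42.0):
    """User rows whose response is an exact function of (age, sex)."""
    b0, b1, b2, b3, b4, b5 = coeffs
    rows = []
    for age in ages:
        a = age - center
        for sex in (0, 1):
            y = b0 + b1 * a + b2 * a * a + sex * (b3 + b4 * a + b5 * a * a)
            for k in range(2):  # two users per cell; weights > 1
                rows.append(
                    {"user_id": f"u{age}{sex}{k}", "age": age, "sex": sex, "y": y}
                )
    return pd.DataFrame(rows)


class TestFitWls:
    def test_noiseless_exact_recovery(self):
        coeffs = (0.47, 0.0012, -2e-5, 0.08, 6e-4, 1e-5)
        res = population.fit_age_trend(users_on_exact_surface(coeffs), "y")
        np.testing.assert_allclose(np.asarray(res.params), coeffs, atol=1e-10)
        assert res.rsquared == pytest.approx(1.0)

    def test_linear_ramp_recovers_closed_form_slope(self):
        # responses 1,2,3 at ages 20,42,64: slope (3-1)/(64-20) = 1/22
        coeffs = (2.0, 1 / 22, 0.0, 0.0, 0.0, 0.0)
        df = users_on_exact_surface(coeffs, ages=(20, 31, 42, 53, 64))
        res = population.fit_age_trend(df, "y")
        assert res.params["age"] == pytest.approx(1 / 22, abs=1e-12)
        assert res.params["intercept"] == pytest.approx(2.0, abs=1e-12)

    def test_wls_on_cells_equals_ols_on_users(self, trend):
        profs = synth.sample_cohort(synth.CohortConfig(n_users=400, seed=9))
        feats = synth.simulate_user_features(profs, trend, seed=9)
        model = population.AgeTrendModel.from_users(feats, "log_alpha_TP10")
        wls = model.fit().params
        ols = model.fit_user_level().params
        np.testing.assert_allclose(np.asarray(wls), np.asarray(ols), atol=1e-8)

    def test_centering_identity(self, trend):
        profs = synth.sample_cohort(synth.CohortConfig(n_users=200, seed=10))
        feats = synth.simulate_user_features(profs, trend, seed=10)
        res = population.fit_age_trend(feats, "log_beta_TP9")
        pred = res.predict(np.array([42.0]), np.array([0.0]))[0]
        assert pred == pytest.approx(res.params["intercept"], abs=1e-12)

    def test_cell_r2_at_least_user_r2(self, trend):
        profs = synth.sample_cohort(synth.CohortConfig(n_users=500, seed=11))
        feats = synth.simulate_user_features(profs, trend, seed=11)
        model = population.AgeTrendModel.from_users(feats, "log_alpha_AF7")
        assert model.fit().rsquared >= model.fit_user_level().rsquared

    def test_rank_deficiency_names_collinear_terms(self):
        df = users_on_exact_surface((1.0, 0.0, 0.0, 0.0, 0.0, 0.0))
        df = df[df["sex"] == 0]  # sex column all zero -> collinear
        cells = population.aggregate_cells(df, "y")
        with pytest.raises(ValueError, match="sex"):
            population.AgeTrendModel(cells, "y").fit()

    def test_too_few_cells_is_an_error(self):
        df = users_on_exact_surface((1.0, 0, 0, 0, 0, 0), ages=(20, 42, 64))
        cells = population.aggregate_cells(df, "y")
        with pytest.raises(ValueError, match="cells"):
            population.AgeTrendModel(cells, "y").fit()


class TestAggregateCells:
    def test_single_user_cells(self):
        df = pd.DataFrame(
            {"user_id": ["a", "b"], "age": [30, 40], "sex": [0, 1], "y": [1.0, 2.0]}
        )
        cells = population.aggregate_cells(df, "y")
        assert (cells["n"] == 1).all()
        assert set(cells["y"]) == {1.0, 2.0}

    def test_cell_mean_and_weight(self):
        df = pd.DataFrame(
            {"user_id": list("ab"), "age": [30, 30], "sex": [0, 0], "y": [1.0, 3.0]}
        )
        cells = population.aggregate_cells(df, "y")
        assert len(cells) == 1
        assert cells.loc[0, "y"] == 2.0 and cells.loc[0, "n"] == 2

    def test_missing_peak_reduces_weight_for_peak_models_only(self):
        df = pd.DataFrame(
            {
                "user_id": list("ab"),
                "age": [30, 30],
                "sex": [0, 0],
                "alpha_peak_TP9": [9.0, np.nan],
                "log_alpha_TP9": [0.5, 0.7],
            }
        )
        peak_cells = population.aggregate_cells(df, "alpha_peak_TP9")
        power_cells = population.aggregate_cells(df, "log_alpha_TP9")
        assert peak_cells.loc[0, "n"] == 1
        assert power_cells.loc[0, "n"] == 2

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            population.aggregate_cells(pd.DataFrame(columns=["age", "sex", "y"]), "y")


class TestConditionalSexRefit:
    def test_no_refit_below_trigger(self):
        coeffs = (0.5, 0.002, 0.0, 0.05, 0.0, 0.0)
        rng = np.random.default_rng(0)
        df = users_on_exact_surface(coeffs, ages=range(20, 70, 2))
        df["y"] += rng.normal(0, 0.3, size=len(df))
        res = population.fit_age_trend(df, "y")
        if not res.interaction_significant:  # null interactions: usually not
            assert res.sex_refits() == {}

    def test_strong_interaction_triggers_refit_and_brackets_slopes(self, trend):
        strong = dataclasses.replace(
            trend,
            logpower_coeffs={
                **trend.logpower_coeffs,
                "alpha": (0.47, 0.001, 0.0, 0.0, 0.004, 0.0),
            },
            logpower_noise_sd=0.1,
        )
        profs = synth.sample_cohort(synth.CohortConfig(n_users=1500, seed=13))
        feats = synth.simulate_user_features(profs, strong, seed=13)
        res = population.fit_age_trend(feats, "log_alpha_TP10")
        assert res.interaction_significant
        refits = res.sex_refits()
        assert set(refits) == {0, 1}
        # male slope ~0.001, female slope ~0.005
        assert abs(refits[0].params["age"] - 0.001) < 3 * refits[0].bse["age"]
        assert abs(refits[1].params["age"] - 0.005) < 3 * refits[1].bse["age"]
        assert refits[1].params["age"] > refits[0].params["age"]

    def test_sparse_sex_skipped_with_warning(self):
        coeffs = (0.5, 0.002, 0.0, 0.05, 0.01, 0.0)
        df = users_on_exact_surface(coeffs, ages=range(20, 70, 2))
        df = df[(df["sex"] == 0) | (df["age"] < 26)]  # 3 female cells
        rng = np.random.default_rng(1)
        df = df.copy()
        df["y"] += rng.normal(0, 1e-6, size=len(df))
        res = population.fit_age_trend(df, "y")
        if res.interaction_significant:
            with pytest.warns(UserWarning, match="refit skipped"):
                refits = res.sex_refits()
            assert 1 not in refits


class TestSexTtest:
    def test_hand_example(self):
        df = pd.DataFrame({"sex": [1, 1, 0, 0], "y": [1.0, 2.0, 3.0, 4.0]})
        res = population.sex_ttest(df, "y")
        assert res.t == pytest.approx(-2.828, abs=1e-3)
        assert res.df == 2

    def test_identical_groups_give_zero(self):
        df = pd.DataFrame({"sex": [0, 0, 1, 1], "y": [1.0, 2.0, 1.0, 2.0]})
        assert population.sex_ttest(df, "y").t == pytest.approx(0.0)

    def test_df_is_n_minus_two(self, trend):
        profs = synth.sample_cohort(synth.CohortConfig(n_users=120, seed=14))
        feats = synth.simulate_user_features(profs, trend, seed=14)
        res = population.sex_ttest(feats, "log_total_TP9")
        assert res.df == len(feats) - 2

    def test_one_empty_sex_is_an_error(self):
        df = pd.DataFrame({"sex": [0, 0, 0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            population.sex_ttest(df, "y")

    def test_sex_difference_detected_on_synthetic_cohort(self, trend):
        profs = synth.sample_cohort(synth.CohortConfig(n_users=2000, seed=15))
        feats = synth.simulate_user_features(profs, trend, seed=15)
        for col in ("log_total_AF7", "log_total_TP9"):
            res = population.sex_ttest(feats, col)
            assert res.p < 0.01 and res.t > 0  # females higher by construction


class TestVarianceDecomposition:
    def test_identical_users_give_zero(self):
        df = pd.DataFrame({"age": [20, 20, 30, 30], "y": [1.0, 1.0, 1.0, 1.0]})
        vd = population.variance_decomposition(df, "y")
        assert vd.between_age_sd == 0.0 and vd.mean_within_age_sd == 0.0

    def test_pure_within_noise(self, rng):
        sigma = 0.5
        ages = np.repeat(np.arange(20, 60), 400)
        df = pd.DataFrame({"age": ages, "y": rng.normal(0, sigma, ages.size)})
        vd = population.variance_decomposition(df, "y")
        assert vd.mean_within_age_sd == pytest.approx(sigma, rel=0.05)
        assert vd.between_age_sd < 0.2 * sigma

    def test_old_ages_pooled_into_one_bin(self):
        df = pd.DataFrame({"age": [78, 81, 85, 40], "y": [1.0, 2.0, 3.0, 4.0]})
        vd = population.variance_decomposition(df, "y")
        assert vd.n_bins == 2  # {40} and {78+}

    def test_within_exceeds_between_on_default_cohort(self, trend):
        profs = synth.sample_cohort(synth.CohortConfig(n_users=2000, seed=16))
        feats = synth.simulate_user_features(profs, trend, seed=16)
        vd = population.variance_decomposition(feats, "log_alpha_TP10")
        assert vd.mean_within_age_sd > vd.between_age_sd


class TestFeatureCorrelation:
    def test_perfect_correlation(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = df["x"]
        assert population.feature_correlation(df, "x", "y").r == pytest.approx(1.0)

    def test_negative_linear_map(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 5.0]})
        df["y"] = -2.0 * df["x"]
        res = population.feature_correlation(df, "x", "y")
        assert res.r == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-2.0)

    def test_against_covariance_oracle(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([3.0, 1.0, 7.0, 2.0, 5.0])
        df = pd.DataFrame({"x": x, "y": y})
        res = population.feature_correlation(df, "x", "y")
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        assert res.r == pytest.approx(cov / (x.std() * y.std()), abs=1e-12)
        assert res.slope == pytest.approx(cov / x.var(), abs=1e-12)

    def test_zero_variance_is_an_error(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="variance"):
            population.feature_correlation(df, "x", "y")


class TestSummaries:
    def test_order_statistics_example(self):
        s = population.summarize_distribution(range(1, 8))
        assert (s.median, s.q1, s.q3) == (4.0, 2.0, 6.0)
        assert (s.lower_adjacent, s.upper_adjacent) == (1.0, 7.0)

    def test_single_value(self):
        s = population.summarize_distribution([3.5])
        assert {s.median, s.q1, s.q3, s.lower_adjacent, s.upper_adjacent} == {3.5}

    def test_outlier_excluded_from_adjacent_values(self):
        s = population.summarize_distribution([1, 2, 3, 4, 5, 6, 7, 100])
        assert s.upper_adjacent == 7.0

    @pytest.mark.parametrize(
        "p,star", [(0.2, ""), (0.04, "*"), (0.009, "**"), (0.0005, "***"), (5e-5, "†")]
    )
    def test_stars_are_a_pure_function_of_p(self, p, star):
        assert population.stars_for_p(p) == star


class TestOmnibusGate:
    def test_four_way_model_fits_and_gates(self, trend):
        profs = synth.sample_cohort(synth.CohortConfig(n_users=150, seed=17))
        feats = synth.simulate_user_features(profs, trend, seed=17, tasks=("CAL", "NFB"))
        long_df = population.long_format(feats, band="alpha")
        res = population.fit_omnibus(long_df)
        # channel main effects must be detected: gains differ by construction
        chan_params = [p for p in res.pvalues.index if "channel" in p and ":" not in p]
        assert any(res.pvalues[p] < 0.05 for p in chan_params)
        assert res.df_resid > 0
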