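import numpy as np
import pandas as pd
import pytest

from epifract.cohort import records_to_frame
from epifract.errors import ContractError, InsufficientDataError, UndefinedEstimateError
from epifract.survival import (
    _mann_whitney_auc,
    build_design,
    check_proportionality,
    cox_fit,
    impute_predicted_mean,
    km_estimate,
    logrank,
    roc_auc,
    split_sample_cv,
)
from epifract.synthetic import CohortSpec, simulate_cohort


def hand_logrank_2group(times, events, groups):
    """Textbook unweighted two-group logrank oracle: (O-E)^2 / V."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def simulated_frame(n=400, seed=0, **kwargs):
    spec = CohortSpec(n_patients=n, seed=seed, **kwargs)
    records, truth = simulate_cohort(spec)
    return records_to_frame(records), truth


class TestKaplanMeier:
    def test_hand_product_limit_toy(self):
        curve = km_estimate([1, 2, 3], [1, 1, 0], horizon=10)
        s = dict(zip(curve.times, curve.survival))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[2.0] == pytest.approx(1 / 3)
        assert curve.horizon_estimate == pytest.approx(1 / 3)

    def test_no_events_means_flat_survival(self):
        curve = km_estimate([2, 5, 7], [0, 0, 0], horizon=10)
        assert np.all(curve.survival == 1.0)
        assert curve.horizon_estimate == 1.0

    def test_simultaneous_failures_drop_to_zero(self):
        curve = km_estimate([5, 5], [1, 1], horizon=5)
        assert curve.horizon_estimate == 0.0

    def test_survival_non_increasing_and_starts_at_one(self):
        rng = np.random.default_rng(2)
        curve = km_estimate(rng.exponential(5, 50), rng.integers(0, 2, 50), 10)
        assert curve.survival[0] <= 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_horizon_equals_event_fraction_without_censoring(self):
        rng = np.random.default_rng(8)
        times = rng.uniform(0, 9, 80)
        curve = km_estimate(times, np.ones(80, int), horizon=10)
        assert curve.horizon_estimate == pytest.approx(0.0)
        early = times < 5
        curve2 = km_estimate(
            np.where(early, times, 20.0), np.ones(80, int), horizon=10
        )
        assert curve2.horizon_estimate == pytest.approx(1 - early.mean())

    def test_empty_input_rejected(self):
        with pytest.raises(ContractError):
            km_estimate([], [], 10)


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 0, 1, 1, 1, 0, 1, 1]
        groups = [0, 0, 0, 0, 1, 1, 1, 1]
        stat, p = logrank(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_two_group_oracle(self):
        times = [1, 3, 4, 6, 2, 5, 7, 8]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        groups = [0, 0, 0, 0, 1, 1, 1, 1]
        stat, _ = logrank(times, events, groups)
        assert stat == pytest.approx(hand_logrank_2group(times, events, groups))

    def test_single_group_rejected(self):
        with pytest.raises(ContractError):
            logrank([1, 2], [1, 1], [0, 0])

    def test_type_i_error_under_exponential_null(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            t = rng.exponential(5.0, 400)
            g = np.repeat([0, 1], 200)
            _, p = logrank(t, np.ones(400, int), g)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)


class TestCox:
    def test_matches_partial_likelihood_grid_search_oracle(self):
        # n=6 toy, single binary covariate, no ties
        df = pd.DataFrame(
            {
                "followup_years": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "dss_event": [1, 1, 0, 1, 1, 0],
                "os_event": [1, 1, 0, 1, 1, 0],
                "node_status": [1, 0, 1, 1, 0, 0],
            }
        )
        fit = cox_fit(df, "dss", ["node_status"])

        def neg_log_pl(beta):
            order = np.argsort(df["followup_years"].to_numpy())
            t = df["followup_years"].to_numpy()[order]
            e = df["dss_event"].to_numpy()[order]
            x = df["node_status"].to_numpy()[order]
            ll = 0.0
            for i in range(len(t)):
                if e[i]:
                    risk = x[i:]  # later times = still at risk
                    ll += beta * x[i] - np.log(np.exp(beta * risk).sum())
            return -ll

        grid = np.linspace(-3, 3, 60001)
        beta_star = grid[np.argmin([neg_log_pl(b) for b in grid])]
        assert fit.coefficients["node_status"] == pytest.approx(beta_star, abs=1e-4)

    def test_null_covariate_hr_near_one_with_nominal_coverage(self):
        rng = np.random.default_rng(5)
        covered, hrs = 0, []
        n_rep = 60
        for rep in range(n_rep):
            n = 300
            df = pd.DataFrame(
                {
                    "followup_years": rng.exponential(5.0, n),
                    "dss_event": 1,
                    "os_event": 1,
                    "er_status": rng.integers(0, 2, n),
                }
            )
            fit = cox_fit(df, "dss", ["er_status"])
            hrs.append(fit.hazard_ratios["er_status"])
            lo, hi = fit.ci95.loc["er_status"]
            covered += lo <= 1.0 <= hi
        assert np.mean(hrs) == pytest.approx(1.0, abs=0.05)
        assert covered / n_rep > 0.85

    def test_reference_level_is_implicit_unit_hazard(self):
        df, _ = simulated_frame(300, seed=3)
        fit = cox_fit(df, "dss", ["category"])
        assert set(fit.hazard_ratios.index) == {"category_intermediate", "category_high"}
        np.testing.assert_allclose(
            fit.hazard_ratios, np.exp(fit.coefficients), rtol=1e-12
        )

    def test_missing_covariates_rejected_before_fit(self):
        df, _ = simulated_frame(200, seed=4)
        assert df["grade"].isna().any()
        with pytest.raises(ContractError):
            cox_fit(df, "dss", ["category", "grade"])

    def test_breslow_ties_not_available(self):
        df, _ = simulated_frame(100, seed=6)
        with pytest.raises(NotImplementedError):
            cox_fit(df, "dss", ["category"], ties="breslow")


class TestProportionality:
    def test_exact_proportional_hazards_flagged_ok(self):
        df, _ = simulated_frame(400, seed=0)
        _, flag = check_proportionality(df, "category", "dss")
        assert flag == "ok"

    def test_crossing_weibull_hazards_flagged_suspect(self):
        rng = np.random.default_rng(1)
        n = 300
        df = pd.DataFrame(
            {
                "followup_years": np.concatenate(
                    [rng.weibull(0.5, n) * 5.0, rng.weibull(2.0, n) * 5.0]
                ),
                "dss_event": 1,
                "os_event": 1,
                "grp": np.repeat([0, 1], n),
            }
        )
        _, flag = check_proportionality(df, "grp", "dss")
        assert flag == "suspect"

    def test_single_stratum_rejected(self):
        df, _ = simulated_frame(100, seed=2)
        df["constant"] = 1
        with pytest.raises(ContractError):
            check_proportionality(df, "constant", "dss")


class TestAUC:
    def test_perfectly_ordered_scores(self):
        assert _mann_whitney_auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_two_subjects_ordered_and_reversed(self):
        assert _mann_whitney_auc(np.array([0, 1]), np.array([0.2, 0.9])) == 1.0
        assert _mann_whitney_auc(np.array([0, 1]), np.array([0.9, 0.2])) == 0.0

    def test_random_scores_near_chance(self):
        rng = np.random.default_rng(14)
        y = np.repeat([0, 1], 1000)
        score = rng.random(2000)
        assert _mann_whitney_auc(y, score) == pytest.approx(0.5, abs=0.03)

    def test_ties_contribute_one_half(self):
        y = np.array([0, 1, 0, 1])
        score = np.array([0.5, 0.5, 0.5, 0.5])
        assert _mann_whitney_auc(y, score) == 0.5

    def test_invariant_under_monotone_transform(self):
        df, _ = simulated_frame(300, seed=7)
        fit = cox_fit(df, "dss", ["category"])
        score = fit.predict_event_probability(df, 10.0)
        y = df["dss_event"].to_numpy()
        assert _mann_whitney_auc(y, score) == pytest.approx(
            _mann_whitney_auc(y, np.log(score / (1 - score))), abs=1e-12
        )

    def test_one_class_outcomes_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            _mann_whitney_auc(np.ones(5), np.random.default_rng(0).random(5))

    def test_roc_auc_from_cox_exceeds_chance_on_informative_category(self):
        df, _ = simulated_frame(
            500, seed=9, category_hrs=(1.0, 3.0, 8.0), covariate_effects={}
        )
        fit = cox_fit(df, "dss", ["category"])
        assert roc_auc(fit, df, "dss", 10.0) > 0.55


class TestImputation:
    def test_no_missing_values_pass_through_unchanged(self):
        df, _ = simulated_frame(150, seed=11, missingness={})
        out, log = impute_predicted_mean(df, ["grade", "node_status"])
        pd.testing.assert_frame_equal(out, df)
        assert log == {"grade": 0, "node_status": 0}

    def test_imputed_counts_match_constructed_missingness(self):
        df, _ = simulated_frame(
            379,
            seed=13,
            missingness={"node_status": 4 / 379, "her2_status": 12 / 379},
        )
        n_node = int(df["node_status"].isna().sum())
        n_her2 = int(df["her2_status"].isna().sum())
        assert n_node > 0 and n_her2 > 0
        out, log = impute_predicted_mean(df, ["node_status", "her2_status"])
        assert log == {"node_status": n_node, "her2_status": n_her2}
        assert not out[["node_status", "her2_status"]].isna().any().any()
        assert set(out["node_status"].unique()) <= {0.0, 1.0}

    def test_mcar_imputation_leaves_cox_hrs_nearly_unbiased(self):
        df, _ = simulated_frame(1000, seed=15, missingness={})
        complete_fit = cox_fit(df, "dss", ["category", "node_status"])
        df_miss = df.copy()
        rng = np.random.default_rng(16)
        mask = rng.random(len(df)) < 0.10
        df_miss.loc[mask, "node_status"] = np.nan
        imputed, _ = impute_predicted_mean(df_miss, ["node_status"])
        imputed_fit = cox_fit(imputed, "dss", ["category", "node_status"])
        delta = (complete_fit.coefficients - imputed_fit.coefficients).abs()
        assert (delta < 0.1).all()

    def test_fully_missing_variable_is_an_error(self):
        df, _ = simulated_frame(100, seed=17, missingness={})
        df["grade"] = np.nan
        with pytest.raises(InsufficientDataError):
            impute_predicted_mean(df, ["grade"])


class TestSplitSampleCV:
    def test_validation_copy_of_training_gives_zero_shrinkage(self):
        df, _ = simulated_frame(200, seed=19)
        report, _, final = split_sample_cv(
            df, "dss", ["category"], validation=df.copy()
        )
        assert report.shrinkage == 0.0
        assert report.auc_training == report.auc_validation
        assert report.generalizable and final is not None

    def test_shrinkage_is_exact_bookkeeping(self):
        df, _ = simulated_frame(300, seed=23)
        report, _, _ = split_sample_cv(df, "dss", ["category"], 0.5, seed=1)
        assert report.shrinkage == report.auc_training - report.auc_validation
        assert report.n_training + report.n_validation == 300
        assert report.n_training == 150

    def test_correctly_specified_model_has_small_shrinkage(self):
        df, _ = simulated_frame(2000, seed=29, covariate_effects={})
        report, _, _ = split_sample_cv(df, "dss", ["category"], 0.5, seed=2)
        assert abs(report.shrinkage) < 0.05

    def test_overfitted_noise_model_shrinks_positively(self):
        rng = np.random.default_rng(31)
        positive = 0
        n_rep = 30
        for rep in range(n_rep):
            n = 100
            t = rng.exponential(5.0, n)
            cut = np.median(t)  # administrative censoring: ~half the cohort events
            df = pd.DataFrame(
                {
                    "followup_years": np.minimum(t, cut),
                    "dss_event": (t <= cut).astype(int),
                    "os_event": (t <= cut).astype(int),
                }
            )
            noise_cols = []
            for j in range(20):
                df[f"noise{j}"] = rng.normal(size=n)
                noise_cols.append(f"noise{j}")
            try:
                report, _, _ = split_sample_cv(df, "dss", noise_cols, 0.5, seed=rep)
            except UndefinedEstimateError:
                continue
            positive += report.shrinkage > 0
        assert positive > n_rep / 2

    def test_too_small_sample_rejected(self):
        df, _ = simulated_frame(30, seed=37)
        with pytest.raises(InsufficientDataError):
            split_sample_cv(df.head(10), "dss", ["category"], 0.5, seed=0)


def test_design_matrix_expands_category_against_low_reference():
    df = pd.DataFrame({"category": ["low", "intermediate", "high"], "grade": [0, 1, 0]})
    design = build_design(df, ["category", "grade"])
    assert list(design.columns) == ["category_intermediate", "category_high", "grade"]
    np.testing.assert_array_equal(design["category_intermediate"], [0.0, 1.0, 0.0])
    np.testing.assert_array_equal(design["category_high"], [0.0, 0.0, 1.0])
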