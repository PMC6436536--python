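"""OLS, the random-intercept mixed model, sum-coding identities, difference scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ansacuity import (
    GenerativeParams,
    crossover_education,
    difference_scores,
    fit_difference_model,
    fit_education_model,
    fit_lmm_random_intercept,
    fit_ols,
    generate_cohort,
    reproduce_tables,
    standardize,
    sum_code,
    sum_coding_combine,
)
from ansacuity.analysis import (
    DegenerateInputError,
    SingularDesignError,
    UndefinedCrossoverError,
    cohort_to_long,
    stars,
)


def parametric_cohort(seed, **overrides):
    return generate_cohort(
        GenerativeParams(seed=seed, **overrides), mode="parametric"
    ).cohort


class TestTransforms:
    def test_standardize_basic(self):
        assert standardize([1, 2, 3]) == pytest.approx([-1, 0, 1])

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40, unique=True))
    def test_standardize_moments_and_idempotence(self, xs):
        z = standardize(xs)
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=1) == pytest.approx(1.0)
        assert standardize(z) == pytest.approx(z)

    def test_standardize_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            standardize([2.0, 2.0, 2.0])

    def test_sum_code_orientation_and_balance(self):
        codes = sum_code(["cards", "computer", "cards", "computer"], "cards")
        assert list(codes) == [1, -1, 1, -1]
        assert codes.sum() == 0

    def test_sum_code_needs_two_levels(self):
        with pytest.raises(ValueError):
            sum_code(["a", "b", "c"], "a")
        with pytest.raises(ValueError):
            sum_code(["a", "a"], "a")

    def test_swapping_positive_level_flips_factor_coefficients(self):
        cohort = parametric_cohort(21)
        long = cohort_to_long(cohort)
        for positive in ("cards", "computer"):
            s = sum_code(long["task"], positive)
            X = pd.DataFrame(
                {"(Intercept)": 1.0, "Education": long["education_years"].astype(float),
                 "task1": s}, index=long.index)
            X["Education:task1"] = X["Education"] * X["task1"]
            res = fit_ols(long["logw"], X)
            if positive == "cards":
                base = res
        flipped = res
        assert flipped["task1"] == pytest.approx(-base["task1"])
        assert flipped["Education:task1"] == pytest.approx(-base["Education:task1"])
        assert flipped["(Intercept)"] == pytest.approx(base["(Intercept)"])
        assert flipped["Education"] == pytest.approx(base["Education"])

    def test_stars_thresholds(self):
        assert [stars(p) for p in (0.0005, 0.005, 0.03, 0.07, 0.5)] == [
            "***", "**", "*", ".", ""]


class TestOLS:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        X = pd.DataFrame({"(Intercept)": 1.0, "x": x})
        res = fit_ols(2 * x, X)
        assert res["x"] == pytest.approx(2.0, abs=1e-12)
        assert res["(Intercept)"] == pytest.approx(0.0, abs=1e-12)
        assert res.residual_summary["max"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        from scipy import stats

        for _ in range(20):
            n, k = int(rng.integers(10, 40)), int(rng.integers(2, 5))
            X = pd.DataFrame(rng.normal(size=(n, k)),
                             columns=[f"b{j}" for j in range(k)])
            y = rng.normal(size=n)
            res = fit_ols(y, X)
            A = X.to_numpy()
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            assert np.allclose(res.coef, beta, atol=1e-8)
            resid = y - A @ beta
            s2 = resid @ resid / (n - k)
            se = np.sqrt(np.diag(s2 * np.linalg.inv(A.T @ A)))
            assert np.allclose(res.se, se, atol=1e-8)
            t = beta / se
            p = 2 * stats.t.sf(np.abs(t), n - k)
            assert np.allclose(res.p_values, p, atol=1e-10)

    def test_rank_deficiency_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(SingularDesignError):
            fit_ols([1.0, 2.0, 3.0, 4.0], X)


class TestMixedModel:
    def test_zero_subject_variance_collapses_to_ols(self):
        cohort = parametric_cohort(31, sigma2_subject=0.0, delta_order=0.0)
        long = cohort_to_long(cohort)
        X = pd.DataFrame(
            {"(Intercept)": 1.0, "Education": long["education_years"].astype(float),
             "task1": long["task_sum"]}, index=long.index)
        X["Education:task1"] = X["Education"] * X["task1"]
        lmm = fit_lmm_random_intercept(long["logw"], X, long["participant_id"])
        ols = fit_ols(long["logw"], X)
        assert np.allclose(lmm.fixed.coef, ols.coef, atol=1e-6)
        # the ML variance estimate is a small sampling quantity, near zero
        # relative to the residual variance
        assert lmm.var_subject <= 0.1 * lmm.var_residual

    def test_balanced_sum_coding_identity(self):
        """Mixed fixed effects == (mean, half-difference) recombination of the
        per-task OLS fits, on complete balanced pairs."""
        for seed in (41, 42):
            cohort = parametric_cohort(seed)
            tabs = reproduce_tables(cohort)
            m = tabs["mixed_logw"]
            comb = sum_coding_combine(
                (tabs["ols_cards"]["(Intercept)"], tabs["ols_cards"]["Education"]),
                (tabs["ols_computer"]["(Intercept)"], tabs["ols_computer"]["Education"]),
            )
            assert m["(Intercept)"] == pytest.approx(comb["intercept"], abs=1e-8)
            assert m["task1"] == pytest.approx(comb["task"], abs=1e-8)
            assert m["Education"] == pytest.approx(comb["education"], abs=1e-8)
            assert m["Education:task1"] == pytest.approx(comb["education_task"], abs=1e-8)

    def test_interaction_recovered_across_cohorts(self):
        """The education-by-task interaction is recovered without bias: the
        mean estimate over independent cohorts sits within 3 SEs of the
        generating coefficient, and a typical single cohort lands within a
        couple of per-fit standard errors."""
        ests, ses = [], []
        for seed in range(20):
            res = reproduce_tables(parametric_cohort(seed, delta_order=0.0))["mixed_logw"]
            ests.append(res["Education:task1"])
            ses.append(res.fixed.se_of("Education:task1"))
        ests = np.asarray(ests)
        se_mean = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.031667) <= 3 * se_mean
        # most single cohorts land within 2 per-fit SEs of the truth
        within = np.abs(ests - 0.031667) <= 2 * np.asarray(ses)
        assert within.mean() >= 0.8

    def test_information_criteria_consistent(self):
        cohort = parametric_cohort(11)
        m = reproduce_tables(cohort)["mixed_logw"]
        assert m.deviance == pytest.approx(-2 * m.loglik)
        assert m.aic == pytest.approx(m.deviance + 2 * 6)
        assert m.n_obs == 282 and m.n_groups == 141


class TestDifferenceScores:
    def test_zero_when_tasks_identical(self):
        cohort = parametric_cohort(3)
        cohort["logw_computer"] = cohort["logw_cards"]
        d, n_excl = difference_scores(cohort)
        assert n_excl == 0
        assert np.allclose(d["diff_logw"], 0.0)

    def test_sign_convention_cards_better_is_negative(self):
        cohort = parametric_cohort(3).head(5).copy()
        cohort["logw_cards"] = cohort["logw_computer"] - 0.5
        d, _ = difference_scores(cohort)
        assert (d["diff_logw"] < 0).all()

    def test_missing_task_subjects_excluded_and_counted(self):
        cohort = parametric_cohort(3)
        cohort.loc[cohort.index[:4], "logw_computer"] = np.nan
        d, n_excl = difference_scores(cohort)
        assert n_excl == 4 and len(d) == len(cohort) - 4

    def test_difference_model_terms(self):
        cohort = parametric_cohort(13)
        res = fit_difference_model(cohort)
        assert res.terms == ("(Intercept)", "Education", "Comp.First.sum",
                             "scale(Age)", "Gender1")
        with_int = fit_difference_model(cohort, include_edu_order_interaction=True)
        assert "Education:Comp.First.sum" in with_int.terms

    def test_order_coefficient_recovered(self):
        cohort = parametric_cohort(17, n_participants=2000)
        res = fit_difference_model(cohort)
        target = GenerativeParams().delta_order
        assert abs(res["Comp.First.sum"] - target) <= 2 * res.se_of("Comp.First.sum")


class TestCrossover:
    def test_published_scale_arithmetic(self):
        assert crossover_education(-0.287, 0.051) == pytest.approx(5.627, abs=0.01)

    def test_zero_intercept(self):
        assert crossover_education(0.0, 0.05) == 0.0

    def test_simple_ratio(self):
        assert crossover_education(-0.1, 0.05) == pytest.approx(2.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(UndefinedCrossoverError):
            crossover_education(-0.3, 0.0)


class TestReproduceTables:
    def test_noise_free_cohort_returns_generating_betas(self):
        p = GenerativeParams(sigma2_subject=0.0, sigma2_resid=0.0, delta_order=0.0,
                             seed=19)
        cohort = generate_cohort(p, mode="parametric").cohort
        m = reproduce_tables(cohort)["mixed_logw"]
        assert m["(Intercept)"] == pytest.approx(p.beta0, abs=1e-5)
        assert m["Education"] == pytest.approx(p.beta_edu, abs=1e-5)
        assert m["task1"] == pytest.approx(p.beta_task, abs=1e-5)
        assert m["Education:task1"] == pytest.approx(p.beta_edu_task, abs=1e-5)

    def test_education_main_effect_is_mean_of_per_task_slopes(self):
        cohort = parametric_cohort(23)
        tabs = reproduce_tables(cohort)
        mean_slope = (tabs["ols_cards"]["Education"]
                      + tabs["ols_computer"]["Education"]) / 2
        assert tabs["mixed_logw"]["Education"] == pytest.approx(mean_slope, abs=1e-8)

    def test_w_scale_variants_present(self):
        tabs = reproduce_tables(parametric_cohort(29))
        for key in ("ols_cards_w", "ols_computer_w"):
            assert tabs[key].terms == ("(Intercept)", "Education")

    def test_education_model_layout(self):
        res = fit_education_model(parametric_cohort(29))
        assert res.terms == ("(Intercept)", "scale(Age)", "Gender1",
                             "scale(Age):Gender1")
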