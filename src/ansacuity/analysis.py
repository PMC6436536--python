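"""Regression stage: the education-by-task analysis of Log W.

Four models, mirroring the analysis conventions of the study design this
package simulates:

1. a linear mixed model ``Log W ~ education * task + (1 | subject)`` fit by
   maximum likelihood (not REML), with the two-level task factor sum-coded
   (cards = +1, computer = -1) so the intercept is the grand mean and the
   task coefficient is half the cards-computer difference;
2. per-task ordinary least squares ``Log W ~ education`` (and the variant
   predicting W rather than Log W);
3. a per-subject difference-score model
   ``(Log W cards - Log W computer) ~ education + order + scale(age) + gender``
   with order and gender sum-coded (computer-first = +1, female = +1);
4. the demographics model ``education ~ scale(age) * gender``.

With balanced complete pairs the mixed model's fixed effects are an exact
recombination of the two per-task OLS fits: intercept = mean of intercepts,
task = half-difference of intercepts, and likewise for the education slopes.
``sum_coding_combine`` implements that identity; ``crossover_education``
turns the difference-score intercept and education slope into the education
level at which the two presentation modes are expected to agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionResult",
    "MixedModelResult",
    "DegenerateInputError",
    "SingularDesignError",
    "UndefinedCrossoverError",
    "standardize",
    "sum_code",
    "stars",
    "fit_ols",
    "fit_lmm_random_intercept",
    "difference_scores",
    "crossover_education",
    "sum_coding_combine",
    "fit_difference_model",
    "fit_education_model",
    "cohort_to_long",
    "reproduce_tables",
    "export_difference_scatter",
]


class DegenerateInputError(ValueError):
    """Constant or otherwise information-free input to a transform."""


class SingularDesignError(ValueError):
    """Rank-deficient design matrix."""


class UndefinedCrossoverError(ZeroDivisionError):
    """Crossover education is undefined when the education slope is zero."""


@dataclass(frozen=True)
class RegressionResult:
    """A fitted linear model in the familiar coefficient-table layout."""

    terms: tuple[str, ...]
    coef: tuple[float, ...]
    se: tuple[float, ...]
    t_values: tuple[float, ...]
    p_values: tuple[float, ...]
    residual_summary: Mapping[str, float]
    n: int
    df_resid: int

    def __getitem__(self, term: str) -> float:
        return self.coef[self.terms.index(term)]

    def se_of(self, term: str) -> float:
        return self.se[self.terms.index(term)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Estimate": self.coef,
                "SE": self.se,
                "t value": self.t_values,
                "Pr(>|t|)": self.p_values,
            },
            index=list(self.terms),
        )


@dataclass(frozen=True)
class MixedModelResult:
    """Random-intercept mixed model: fixed-effect table plus variance parts."""

    fixed: RegressionResult
    var_subject: float
    var_residual: float
    loglik: float
    aic: float
    bic: float
    deviance: float
    n_obs: int
    n_groups: int
    converged: bool

    def __getitem__(self, term: str) -> float:
        return self.fixed[term]


def standardize(values: Sequence[float]) -> np.ndarray:
    """Z-score with the sample (n-1) standard deviation, like R's ``scale()``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateInputError("standardize needs >= 2 distinct values")
    return (x - x.mean()) / x.std(ddof=1)


def sum_code(values: Sequence, positive_level) -> np.ndarray:
    """Code a two-level factor as +/-1, with ``positive_level`` mapped to +1."""
    arr = np.asarray(values)
    levels = set(arr.tolist())
    if len(levels) != 2:
        raise ValueError(f"sum_code needs exactly 2 levels present, got {sorted(map(str, levels))}")
    if positive_level not in levels:
        raise ValueError(f"positive level {positive_level!r} absent from data")
    return np.where(arr == positive_level, 1.0, -1.0)


def stars(p: float) -> str:
    """Significance marks at the conventional .1/.05/.01/.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def _resid_summary(resid: np.ndarray) -> dict[str, float]:
    q = np.quantile(resid, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def fit_ols(response: Sequence[float], design: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares on a named design matrix (pass the intercept
    column explicitly).

    Standard errors use the unbiased residual variance; p-values are
    two-sided from the t distribution on ``n - n_terms`` degrees of freedom.
    """
    y = np.asarray(response, dtype=float)
    X = design.astype(float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    if len(y) <= X.shape[1]:
        raise SingularDesignError("need more observations than terms")
    res = sm.OLS(y, X).fit()
    return RegressionResult(
        terms=tuple(X.columns),
        coef=tuple(res.params),
        se=tuple(res.bse),
        t_values=tuple(res.tvalues),
        p_values=tuple(res.pvalues),
        residual_summary=_resid_summary(np.asarray(res.resid)),
        n=len(y),
        df_resid=int(res.df_resid),
    )


def fit_lmm_random_intercept(
    response: Sequence[float], design: pd.DataFrame, groups: Sequence
) -> MixedModelResult:
    """Random-intercept linear mixed model, fit by maximum likelihood.

    Reports the fixed-effect table (Wald z p-values alongside the t values),
    the subject-intercept and residual variances, and the ML information
    criteria.  Non-convergence is flagged on the result rather than raised.
    """
    y = np.asarray(response, dtype=float)
    X = design.astype(float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError("fixed-effect design is rank deficient")
    model = sm.MixedLM(y, X, groups=np.asarray(groups))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance warnings are expected
        try:
            res = model.fit(reml=False)
        except np.linalg.LinAlgError:
            # singular Hessian when the subject variance hits the boundary
            res = model.fit(reml=False, method="cg")
    k_fe = X.shape[1]
    fe = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    t = fe / se
    p = 2.0 * stats.norm.sf(np.abs(t))
    llf = float(res.llf)
    k = k_fe + 2  # fixed effects + subject variance + residual variance
    n_obs = len(y)
    fitted = np.asarray(res.fittedvalues, dtype=float)
    fixed = RegressionResult(
        terms=tuple(X.columns),
        coef=tuple(fe),
        se=tuple(se),
        t_values=tuple(t),
        p_values=tuple(p),
        residual_summary=_resid_summary(y - fitted),
        n=n_obs,
        df_resid=n_obs - k,
    )
    return MixedModelResult(
        fixed=fixed,
        var_subject=float(np.asarray(res.cov_re)[0, 0]),
        var_residual=float(res.scale),
        loglik=llf,
        aic=-2.0 * llf + 2.0 * k,
        bic=-2.0 * llf + k * np.log(n_obs),
        deviance=-2.0 * llf,
        n_obs=n_obs,
        n_groups=int(pd.Series(groups).nunique()),
        converged=bool(res.converged),
    )


def difference_scores(cohort: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-subject (cards Log W - computer Log W) with demographic covariates.

    Subjects missing either task are excluded; the count of exclusions is
    returned alongside.  A negative score means better (lower-W) performance
    on cards.
    """
    required = {"participant_id", "logw_cards", "logw_computer"}
    missing = required - set(cohort.columns)
    if missing:
        raise KeyError(f"cohort is missing columns: {sorted(missing)}")
    complete = cohort.dropna(subset=["logw_cards", "logw_computer"]).copy()
    n_excluded = len(cohort) - len(complete)
    complete["diff_logw"] = complete["logw_cards"] - complete["logw_computer"]
    return complete, n_excluded


def crossover_education(intercept: float, edu_slope: float) -> float:
    """Education (years) at which the expected difference score crosses zero.

    The difference-score model predicts ``intercept + slope * education``;
    the crossover is ``-intercept / slope``.
    """
    if edu_slope == 0:
        raise UndefinedCrossoverError("crossover undefined for zero education slope")
    return -float(intercept) / float(edu_slope)


def sum_coding_combine(
    cards: tuple[float, float], computer: tuple[float, float]
) -> dict[str, float]:
    """Recombine per-task (intercept, education-slope) OLS fits into the
    sum-coded mixed-model fixed effects.

    With cards coded +1 and computer -1 on balanced complete pairs:
    intercept = mean of the task intercepts, task = half their difference,
    education = mean of the slopes, education:task = half their difference.
    """
    b0_c, b1_c = cards
    b0_p, b1_p = computer
    return {
        "intercept": (b0_c + b0_p) / 2.0,
        "task": (b0_c - b0_p) / 2.0,
        "education": (b1_c + b1_p) / 2.0,
        "education_task": (b1_c - b1_p) / 2.0,
    }


def _demographic_design(d: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "(Intercept)": 1.0,
            "Education": d["education_years"].astype(float),
            "Comp.First.sum": np.where(d["computer_first"].astype(bool), 1.0, -1.0),
            "scale(Age)": standardize(d["age_years"]),
            "Gender1": sum_code(d["gender"], "female"),
        },
        index=d.index,
    )


def fit_difference_model(
    cohort: pd.DataFrame, include_edu_order_interaction: bool = False
) -> RegressionResult:
    """The difference-score regression with demographic and order covariates.

    ``include_edu_order_interaction`` adds the education x task-order term
    (off by default; it is a diagnostic variant, not part of the main model).
    """
    d, _ = difference_scores(cohort)
    X = _demographic_design(d)
    if include_edu_order_interaction:
        X["Education:Comp.First.sum"] = X["Education"] * X["Comp.First.sum"]
    return fit_ols(d["diff_logw"], X)


def fit_education_model(cohort: pd.DataFrame) -> RegressionResult:
    """``education ~ scale(age) * gender`` — the demographics regression."""
    z = standardize(cohort["age_years"])
    g = sum_code(cohort["gender"], "female")
    X = pd.DataFrame(
        {
            "(Intercept)": 1.0,
            "scale(Age)": z,
            "Gender1": g,
            "scale(Age):Gender1": z * g,
        },
        index=cohort.index,
    )
    return fit_ols(cohort["education_years"], X)


def cohort_to_long(cohort: pd.DataFrame) -> pd.DataFrame:
    """Stack the wide cohort into one row per participant-task observation."""
    rows = []
    for task, col, s in (("cards", "logw_cards", 1.0), ("computer", "logw_computer", -1.0)):
        part = cohort[["participant_id", "education_years"]].copy()
        part["task"] = task
        part["task_sum"] = s
        part["logw"] = cohort[col].to_numpy()
        rows.append(part)
    long = pd.concat(rows, ignore_index=True).dropna(subset=["logw"])
    return long.sort_values(["participant_id", "task"]).reset_index(drop=True)


def _per_task_ols(cohort: pd.DataFrame, col: str) -> RegressionResult:
    d = cohort.dropna(subset=[col])
    X = pd.DataFrame(
        {"(Intercept)": 1.0, "Education": d["education_years"].astype(float)},
        index=d.index,
    )
    return fit_ols(d[col], X)


def reproduce_tables(cohort: pd.DataFrame) -> dict:
    """Run the full analysis suite on a cohort table.

    Returns a dict with the mixed model (``mixed_logw``), the per-task OLS
    fits on Log W (``ols_cards``, ``ols_computer``) and on raw W
    (``ols_cards_w``, ``ols_computer_w``), the difference-score model
    (``difference_model``), the demographics model (``education_model``),
    the crossover education in years, and the count of subjects excluded
    from paired analyses.
    """
    long = cohort_to_long(cohort)
    X = pd.DataFrame(
        {
            "(Intercept)": 1.0,
            "Education": long["education_years"].astype(float),
            "task1": long["task_sum"],
        },
        index=long.index,
    )
    X["Education:task1"] = X["Education"] * X["task1"]
    mixed = fit_lmm_random_intercept(long["logw"], X, long["participant_id"])

    w_cohort = cohort.copy()
    w_cohort["w_cards"] = np.exp(cohort["logw_cards"])
    w_cohort["w_computer"] = np.exp(cohort["logw_computer"])

    diff_model = fit_difference_model(cohort)
    _, n_excluded = difference_scores(cohort)
    return {
        "mixed_logw": mixed,
        "ols_cards": _per_task_ols(cohort, "logw_cards"),
        "ols_computer": _per_task_ols(cohort, "logw_computer"),
        "ols_cards_w": _per_task_ols(w_cohort, "w_cards"),
        "ols_computer_w": _per_task_ols(w_cohort, "w_computer"),
        "difference_model": diff_model,
        "education_model": fit_education_model(cohort),
        "crossover_years": crossover_education(
            diff_model["(Intercept)"], diff_model["Education"]
        ),
        "n_excluded_paired": n_excluded,
    }


def export_difference_scatter(cohort: pd.DataFrame, path) -> pd.DataFrame:
    """Write a plain education-vs-difference-score scatter table (TSV).

    Deliberately unsmoothed — a convenience export for external plotting.
    """
    d, _ = difference_scores(cohort)
    out = d[["participant_id", "education_years", "age_years", "gender", "diff_logw"]]
    out.to_csv(path, sep="\t", index=False)
    return out
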