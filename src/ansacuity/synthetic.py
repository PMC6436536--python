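"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a remote-population study cohort in three layers:

* demographics — adult ages from a truncated normal (mean 36.8, SD 16.3,
  range 17-77), balanced genders, schooling years (0-16) produced by a linear
  model on standardized age, gender and their interaction (younger men are
  the more educated group), and a task-order assignment near the study's
  78:63 cards-first/computer-first split;
* latent acuity — per-subject per-task Log W from the sum-coded fixed-effect
  model ``beta0 + beta_edu*edu + beta_task*s + beta_edu_task*edu*s`` (cards
  s = +1) plus a subject random intercept, a task-level residual, and a
  task-order shift that moves the cards-minus-computer difference by the
  order coefficient for computer-first subjects;
* observation — either *parametric* mode, where the latent Log W is emitted
  directly as the observed outcome, or *full* mode, where each
  participant-task pair is pushed through the practice gate and the 30-trial
  staircase and the observed Log W is the MAP re-fit of the simulated
  responses (so estimation noise and practice attrition are present).

Default coefficients and variance components are the package's reference
generating condition; see ``docs/methods.md`` for their provenance and units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import staircase
from .analysis import standardize
from .estimation import DEFAULT_BOUNDS, PriorSpec, fit_w_map

__all__ = [
    "EducationModel",
    "GenerativeParams",
    "Participant",
    "Dataset",
    "sample_demographics",
    "sample_true_logw",
    "generate_cohort",
]

_TASK_SUM = {"cards": 1.0, "computer": -1.0}


@dataclass(frozen=True)
class EducationModel:
    """Linear model for schooling years: ``edu ~ scale(age) * gender``.

    Gender is sum-coded with female = +1, so a negative ``b_gender`` makes
    men the more-educated group.  ``sd_resid`` is the latent Gaussian noise
    SD before rounding/clamping to the 0-16 year range.
    """

    intercept: float = 3.5706
    b_age: float = -1.2454
    b_gender: float = -1.2057
    b_age_gender: float = -0.4277
    sd_resid: float = 3.4


@dataclass(frozen=True)
class GenerativeParams:
    """All coefficients and variances of the synthetic cohort.

    Log W fixed effects use the sum-coded task (cards = +1); ``delta_order``
    is the coefficient of the (+1 = computer-first) order code in the
    cards-minus-computer difference-score model, applied as a symmetric
    ``+/- delta_order/2`` shift to the two tasks.
    """

    beta0: float = -1.252289
    beta_edu: float = -0.042551
    beta_task: float = -0.165655
    beta_edu_task: float = 0.031667
    sigma2_subject: float = 0.02481
    sigma2_resid: float = 0.20978
    delta_order: float = -0.38043
    edu_model: EducationModel = field(default_factory=EducationModel)
    n_participants: int = 141
    age_mean: float = 36.8
    age_sd: float = 16.3
    age_range: tuple[float, float] = (17.0, 77.0)
    prop_computer_first: float = 63.0 / 141.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_subject < 0 or self.sigma2_resid < 0:
            raise ValueError("variance components must be nonnegative")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not 0.0 <= self.prop_computer_first <= 1.0:
            raise ValueError("prop_computer_first must lie in [0, 1]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        if self.edu_model.sd_resid < 0:
            raise ValueError("education noise SD must be nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeParams":
        d = dict(d)
        if "edu_model" in d and isinstance(d["edu_model"], dict):
            d["edu_model"] = EducationModel(**d["edu_model"])
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)

    def implied_marginal_fixed_effects(self) -> dict[str, float]:
        """Fixed effects of the marginal Log W model the analysis stage fits.

        The order shift enters Log W as ``(delta_order/2) * o_i * s_task``;
        with an unbalanced order assignment (mean order code ``o_bar``) it
        folds into the marginal task coefficient.  Intercept, education and
        interaction are unaffected because the shift cancels within subject.
        """
        n = self.n_participants
        n_comp_first = int(round(n * self.prop_computer_first))
        o_bar = (2 * n_comp_first - n) / n
        return {
            "intercept": self.beta0,
            "education": self.beta_edu,
            "task": self.beta_task + 0.5 * self.delta_order * o_bar,
            "education_task": self.beta_edu_task,
        }


@dataclass(frozen=True)
class Participant:
    id: str
    education_years: int
    age_years: float
    gender: str  # 'female' | 'male'
    computer_first: bool
    passed_practice: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.education_years <= 16:
            raise ValueError(f"education must lie in 0..16, got {self.education_years}")
        if self.gender not in ("female", "male"):
            raise ValueError(f"gender must be 'female' or 'male', got {self.gender!r}")


@dataclass
class Dataset:
    """A generated cohort: wide outcome table plus full-mode raw material."""

    params: GenerativeParams
    mode: str  # 'parametric' | 'full'
    cohort: pd.DataFrame  # one row per retained participant
    true_logw: pd.DataFrame  # long: participant_id, task, true_log_w, true_w
    sessions: list[staircase.SessionRecord] = field(default_factory=list)
    n_practice_failures: int = 0


def sample_demographics(
    params: GenerativeParams, rng: np.random.Generator | None = None
) -> list[Participant]:
    """Draw ages, genders, schooling and task order for a cohort."""
    rng = rng or np.random.default_rng(params.seed)
    n = params.n_participants
    lo, hi = params.age_range
    a = (lo - params.age_mean) / params.age_sd
    b = (hi - params.age_mean) / params.age_sd
    ages = truncnorm.rvs(a, b, loc=params.age_mean, scale=params.age_sd,
                         size=n, random_state=rng)
    genders = np.where(rng.random(n) < 0.5, "female", "male")
    z = standardize(ages)
    g = np.where(genders == "female", 1.0, -1.0)
    em = params.edu_model
    latent = (
        em.intercept
        + em.b_age * z
        + em.b_gender * g
        + em.b_age_gender * z * g
        + rng.normal(0.0, em.sd_resid, size=n)
    )
    education = np.clip(np.rint(latent), 0, 16).astype(int)
    n_comp_first = int(round(n * params.prop_computer_first))
    comp_first = np.zeros(n, dtype=bool)
    comp_first[rng.permutation(n)[:n_comp_first]] = True
    width = len(str(n))
    return [
        Participant(
            id=f"p{i + 1:0{width}d}",
            education_years=int(education[i]),
            age_years=float(ages[i]),
            gender=str(genders[i]),
            computer_first=bool(comp_first[i]),
        )
        for i in range(n)
    ]


def sample_true_logw(
    participants: Sequence[Participant],
    params: GenerativeParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Latent per-subject per-task Log W (long format, with W = exp(Log W)).

    ``LogW(i, task) = beta0 + beta_edu*edu + beta_task*s + beta_edu_task*edu*s
    + u_i + eps_{i,task} + (delta_order/2)*o_i*s`` with ``u ~ N(0,
    sigma2_subject)``, ``eps ~ N(0, sigma2_resid)``, ``s`` the task sum code
    and ``o_i = +1`` for computer-first participants.
    """
    rng = rng or np.random.default_rng(params.seed + 1)
    rows = []
    sd_u = math.sqrt(params.sigma2_subject)
    sd_e = math.sqrt(params.sigma2_resid)
    for p in participants:
        u = rng.normal(0.0, sd_u)
        o = 1.0 if p.computer_first else -1.0
        for task in ("cards", "computer"):
            s = _TASK_SUM[task]
            lw = (
                params.beta0
                + params.beta_edu * p.education_years
                + params.beta_task * s
                + params.beta_edu_task * p.education_years * s
                + u
                + rng.normal(0.0, sd_e)
                + 0.5 * params.delta_order * o * s
            )
            rows.append(
                {"participant_id": p.id, "task": task,
                 "true_log_w": lw, "true_w": math.exp(lw)}
            )
    return pd.DataFrame(rows)


def _cohort_frame(participants: Sequence[Participant], logw: pd.DataFrame) -> pd.DataFrame:
    wide = logw.pivot(index="participant_id", columns="task", values="obs_log_w")
    rows = []
    for p in participants:
        rows.append(
            {
                "participant_id": p.id,
                "education_years": p.education_years,
                "age_years": p.age_years,
                "gender": p.gender,
                "computer_first": p.computer_first,
                "logw_cards": wide.at[p.id, "cards"] if p.id in wide.index else np.nan,
                "logw_computer": wide.at[p.id, "computer"] if p.id in wide.index else np.nan,
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(
    params: GenerativeParams,
    mode: str = "parametric",
    prior: PriorSpec = PriorSpec(),
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> Dataset:
    """Generate a full synthetic dataset at the given fidelity level.

    ``parametric`` emits the latent Log W directly; ``full`` simulates the
    practice gate and both 30-trial staircase sessions per retained
    participant and re-estimates Log W from the responses with the weak-prior
    MAP fitter, so the observed values carry estimation noise.
    """
    if mode not in ("parametric", "full"):
        raise ValueError(f"mode must be 'parametric' or 'full', got {mode!r}")
    ss = np.random.SeedSequence(params.seed)
    rng_demo, rng_logw, rng_sess = (np.random.default_rng(c) for c in ss.spawn(3))
    participants = sample_demographics(params, rng_demo)
    true_logw = sample_true_logw(participants, params, rng_logw)

    if mode == "parametric":
        obs = true_logw.copy()
        obs["obs_log_w"] = obs["true_log_w"]
        cohort = _cohort_frame(participants, obs)
        return Dataset(params=params, mode=mode, cohort=cohort, true_logw=true_logw)

    by_pid = true_logw.set_index(["participant_id", "task"])["true_w"]
    sessions: list[staircase.SessionRecord] = []
    retained: list[Participant] = []
    obs_rows = []
    n_fail = 0
    for p in participants:
        first_task = "computer" if p.computer_first else "cards"
        w_first = float(by_pid[(p.id, first_task)])
        practice_seed = int(rng_sess.integers(0, 2**31))
        practice = staircase.run_practice(w_first, practice_seed)
        if not practice.passed:
            n_fail += 1
            continue
        retained.append(replace(p, passed_practice=True))
        for task in ("cards", "computer"):
            w_true = float(by_pid[(p.id, task)])
            sess_seed = int(rng_sess.integers(0, 2**31))
            rec = staircase.simulate_session(w_true, task, p.id, sess_seed)
            sessions.append(rec)
            est = fit_w_map(rec.trials, prior=prior, bounds=bounds)
            obs_rows.append(
                {"participant_id": p.id, "task": task, "obs_log_w": est.log_w}
            )
    obs = pd.DataFrame(obs_rows)
    cohort = _cohort_frame(retained, obs)
    return Dataset(
        params=params,
        mode=mode,
        cohort=cohort,
        true_logw=true_logw,
        sessions=sessions,
        n_practice_failures=n_fail,
    )
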