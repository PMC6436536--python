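# Methods

This note documents the models, default parameters, and design decisions in
`ansacuity`, and what the simulation-based validation does and does not
establish.

## Psychometric model

Numerosities are represented as scalar-variability Gaussians: a set of `n`
dots maps to `Normal(n, (W·n)²)`. A two-set comparison is answered correctly
when the representation of the larger set exceeds the smaller one's, giving

    p(correct | n₁, n₂, W) = Φ( |n₁ − n₂| / (W √(n₁² + n₂²)) )

This is the canonical linking function of the maximum-likelihood
Weber-fraction fitting tradition, and the single point of change if a
different link is ever wanted (`psychophysics.p_correct`). The closed form
is verified in the tests against a two-Gaussian Monte-Carlo oracle at ≥ 10⁶
draws per condition.

Assumptions: trials are conditionally independent given `W`; no sequential
dependencies, no response-time component, and no use of non-numerical cues
(dot area, density). A lapse/guessing rate is supported
(`p_eff = (1−λ)p + λ/2`) but defaults to 0, since the reference analysis fits
none; all-correct sessions are instead handled by the search bounds and the
boundary flags. Inside the log-likelihood, per-trial probabilities are
clamped to `[1e−9, 1 − 1e−9]` so the objective stays finite at extreme `W`.

## The staircase task

Twelve ratio levels with fixed count pairs: 5:15, 7:14, 8:12, 9:12, 8:10,
10:12, 12:14, 7:8, 8:9, 9:10, 10:11, 11:12 (labels 1:3 … 11:12, totals as
close to 20 dots as the ratios allow). Level 0 (1:3) is used only for
practice. A test session is 30 trials starting at 1:2 under a
two-up/one-down rule: two consecutive correct answers promote one level, an
error demotes one level, and errors at 1:2 keep the participant at 1:2.

Bookkeeping choices the rule's verbal description leaves open:

* **Ceiling**: two correct at 11:12 stay at 11:12 (standard staircase
  convention; only the floor is prescribed).
* **Counter**: the consecutive-correct counter resets on every error, every
  level change, and on the promotion-clamp at the ceiling.
* **Decks**: each level has 8 trial versions (4 red-correct, 4
  black-correct), dealt without replacement from a seeded shuffle; an
  exhausted deck is reshuffled, since a floor-sitting chance responder needs
  more than 8 trials at one level.

The practice gate is up to three 8-trial blocks at 1:3; an attempt passes
only with zero errors. A pure guesser therefore passes with probability
`1 − (1 − 0.5⁸)³ ≈ 1.17%`, which the tests verify by simulation.

Stimulus geometry (`make_stimulus_spec`) generates radii log-uniform in
[0.02, 0.07] (unit-disc units) and then forces the largest and smallest
radius to be equal across the two color sets — the only constraint the task
description actually fixes. Centers are rejection-sampled to be
non-overlapping inside the unit disc. Geometry is a serializable spec, not a
rendered image, and does not feed back into simulated responses.

## Weber-fraction estimation

`fit_w_ml` maximizes the session log-likelihood over `W ∈ [0.01, 3.0]`
(bounds cover all plausible human values); `fit_w_map` adds a log prior.
The optimizer works in `log W` (better conditioning), bracketing the global
mode with a 64-point log-spaced scan before a bounded Brent refinement, so
it provably agrees with a dense grid search (tested against a 2,000-point
grid oracle). When a search bound ties the optimum — the clamp flattens the
objective into a plateau for all-correct or chance sessions — the estimate
snaps to the bound and the corresponding boundary flag is set. Fits are
bit-for-bit deterministic given the trials and settings.

**Prior.** Default `exponential(scale = 1.0)` on `W`: the simplest monotone
density favoring small `W`, weak enough that informative sessions move
negligibly. A half-normal family and a `none` family (exactly ML) are
provided. The MAP mode is the posterior mode in `W` (no Jacobian re-scoring
in log space). Simulations in the test suite show var(MAP) < var(ML) with
|mean shift| < 0.05 at `W = 0.25`.

**Log convention.** `Log W` is the natural logarithm throughout: a grand
mean near −1.25 corresponds to `W ≈ 0.29`, an ordinary adult Weber fraction,
whereas a base-10 reading would imply an implausible `W ≈ 0.056`.

## Synthetic cohort generator

The generator produces cohorts with the covariance structure the analysis
stage assumes. Defaults (all configurable via `GenerativeParams`):

| parameter | default | units / meaning |
|---|---|---|
| `n_participants` | 141 | analyzed cohort size |
| `age_mean`, `age_sd`, `age_range` | 36.8, 16.3, (17, 77) | years; truncated normal |
| `prop_computer_first` | 63/141 | task-order split |
| `beta0` | −1.252289 | grand-mean Log W |
| `beta_edu` | −0.042551 | Log W per education year |
| `beta_task` | −0.165655 | half the cards−computer Log W gap |
| `beta_edu_task` | 0.031667 | education × task interaction |
| `sigma2_subject` | 0.02481 | subject random-intercept variance |
| `sigma2_resid` | 0.20978 | residual Log W variance |
| `delta_order` | −0.38043 | order coefficient on the difference score |
| `edu_model` | (3.5706, −1.2454, −1.2057, −0.4277, 3.4) | education ~ scale(age)×gender; latent SD |

Conventions: task is sum-coded cards = +1; gender is sum-coded female = +1
(so the negative gender coefficients encode the cohort's young-and-male
education gradient); the order shift enters Log W as
`(delta_order/2)·o·s` with `o = +1` for computer-first participants, so the
cards-minus-computer difference score moves by `delta_order` per unit of the
order code — a practice benefit to whichever task comes second.

Education is generated as a latent Gaussian linear predictor on standardized
age, gender and their interaction, then rounded and clamped to 0–16 years.
The latent noise SD (3.4) is not part of the reference coefficient set; it
was back-derived from the scale of the education model's intercept standard
error (`0.2849·√141 ≈ 3.4`). Because the latent mean (≈ 3.6) sits near the
floor, roughly a sixth of the latent mass censors at 0; fitted education
coefficients on generated cohorts are therefore attenuated by ~20% relative
to the latent ones. The tests verify exact recovery when the latent mean is
mid-range and the qualitative structure under the default censoring.

**Fidelity modes.** `parametric` emits the latent Log W directly — the right
mode for validating the regression stage, since the observations follow the
generating model exactly. `full` pushes every participant through the
practice gate (using their first-task `W`; the gate precedes the first task)
and both 30-trial staircase sessions, then re-estimates Log W by MAP. Full
mode adds estimation noise (larger marginal Log W variance) and attenuates
the group-level effects toward zero; under the defaults ~3–13% of
participants fail practice, concentrated among low-education high-`W`
computer-first subjects. The generator does not emulate: familiarity or
attention effects beyond the order shift, non-numerical stimulus cues,
sequential trial dependencies, or the surveyed-but-unmodeled covariates
(Spanish proficiency, household size). Passing recovery tests on these
cohorts therefore validates the statistical machinery, not the behavioral
completeness of the model.

## Analysis stage

OLS fits report the usual coefficient table with two-sided p-values on
`n − k` residual df. The mixed model is fit by maximum likelihood (not
REML), matching the convention of the reference tables, via a profiled
single-variance-component routine (statsmodels `MixedLM`); it reports
logLik, AIC, BIC and deviance with `k = #fixed + 2` parameters. Because the
reference mixed-model table prints t values only, the package reports both t
and Wald-normal p-values for fixed effects; these p-values are asymptotic
and slightly anti-conservative at n = 141.

On balanced complete pairs the sum-coded mixed model's fixed effects are an
exact linear recombination of the two per-task OLS fits (mean /
half-difference of intercepts and slopes); `sum_coding_combine` implements
the identity and the tests hold it to 1e−8 on every simulated cohort. The
optional education × order interaction in the difference-score model is off
by default (a diagnostic variant). Subjects missing a task are excluded from
paired analyses and counted.

## Validation experiment design and problem sizes

* **Estimator validity**: grid-oracle equivalence on 10 random sessions;
  MAP recovery at true `W ∈ {0.15, 0.25, 0.40}` over 500 sessions each;
  variance-reduction check on the same replicates.
* **End-to-end recovery**: 500 parametric cohorts of n = 141 generated from
  the reference mixed model itself — i.e. with `delta_order = 0`, since the
  order shift is a difference-score quantity that, added on top of the
  mixed model's variance components, cancels within-subject covariance and
  misspecifies the fitted model. Wald intervals use the t quantile with
  `n_subjects − 2` df (each sum-coded effect is, by the balanced identity, a
  per-subject regression coefficient with that df); observed coverage is
  ~94–97% per fixed effect.
* **Staircase limits**: the noiseless forced climb is checked exactly; the
  chance practice pass rate is checked over 10⁵ seeded runs against the
  closed form.

## Known limitations

* A 30-trial staircase is information-limited at high `W`: at true
  `W = 0.40` the MAP fit's median absolute error is ≈ 0.09 (median bias
  ≈ −0.04), versus ≈ 0.03 at `W = 0.15` and ≈ 0.06 at `W = 0.25`. Session
  length, not the optimizer, is the binding constraint; this is precisely
  the regime the weak prior is for.
* Mixed-model subject variance frequently hits the zero boundary on cohorts
  of this size when the intraclass correlation is small; fixed effects are
  unaffected (they equal the OLS recombination on balanced data) and the
  boundary fit is reported as-is.
* Full-fidelity cohorts attenuate the education × task interaction through
  estimation noise and practice-gate selection; the interaction's sign
  survives in most replicates but its magnitude is biased toward zero.
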