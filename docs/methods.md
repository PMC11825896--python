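# Methods

This note documents the statistical model `edlatent` implements, the
synthetic cohort it is validated on, and the numerical and design choices
a maintainer would want to know about.

## The estimand and why a latent variable

The target is the average treatment effect (ATE) of hospital admission vs
discharge on binary post-discharge outcomes — ED revisit, hospital
readmission, and death within 3, 9, and 30 days of final discharge —
expressed as a risk difference (RD) in percentage points. The central
obstacle is confounding by indication: the clinician's impression of
severity drives both the disposition and the outcome, and is only
partially recorded. The model introduces a binary latent health state
`H` (adverse vs benign) to absorb this, identified through five proxy
observations taken before the admission process begins (triage acuity and
four vital signs). Identification rests on two assumptions: potential
outcomes are independent of the disposition given `(H, x)`, and visits
are independent of one another.

## Model components

* **Latent prior** — logistic regression of `H` on the seven baseline
  characteristics (age, sex, insurance class, diabetes, CHF,
  hypertension, HCC score), encoded as a 9-column design (continuous
  covariates standardised, insurance dummy-coded against medicare).
* **Proxies** — linear-Gaussian models for temperature, blood pressure,
  respiration rate and heart rate; a logistic model for the ESI = 2
  indicator. Each has an `H` main effect and baseline effects.
* **Admission process** — a two-boundary Wiener first-passage model:
  unit-diffusion evidence starts at `w₀·a ∈ (0, a)` and drifts at rate
  `μ = δ₀ + δ_H H + δ_x·x + δ_w·w`; absorption at `a` is admission,
  at 0 discharge, and the absorption time is the treatment time (hours).
  Diffusion is fixed at 1 and the geometry (`a`, `w₀`) is covariate-free,
  the minimal identifiable parameterisation for a joint decision/timing
  likelihood. The defective first-passage densities use the dual
  small-time/large-time series representations, switching at
  `t/a² = 0.18`, truncated when a term falls below 1e-9, evaluated in the
  log domain (floor `exp(-690)`).
* **Outcomes** — identity-link Bernoulli models
  `P(Y_k=1) = β_k0 + β_kH H + β_kA A + β_kHA H·A`, clamped to
  `[1e-6, 1-1e-6]`. The identity link keeps `β_kA` on the risk-difference
  scale. The admission main effect and the latent-by-admission
  interaction are included by default (`include_interaction=False` drops
  the interaction); the interaction is what lets subgroup effects differ.
  The three windows of one outcome family are nested truncations of a
  single event, so they enter the likelihood as one categorical over the
  increment pattern `(Y₃, Y₉−Y₃, Y₃₀−Y₉, 1−Y₃₀)` rather than as three
  independent Bernoullis — treating them as independent misstates the
  joint law badly enough to bias every component (verified by initialising
  EM at the generating parameters and watching it walk away).

## Fitting

EM with exact E-step (posterior responsibility `γ_i`, computed in the log
domain) and conditional M-steps:

* latent prior and acuity model — fractionally weighted logistic MLE on
  the doubled frame (each visit appears as `H=1` with weight `γ_i` and as
  `H=0` with weight `1−γ_i`); complete separation is handled by capping
  the linear predictor at ±30 and flagging the fit;
* continuous proxies — closed-form weighted least squares plus weighted
  residual SD;
* outcomes — closed-form weighted cell means (the saturated MLE) under
  the interaction model, a small Nelder–Mead fit without it; the clamp is
  applied to the cell probabilities;
* threshold block — warm-started L-BFGS on `(log a, logit w₀, δ)` with
  analytic drift gradients (the drift enters the density only through an
  exponential prefactor) and central-difference geometry partials,
  limited to a few inner iterations per EM step (a generalized-EM update:
  the update is kept only if it improves its expected complete-data
  objective, so monotonicity survives).

Each conditional step cannot decrease the observed log-likelihood, so the
trace is non-decreasing; this is asserted in the tests with 1e-8 relative
slack. Convergence is declared when the relative change falls below
`rel_tol` (default 1e-8, `max_iter` 500; the simulation studies use 1e-7
and 120, which the trace plateaus comfortably within).

**Initialisation and restarts.** A 2-component Gaussian mixture on the
four continuous proxies provides a severity split, oriented so the
higher-temperature component is adverse, then blended 50/50 with the
admission indicator — encoding the clinical prior that adverse-state
patients are admitted more often. This matters: a split on the first
principal proxy alone reproducibly converged to a wrong-sign local mode
(`δ_H < 0`) with a posterior decoupled from the latent state. Restarts
(default 10) perturb the initial responsibilities on the logit scale;
the best final likelihood wins. Label ambiguity is resolved by requiring
the latent temperature effect to be nonnegative (the swap
`H ↔ 1−H` with the matching parameter transformation is
likelihood-preserving).

**Uncertainty.** The parameter covariance is the inverted
outer-product-of-gradients (observed-information) estimate built from
central-difference per-visit scores (step `1e-5·(1+|θ|)`); it needs `2p`
likelihood sweeps instead of the `O(p²)` a full numerical Hessian would,
and agrees with it in expectation under correct specification. If the
information matrix is not positive definite the fit is flagged and a
bootstrap is recommended. The ATE standard error propagates this
covariance through the per-visit counterfactual contrast by the delta
method, re-running the E-step at perturbed parameters so posterior
uncertainty is included. Counterfactual predictions integrate `H` over
the *posterior* `γ_i` (each visit's observed data held fixed), not the
prior.

## Comparators

Unadjusted two-proportion RD; Hájek (normalised) IPW with a logistic
propensity model on baseline + proxies, scores trimmed to
`[1e-6, 1−1e-6]`, no weight truncation by default; and parametric
g-computation (logistic outcome model on admission + measured variables,
standardised over the empirical covariate distribution). IPW and
g-computation use a seeded nonparametric bootstrap (default 500
resamples) including the model refit. Note the true assignment mechanism
is a first-passage probability, not a logistic — the logistic propensity
is an approximation, adequate at the confounding strengths of the default
scenarios but another reason these estimators are comparators rather than
the primary analysis.

## Synthetic cohort

The generator realises the model forward, with defaults calibrated once
to the descriptive statistics of a 3,591-visit cohort of older adults
(age ~ truncated normal 79.2 ± 8.9 on [65, 110]; 58.5% female; 91.9%
medicare; HCC ~ gamma with mean 1.65, SD 1.41; presentation mix 44%
falls / 16% weakness / 13% syncope / 13% UTI / 8% pneumonia / 6%
cellulitis; vital-sign means and SDs matched; ~28% ESI 2; ~39% admitted;
mean treatment time ≈ 1.7 h via `a = 3.4`, `w₀ = 0.38`, `δ₀ = −0.55`,
`δ_H = 1.5`). Latent prevalence is ≈ 0.33. True 30-day outcome
coefficients use `β_A` of −6.4, +5.8 and +1.0 percentage points for
revisit, readmission and mortality, so the generator's ground-truth ATEs
sit at the adjusted estimates a practitioner would expect for this
population; `β_H > 0` makes the adverse state worse off, which combined
with `δ_H > 0` creates the confounding by indication the estimator
exists to remove. The 30-day event is the primitive Bernoulli; an
event's day is uniform on (0, 30], making the 3- and 9-day indicators
deterministic truncations (so window-w effects are the 30-day effects
scaled by w/30).

First-passage pairs are simulated by Euler steps (`dt = 1e-4·a²`; the
Gaussian transition is exact for constant drift) with a Brownian-bridge
crossing check each step, which removes the leading-order discretisation
bias in the absorption probability; absorbed times use the midpoint of
the crossing step. Screening fields (troponin, pulse oximetry, systolic
BP, diagnosis flags, visit dates, eloped/AMA/transfer dispositions, the
2% out-of-range triage levels) exist to exercise the exclusion rules and
are independent of the latent process. Missingness is MCAR with modest
per-field rates, matching what median/mode imputation assumes; the
decision and treatment time are never masked.

Named scenarios: `default` (latent confounding), `randomized` (zero drift
effects), `measured_confounding` (no latent effects; admission and
outcomes share HCC — the generator's outcome models accept baseline
effects precisely so this scenario exists), `null` (zero admission
effect) and `heterogeneous` (latent-by-admission interactions).

**What the generator does not emulate** — and hence what passing tests do
not establish about real EHR data: informative missingness,
measurement-error correlation between proxies, time-varying severity,
competing risks (a flag exists to censor post-death events but is off by
default), coding artefacts, and any deviation of the true admission
process from the Wiener form. Recovery results here show the estimator
works when its assumptions hold; they cannot show the assumptions hold in
practice.

## Cohort definition and preprocessing

Inclusion/exclusion follows the study rules exactly, with all cutoffs
strict as printed (ESI ∈ {2,3}; admitted or discharged to
residence/SNF/IRF, with SNF/IRF then counted as discharges; visits in the
last 45 days of the sample period dropped; troponin > 0.10 ng/mL,
systolic BP < 80 mmHg, respiration rate > 30/min, SpO₂ < 88%, heart rate
> 120/min, stroke/MI/femur-fracture flags, and cellulitis with
temperature > 100.3 °F excluded). Missing screening values never trigger
an exclusion (absence of evidence of abnormality). Excluded visits are
counted under their *first* failing rule in a fixed order (disposition →
acuity → 45-day tail → troponin → vitals → diagnosis flags →
cellulitis/fever) so filter reports are reproducible. Imputation is
median/mode on the filtered cohort (ties to the smallest category),
then standardisation with sample mean and SD (ddof = 1); both orders of
operations follow the stated pipeline: filter, impute, standardise.

## Problem sizes used in validation

The simulation studies use cohorts of n = 5,000 with 20 replications for
parameter and ATE recovery (about 25 s per replication on one CPU),
n = 1,000 across 50 seeds for the EM-ascent property, n = 4,000 with 5
replications per scenario for the estimator concordance/contrast
structure, and 10⁶ simulated first passages for the density cross-check.
At n = 5,000, roughly 96% of generating parameters fall inside their 95%
Wald intervals across replications, the mean bias of each outcome's
admission coefficient is below 0.02, and the 95% CI for the overall RD
covers the true ATE in 20/20 replications per outcome. Running the full
pipeline (with MCAR missingness and imputation, rather than the clean
generator frame) roughly preserves unbiasedness but inflates the per-run
spread of the latent RD to about 3–6 percentage points at this n; the
reported Wald intervals reflect that.

## Known limitations

* The latent state is binary; an ordinal or continuous severity axis is a
  natural extension the config leaves room for but nothing implements.
* `β_A` and `β_HA` are weakly separated when the posterior is far from
  0/1, so individual outcome coefficients are noisy even when the ATE is
  well estimated; intervals are honest about this.
* The delta-method SE treats the model as correctly specified; no
  sandwich correction is offered.
* Subgroup CIs propagate parameter uncertainty only, not the sampling
  variability of subgroup membership.
* No multiple-testing adjustment anywhere, by design; nominal CIs and
  p-values only.
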