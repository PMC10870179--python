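# Methods

## The model

`weightmsm` analyses longitudinal weight change in primary-care cohorts as a
**panel-observed continuous-time multistate Markov model**. Weight status is
categorized relative to each patient's baseline weight into five states:

| state | meaning                  | relative weight band  |
|------:|--------------------------|-----------------------|
| 1     | ≥10% loss                | w ≤ 0.90·b            |
| 2     | 5–10% loss               | 0.90·b < w ≤ 0.95·b   |
| 3     | stable (baseline ±5%)    | 0.95·b < w < 1.05·b   |
| 4     | 5–10% gain               | 1.05·b ≤ w < 1.10·b   |
| 5     | ≥10% gain                | w ≥ 1.10·b            |

Patients move only between **adjacent** states, giving a birth–death ladder
with eight transition intensities. Each intensity has a proportional
(log-linear) form

    q_rs(z) = q⁰_rs · exp(β_rsᵀ z),

where z collects baseline covariates and time-varying weight-management
treatment (WMT) exposure indicators, and exp(β) is the hazard ratio (HR) of
a covariate on that transition. Because weights are recorded only at clinic
visits, transition *times* are never observed — only the state at each visit.
The likelihood for an observation pair (s_i at t_i, s_{i+1} at t_{i+1}) is
therefore the (s_i, s_{i+1}) entry of the interval transition-probability
matrix

    P(t_i, t_{i+1}) = ∏_j expm( Q(z_j) · Δt_j ),

the product running over the piecewise-constant exposure segments between the
two visits. Splitting at exposure changepoints is *exact* under the model;
an alternative "value-at-interval-start" compatibility mode is provided
because panel-MSM tooling conventions differ (`covariate_timing=
"interval-start"`).

### Exposure coding

The time-varying WMT exposures follow recency-window rules, all in days from
the trajectory baseline:

* **nutrition_90d** — a registered-dietitian visit occurred in the prior 90
  days. An event on day d activates the indicator on [d, d+90): the event
  counts on its own day and expires when the window elapses.
* **mr_early_active / mr_late_active** — a very-low-calorie meal-replacement
  (MR) program visit in the prior 90 days, split by program phase: early
  while t − program_start < 184 days (~months 1–6), late for 184–730 days
  (~months 6–24). Patient-specific calendar months are approximated by
  30.5-day months.
* **aom_any** — any anti-obesity-medication order interval covers t,
  pooling the dedicated agents with GLP-1 receptor agonists prescribed for
  type-2 diabetes; off-label single-agent combinations (phentermine +
  topiramate, bupropion + naltrexone) are captured as interval
  intersections, which `cohort.combination_exposure_intervals` also reports
  separately for utilization tables.
* **surgery bins** — one-hot time-since-bariatric-surgery bins 0–90,
  91–180, 181–364 and ≥365 days, monotone non-decreasing over follow-up.

Boundary conventions: loss cut points are inclusive on the loss side and
gain cut points on the gain side ("10% or greater loss" ⇒ w = 0.90·b is
state 1); the stable state is the open interval. Ties are not otherwise
specified by the category definitions, so the convention is centralized in
`cohort.derive_weight_states` and documented there.

### Covariate masking

Not every covariate is estimable on every transition: exposed person-time in
the extreme states is rare. `TransitionStructure` carries a per-transition
boolean mask; masked-out coefficients are fixed at log-HR 0 and reported as
not estimated. The default production pattern puts demographics, nutrition,
MR-early and AOM on all eight transitions; MR-late and the granular surgery
bins only on transitions out of the loss states (2→1, 1→2, 2→3); and a
pooled ">90 days since surgery" level only on the transitions out of
baseline. Derived pooled indicators (`surg_gt90`, `surg_any`, `mr_active`)
are available for sparser cohorts.

## Estimation

Maximum likelihood over (log q⁰, β). The driver is L-BFGS-B with an
**analytic gradient**, followed by a damped Newton polish using the observed
information, which settles flat ridges that limited-memory quasi-Newton can
stall on. The gradient uses the eigendecomposition form of the Fréchet
derivative of the matrix exponential: with Q = V Λ V⁻¹,

    d expm(Qt) = V ( F ∘ (V⁻¹ dQ V) ) V⁻¹ ,
    F_ij = (e^{λ_i t} − e^{λ_j t}) / (λ_i − λ_j),   F_ii = t e^{λ_i t},

so the derivative of one probability entry against all parameters collapses
to an inner product per exposure segment. The likelihood value itself is
cross-checked against scaling-and-squaring Padé `expm`, which is also what
the public `interval_probability` uses; if an eigenvector matrix is badly
conditioned (condition number > 1e10) the fitter falls back to the Padé
path with complex-step differentiation. The covariance estimate is the
inverse of the observed information, computed by central differences of the
analytic gradient; Wald CIs use z = 1.96 with no multiplicity correction.

Initial values are crude occurrence/exposure rates: observed adjacent
interval transitions divided by time at risk in the origin state, floored at
1e-6/day, with β = 0. Zero-probability observations contribute −∞ to the
public log-likelihood; inside the optimizer probabilities are floored at
1e-300 so line searches can recover.

## Summaries

* **1-year state probabilities** (`prediction.state_probabilities`): row
  `start_state` of the 364-day interval matrix under an idealized,
  uninterrupted exposure schedule. MR phases advance (early for days 0–183,
  then late) by default; an "early-throughout" mode is provided since the
  idealized schedule for a phased program is a modelling choice. For
  surgery, the time-since bins advance 0–90 / 91–180 / 181–364; the ≥365
  bin is unreachable within a 364-day horizon.
* **CIs** by multivariate-normal simulation of the parameter vector
  (default B = 1000, percentile intervals, seeded); a non-PSD covariance is
  repaired by clipping negative eigenvalues, with a warning.
* **Population counterfactuals** (`counterfactuals`): per-patient 1-year
  probabilities of ≥5% loss propagated through each patient's *actual*
  exposure timeline; AME = mean(observed) − mean(all WMT zeroed);
  PAF = AME / mean(observed), in percent; per-WMT AMEs zero one treatment
  at a time. Fold-increase scenarios scale the per-patient WMT contribution
  linearly — p_i(m) = p_i(0) + m·[p_i(1) − p_i(0)], clipped to [0, 1] — so
  the per-fold increment of the population mean equals the AME by
  construction. A "k-fold increase" can be read as multiplier k
  (`fold_convention="multiply"`, default) or k+1 (`"increase-by"`); both are
  exposed because a reported fold-increase series can be arithmetically consistent
  with the latter reading. A resampling mode instead copies exposed
  patients' exposure histories onto randomly selected unexposed patients
  (m−1) more times. The **tipping point** is the smallest multiplier whose
  loss-minus-gain difference is positive with a CI excluding zero.

## Cross-sections and matching

Yearly cross-sections take each patient's first weight in the calendar year.
Year contrasts use GEE with patient clusters, exchangeable working
correlation (moment estimate) and robust HC0-style sandwich errors —
Gaussian/identity for BMI, binomial/logit for prevalence and utilization —
summarized by AMEs with delta-method CIs. Age enters adjusted models
linearly; a spline was considered and rejected for parity with the simple
reported adjustment set.

Comparator selection fits a logistic propensity model (follow-up time, age,
BMI, sex, weight-related condition flags) and matches exposed to unexposed
1:1 **without replacement** within the 16 strata of sex × majority race ×
majority ethnicity × any weight-related condition, minimizing the total
|logit propensity difference| by optimal rectangular assignment
(`scipy.optimize.linear_sum_assignment`) — never worse than greedy
nearest-neighbour, and exact on small strata by enumeration. No caliper is
applied by default, matching the design in which every exposed patient is
retained. Balance is verified with standardized mean differences
(max |SMD| < 0.1 criterion).

## Synthetic cohort generator

`synthetic_ehr.simulate_population` emulates the raw material of the study
so every stage is testable without access to health-system data:

* demographics: age ~ N(50, 15²) truncated to 18–90, 57% female, 79%
  majority race, 3% Hispanic; weight-related condition flags at low
  prevalences; height ~ N(1.68, 0.09²) m.
* baseline BMI ~ N(35, 5²) truncated at 30, so the trajectory cohort is a
  cohort with obesity; baseline weight = BMI·height².
* panel observation: a homogeneous Poisson visit process (default 4
  visits/year over ~3 years) — the simplest process whose inter-visit gaps
  the panel likelihood conditions on; two pre-entry visits satisfy the
  2-visits-≥358-days-apart eligibility rule.
* WMT uptake: logistic in baseline BMI and comorbidity (deliberate
  confounding for the matching stage to remove), with uptake probabilities
  ~6.3% nutrition, 0.4% MR, 2.6% AOM, 1.0% surgery among patients with
  obesity (~10% any WMT). Uptake draws event streams (dietitian visits,
  MR visits, medication order intervals, a surgery date) which are coded
  into exposures by the *same* cohort-builder rules the analysis uses — so
  latent dynamics and downstream exposure coding agree by construction.
* latent dynamics: exact Gillespie simulation under piecewise-constant
  intensities. Default baseline intensities (per day, transitions
  2→1, 3→2, 4→3, 5→4, 1→2, 2→3, 3→4, 4→5):
  0.00246, 0.00168, 0.00479, 0.00118, 0.00322, 0.00978, 0.00111, 0.00184 —
  calibrated once so the 364-day no-treatment distribution from baseline is
  ≈ (5.1, 10.7, 67.8, 11.7, 4.9)%, i.e. ≈16% achieving ≥5% loss, matching
  the reference no-WMT profile. Ground-truth WMT hazard ratios are modest
  for nutrition (1.35 loss-side), strong for MR-early (6.0) and early
  surgery (12.0), intermediate for medication (1.55), with gain-side HRs
  below 1 — the qualitative ordering reported for these treatments.
* observed weights are drawn uniformly on the *open* relative-weight band of
  the occupied state (open-ended bands truncated at ±20%), with a 1e-6
  margin so emitted weights never sit on a category boundary; the day-0
  weight is the baseline itself. Only the state is model-relevant, so the
  within-band distribution is intentionally simple.

What the generator does **not** emulate: measurement error and EHR coding
noise, drug-specific dose effects, anthropometric growth curves, seasonal
visit patterns, informative observation (sicker patients visiting more), or
mortality/pregnancy censoring at realistic rates. Passing tests therefore
demonstrate that the *machinery* — exposure coding, likelihood, optimizer,
counterfactual propagation — is correct under the model's own assumptions,
not that the model is robust to real-data violations of them.

## Problem sizes and numerical choices

The test suite and acceptance script run on scaled-down cohorts chosen to
keep Monte-Carlo error well inside the asserted tolerances: parameter
recovery uses 2000 patients × ~6 visits per replicate with a 50%-exposed
always-on treatment (HR 2.0 loss-side / 0.7 gain-side) over 20 replicates;
simulation oracles use 1e5 exact paths (3 Monte-Carlo-SE bands); the
pipeline demonstration uses 4000 patients. Probability matrices are
row-stochastic to 1e-10; interval splitting reproduces the unsplit product
to 1e-12 (Chapman–Kolmogorov); the two-state closed form is matched to
1e-10.

## Known limitations

* Death, pregnancy and metastatic cancer truncate follow-up rather than
  entering as absorbing states; with informative censoring the intensities
  are biased toward the healthy.
* Weight-status misclassification (scale noise around band boundaries) is
  not modelled; a hidden-Markov extension is out of scope.
* The baseline intensities are time-homogeneous; secular drift is absorbed
  into covariates or ignored.
* MLEs for exposure coefficients on transitions with no exposed events
  diverge; such coefficients should be masked out (the default structures
  do), and the fitter reports a singular information matrix when they are
  not.
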