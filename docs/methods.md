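# Methods

`prostasim` reimplements a population microsimulation of prostate-specific
antigen (PSA) screening for prostate cancer in an ageing, middle-income male
population, together with the screening decision tree, post-diagnosis
prognosis model and health-economic evaluation built on top of it. This note
records the model, its conventions, the choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Model structure

The simulation has three coupled parts:

1. **Natural-history microsimulation** (yearly cycle). Each man carries a
   latent timeline: tumour onset with hazard linear in age,
   `λ_o(t) = γ_o·t`; a Gleason grade (low/high risk) fixed at onset with
   `P(low) = γ_LR`; mean log PSA growing as
   `P(t) = b + a0·t + a_x·(t − t_o)` after onset (`a_x = a1` low-risk,
   `a2` high-risk); metastasis and clinical (symptomatic) detection with
   PSA-proportional hazards `exp(P)·γ_m` and `exp(P)·γ_c`, the latter
   multiplied by `θ_c` once metastatic. Undiagnosed men die of other causes
   by an age-specific life table.
2. **Screening decision tree**. At scheduled ages an observed PSA
   (`exp(P + ε)`, `ε ~ N(0, σ_ε²)`) is compared with the protocol cutoff
   (fixed 4.0 ng/mL, or 2/3/4/7 ng/mL by age band). Positives get
   multiparametric MRI (sens 0.89, spec 0.80); MRI positives get a targeted
   biopsy (sens 0.64, spec 1.00 — no false-positive diagnoses); PSA above
   10 ng/mL goes directly to systematic biopsy. Adherence is 100%.
3. **Eight-state monthly Markov prognosis model** (RP, RT, BCR after each,
   mHSPC, nmCRPC, mCRPC, Death) with the published monthly transition
   probabilities. Localized cases enter RP with probability 0.90, else RT;
   metastatic cases enter mHSPC. Each calendar year's diagnoses are spread
   uniformly over 12 monthly entry cycles.

All event times are drawn by **exact inverse transform**: because `exp(P(t))`
is piecewise exponential in age, every cumulative hazard has a closed form
and a closed-form inverse (the degenerate flat-PSA case `a0 + a_x = 0` is
handled as a separate linear branch). No integration grid is involved;
hazards use the noise-free mean PSA trajectory, while the observation noise
`ε` affects only screening test values.

## Key parameters

| parameter | meaning | default |
|---|---|---|
| `γ_o` | onset hazard slope (yr⁻² ) | 0.00024 |
| `γ_m`, `γ_c` | metastasis / detection hazard per unit PSA (yr⁻¹) | 0.0004 / 0.0005 |
| `θ_c` | detection boost after metastasis | 19.1334 |
| `γ_LR` | share of low-risk tumours | 0.673 |
| `a0, a1, a2, b` | log-PSA growth (log ng/mL per yr; intercept) | 0.0215 / 0.0566 / 0.1051 / −0.1061 |
| `σ_ε` | log-PSA observation noise | 0.2 (not printed in the source table; exposed in config) |
| discounting | annual, costs | 3% |
| horizon | incidence model | 30 years |

Costs are payer-perspective USD (1 CNY = 0.14 USD); utilities are EQ-5D
state values (RP/RT 0.800, BCR 0.790, mHSPC 0.755, nmCRPC 0.775, mCRPC
0.726). The RP/RT states accrue monthly post-treatment ADT (312.23) plus
monitoring (3.78); BCR states accrue BCR ADT (297.81) plus monitoring; the
advanced states accrue their named treatment costs. RP (6594.70) and RT
(4550.00) are one-time charges at Markov entry. This state→cost mapping is
the package's reading of the published cost rows and is configurable.

## Accounting conventions

These conventions were fixed by requiring the engine to be internally
consistent with the full set of published outcomes; each is a documented
option, and the defaults reproduce the source analysis.

- **Tumour-free entry.** Onset hazard accrues from each man's age at model
  entry, so the baseline cohort carries no prevalent latent disease. The
  alternative (`onset_accrual="model_start"`, accrual from age 40 for all,
  detection conditioned on being undiagnosed at entry) yields a prevalent
  pool whose detection flow more than triples baseline incidence and is
  inconsistent with the published incidence level.
- **QALY scope.** Quality-adjusted survival is accumulated over
  post-diagnosis trajectories only (the decision-tree-feeding-a-Markov-cohort
  convention); undiagnosed life-years are outside the valued horizon.
  A `qaly_scope="population"` option values undiagnosed months at utility
  1.0 instead. Costs always cover the whole population (tests, genetic
  tests, treatment).
- **Prognosis horizon and clock.** Each yearly diagnosis cohort runs the
  full 360 monthly Markov cycles from its own entry, with discounting
  restarting at entry (screening costs are discounted on the calendar
  clock). The published incremental QALYs are numerically consistent only
  with *undiscounted* quality-adjusted survival combined with 3%-discounted
  costs — with 3% QALY discounting the per-entrant discounted QALY ceiling
  of the published transition matrix (~12 for an RP entrant) cannot produce
  the published per-capita QALY gains at the published incidence — so
  `EconParams` carries separate cost (0.03) and QALY (0.0) rates.
- **Mortality.** Markov Death transitions are treated as the all-cause
  mortality of diagnosed men (they were estimated from complete follow-up of
  a diagnosed cohort), so the life table is not applied on top of Markov
  states; a `competing_mortality` option stacks it for scenario analyses.
- **Outcome estimators.** Average incidence and metastatic-at-detection
  rates are pooled person-time rates over men aged 45–84 (incidence
  density). The annual case-fatality rate is prostate-cancer deaths (any
  Markov-state death by default; restrictable to metastatic states) over
  diagnosed patient-years, pooled across the horizon — with a tumour-free
  baseline cohort the first years hold only a handful of patients, and a
  mean of annual ratios would be dominated by their noise.
- **Lives gained** (harm–benefit ratios) are averted all-cause deaths
  within the horizon. In-state death attributions are retained as options
  but can go negative under heavy overdiagnosis: moving 10–20% of the
  population into the prognosis model generates more in-state deaths than
  the averted metastatic entries, even while total survival improves.
- **Risk stratification.** 33.2% of men are flagged high-risk (family
  history, top-quartile polygenic risk score, or rare pathogenic mutation
  carriage); the one-time PRS (16.81 USD) or WGS (252.00 USD) cost is
  charged to every man at model start. High-risk men share the natural
  history by default (`onset_rr = 1.0`, configurable): the source models no
  separate prognosis for them, and the stratified ICER reproduces the
  published value under this choice.

## Calibration

Two procedures recover unobservable inputs:

- **Hazard grid search**: factors 1.0–4.0 in strides of 0.2, applied as
  multipliers and divisors of `γ_o` and `γ_c` (31 distinct candidates per
  parameter, 961 pairs), minimising the mean absolute error against a
  reference age-specific incidence curve on 5-year bands over 45–84.
  The search is exhaustive and deterministic at a fixed seed; ties break
  toward the pair closest to (1, 1) on the log scale. The reference the
  source used is not available, so the shipped references are synthetic
  curves generated by the simulator itself at planted multipliers, which
  the search must recover exactly; `γ_m` and `θ_c` stay at their published
  values.
- **MCMC for PSA growth**: an affine-invariant ensemble sampler on
  `(a0, a1, a2, b, σ_ε)` under the Gaussian log-PSA change-point likelihood,
  with onset and grade treated as known (they are, in synthetic data), ages
  centred at 60 during sampling to decorrelate slope and intercept,
  weakly-informative normal priors truncated to `a2 ≥ a1 ≥ 0`, and
  split-R̂ < 1.05 reported as the convergence criterion (non-convergence
  warns, never silently passes).

## Sensitivity analysis

One-way analysis evaluates each parameter at its published bounds (0.75–1.33×
for exponential-scale parameters, 0.75–1.25× for linear ones, 95% CIs where
printed). Probabilistic analysis draws all parameters simultaneously —
uniform on the published range by default, with beta/gamma options — for a
configurable number of iterations, re-simulating the paired
strategy/baseline runs with a common cohort seed (common random numbers), so
iteration-to-iteration variation reflects the parameter draws. Acceptability
curves report the fraction of iterations with non-negative net monetary
benefit `w·ΔQ − ΔC` over a willingness-to-pay grid (0–20,000 USD/QALY, with
regional per-capita GDP thresholds from 6,738 to 26,700 USD).

## Synthetic data

`prostasim.synthetic` generates every input with known ground truth: a
census-shaped male pyramid (seventh-census band counts from age 40, mass
shifting above 60 under projection), a Gompertz life table
(`qx = 4.85·10⁻⁵·e^{0.093·age}`, matched to the Chinese male 2020 table at
ages 40/60/85), longitudinal screening-trial PSA tables drawn from the exact
natural-history model with latent labels stored alongside, and reference
incidence curves at planted multipliers. It emulates the *structure* of the
real inputs, not their full texture: no regional heterogeneity, no secular
mortality trend, integer entry ages, uniform trial entry, and perfect
visit compliance. Passing tests therefore demonstrate internal correctness
and recoverability under the model's own assumptions — not that the model
describes any particular real population.

## Numerical choices and degenerate inputs

- Event times beyond age 150 are treated as "never"; other-cause death is
  forced by age 110.
- Screening randomness (PSA noise, MRI and biopsy uniforms) is pre-drawn
  per man × calendar age (45–74), so strategies differ only through which
  visits they schedule (common random numbers); a strategy with an empty
  schedule is bit-for-bit identical to the no-screening baseline at the
  same seed.
- Individual entry months into the Markov model use stochastic rounding
  (uniform month 0–11); cohort-mode entry splits mass exactly 1/12 per
  month.
- Ties between metastasis and detection at the same instant stage the
  diagnosis as metastatic.
- Markov rows are validated at load (probabilities in [0, 1], row exits
  ≤ 1, Death absorbing); sensitivity draws that violate a row are redrawn
  with a capped retry count.

## Problem sizes

Default analyses use 500,000 simulated men for headline reproductions
(Monte-Carlo error well under the reporting precision), 10⁵ draws for
distributional checks, 2,000 trajectories for MCMC recovery, and 4,000 men
per candidate for the planted-multiplier grid search. All were chosen so the
full suite and the reproduction script each complete in minutes on one CPU.

## Known limitations

- Active surveillance, grade progression in undetected tumours, imperfect
  adherence, and PI-RADS score distributions beyond the binary ≥4 rule are
  not modelled (they are equally absent from the source analysis).
- The RT arm's published monthly death probability (0.070772) reflects a
  frail selected real-world cohort; combined with the 90/10 RP/RT split it
  makes RT entry extremely poor-prognosis, which materially shapes
  population-scope QALY accounting.
- The hazard calibration the source performed against an external incidence
  reference cannot be repeated here (the reference and the chosen
  multipliers are not printed); Table-level hazards are used as final, which
  leaves metastatic-at-detection shares somewhat below the published values
  in every scenario.
- A closed cohort of men 40+ is simulated; men younger than 40 at baseline
  never enter, so late-horizon screening ages are populated only by ageing
  of the initial cohort.
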