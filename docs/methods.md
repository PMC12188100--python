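# Methods

## Model

`t2dsim` is an individual-level, discrete-time microsimulation of type 2
diabetes (T2DM) progression with a 1-year cycle. Each simulated patient
carries demographics (age, sex), a continuous risk-factor vector (HbA1c,
BMI, systolic blood pressure, LDL, HDL, eGFR, haemoglobin, white-cell
count, heart rate), binary risk factors (micro-/macro-albuminuria,
peripheral vascular disease, atrial fibrillation, left-ventricular
hypertrophy, smoking), and a comorbidity history.

Every cycle has two levels:

1. **Health-state determination.** HbA1c < 6.5 % puts the patient in the
   combined normal-glucose-tolerance / pre-diabetes state (`NGT_PRE`);
   HbA1c ≥ 6.5 % is `T2DM`. T2DM is absorbing: once classified, a patient
   never reverts, even if a later risk-factor update were to pull HbA1c
   below the threshold. The diagnosed patient is assumed to receive
   standard-of-care treatment from the next cycle on, which is embedded in
   the post-onset equations.

2. **Events, mortality, risk-factor update.**
   - *Before onset* the patient faces three comorbidities — MI, CHF,
     stroke — via Framingham-style annual hazard equations. CHF is
     chronic (persists once it occurs); MI and stroke are acute and can
     occur at most once while in `NGT_PRE`.
   - *After onset* the patient faces eight comorbidities (CHF, IHD,
     blindness, renal failure, MI, stroke, amputation, diabetic ulcer)
     via UKPDS-OM2-style equations. CHF, IHD, blindness and renal failure
     are chronic; MI, stroke and amputation are acute with a cap of two
     occurrences each in the diabetic state (acute events from the
     pre-onset years do not count against this cap, so the lifetime
     maximum for MI/stroke is three; this is switchable). Whether the
     diabetic ulcer is once-only is not settled in the sources; the
     default treats it as a chronic once-only condition
     (`ulcer_chronic`, switchable).
   - Candidate events are evaluated in a **uniformly random order** each
     patient-year, one independent uniform draw per candidate, with the
     history updated immediately so later events in the same year condition
     on earlier ones. Chronic events are skipped once present; acute
     events are skipped at their caps.
   - **Mortality** is evaluated once per year after event resolution. In
     the diabetic state one of four mutually exclusive equations applies,
     selected by the 2×2 of (any comorbidity history) × (any new
     comorbidity this year): Gompertz-on-age hazards in event-free years
     and logistic event-year equations. Before onset, a year with a
     comorbidity uses the 1-year age/sex all-cause mortality lookup for
     that comorbidity (several same-year events combine by taking the
     maximum, switchable to a complement-product rule); an event-free year
     uses the background life-table probability with the MI/CHF/stroke
     component removed on the cumulative-hazard scale
     (`p = 1 − exp(−(H_all − c))`, floored at zero), since those causes
     are modelled explicitly.
   - **Risk factors** update at the end of the year for survivors. Each
     continuous factor follows a linear/autoregressive equation that may
     depend on the other current factors, producing correlated progression
     (e.g. BMI enters the SBP and HDL updates; albuminuria and HbA1c
     accelerate eGFR decline). Updates are simultaneous: every equation
     reads the pre-update values. Outputs are truncated to configurable
     physiologic bounds. Binary factors progress by annual-incidence
     logistic draws and are absorbing. LVH is predicted by a logistic
     equation (Bernoulli draw by default; a deterministic 0.5 threshold is
     available).

3. **Transition to diabetes.** A patient whose HbA1c lies in the
   pre-diabetes band has probability `p_jump = 0.129` per year of a sudden
   HbA1c rise of `delta_hba1c = 0.54` percentage points — replacing, not
   supplementing, the ordinary HbA1c progression equation in that year —
   which carries them over the 6.5 % threshold; the updated HbA1c
   determines next cycle's state. The band is nominally 6.0–6.4 %; the
   default closes the undefined (6.4, 6.5) gap by using [6.0, 6.5)
   (`include_gap`, switchable).

## Equation algebra

All equations are data: a functional form plus a named coefficient map,
loaded from YAML. Supported forms: exponential, Weibull (time scale =
diabetes duration) and Gompertz (time scale = age) proportional hazards,
converted to annual probabilities by integrating the hazard over the cycle
(`p = 1 − exp(−H(t, t+1))`, with `H = exp(xβ)((t+1)^ρ − t^ρ)` for Weibull
and `exp(xβ)(e^{φ(t+1)} − e^{φt})/φ` for Gompertz); logistic regressions;
linear/autoregressive updates; and age/sex lookup tables. Predictors may
be centred, scaled, hinged or thresholded before multiplication.
Hazard-to-probability conversion is verified against numerical quadrature
to 1e-8 relative error in the test suite.

## Parameter provenance — synthetic reference values

The shipped default parameterisation (`data/default_model.yaml`) is
**synthetic**: the structure (forms, predictor sets, selector logic,
two-layer design) follows the published modelling tradition for this
disease area, but coefficient values were set by this package, not
transcribed from source publications. Intercepts were calibrated
analytically so that, at a reference covariate profile (age 60, HbA1c 7 %,
SBP 135 mmHg, BMI 30, LDL 3.0, HDL 1.2, eGFR 80), first-year event
probabilities and the resulting 20-year cumulative incidences fall in
epidemiologically plausible ranges for a newly diagnosed diabetic cohort
(roughly: MI ≈ 25–35 %, stroke ≈ 15 %, CHF ≈ 20 %, renal failure ≈ 8 %,
death ≈ 40–50 % over 20 years). Slope coefficients use conventional
magnitudes (e.g. ≈ 0.04–0.08 per year of age on the log-hazard scale).
The same applies to the life tables, case-fatality tables, cost table
(CAD 2022), utility table, intervention effect profile and PSA priors.
Exceptions — values the model states directly and which are used verbatim:
`p_jump = 0.129`, `delta_hba1c = 0.54`, the 6.5 % threshold and 6.0–6.4 %
band, 50 % programme compliance, 1.5 % annual discounting, a CAD 30,000
willingness-to-pay, 5,100-patient study cohorts, and validation years
5/10/15/20. Replacing the YAML with literature-transcribed values changes
the numbers, not the mechanics; every test of mechanism is independent of
the shipped values.

The packaged external-validation reference
(`data/observed_dppos_t2dm_synthetic.csv`) is likewise a synthetic
reconstruction of a 15-year prevention-trial incidence curve (anchored to
≈ 55–62 % cumulative incidence at year 15), standing in for observed trial
data.

## Cohorts

Baseline characteristics are drawn independently per patient from
configured marginals (normal, lognormal, Bernoulli, categorical, fixed;
truncation by inverse-CDF restriction, so no rejection loops). An optional
Gaussian copula couples chosen continuous characteristics with a
configured correlation matrix while preserving the marginals; the default
is independent draws, with correlation emerging over time through the
progression equations. Three cohorts ship:

* `uk_t2dm_like` — newly diagnosed diabetic cohort (mean age 52.5,
  39 % female, HbA1c truncated to ≥ 6.5 so every patient classifies T2DM);
* `dppos_like` — prediabetic prevention-trial cohort (mean age 50.6, 68 %
  female, BMI 34, HbA1c 5.91 ± 0.50 truncated below 6.5); characteristics
  not typically reported for such trials fall back to the `uk_t2dm_like`
  values;
* `toy` — small deterministic mixed cohort for tests.

## Randomness and reproducibility

All draws come from keyed counter-based substreams: a 64-bit key per
patient id derived from the master seed, mixed with (purpose, year, slot)
counters through the SplitMix64 finaliser. Consequences, all tested:
cohorts are bit-reproducible and extension-stable (adding patients never
perturbs existing ones); simulating a patient alone or inside any
permutation of a cohort gives identical results; two arms sharing a master
seed share patient-level randomness (common random numbers), so a null
intervention yields exactly zero incremental outcomes and incremental
estimates have strongly reduced Monte-Carlo variance. Event ordering uses
an argsort of per-event uniforms (a uniform random permutation); each
candidate event consumes one uniform addressed by its identity, which is
distributionally identical to drawing in permutation order and keeps the
stream layout order-independent.

## Intervention overlay

The prevention programme is modelled on an intensive lifestyle
intervention: per-programme-year additive shifts to the BMI and HbA1c
update outputs (year-1 shifts of −2.0 kg/m² and −0.10 points with partial
regain thereafter), a multiplicative reduction of the jump probability
(default multiplier 0.55 over a 10-year programme), 50 % compliance, and a
per-year programme cost schedule. Effects apply to compliant patients who
have not yet developed diabetes; post-onset equations are never modified
directly, so any post-onset benefit flows through the altered risk-factor
paths. Costing is intention-to-treat by default (every intervention-arm
patient alive in a programme year is charged; `cost_compliers_only`
switches this). In the external-validation harness compliance is set to
1.0, reflecting trial conditions; the 50 % rate applies to the real-world
case study.

## Economics

Costs (CAD 2022) accrue as a state background cost plus comorbidity costs:
acute events carry an event-year cost, chronic conditions an annual cost in
every year present (the onset year charges the event cost only);
pre-diabetes comorbidity costs are the diabetic-state costs times
condition-specific ratios. Utilities are age/sex baseline weights minus a
diabetes decrement and condition decrements (event-year for acute events;
persistent for histories and chronic conditions), floored at zero with a
logged warning. Years are whole cycles: the death year accrues in full and
no half-cycle correction is applied. Discounting is `1/(1+r)^t` with
cycle 0 undiscounted (the alternative start-at-year-1 convention is a
one-line change in `discount`). Incremental results are computed pairwise
per PSA iteration; INMB = λ·ΔQALY − ΔCost holds exactly per iteration, and
uncertainty intervals are 2.5/97.5 percentiles over iterations. Event
rates are first-occurrence counts per 100,000 person-years at risk, with
at-risk time ending at the first occurrence, death, or the horizon.

## Probabilistic sensitivity analysis

The cohort is generated once and reused across all iterations, so
parameter uncertainty is cleanly separated from sampling uncertainty.
Priors are configured per scalar by dotted path: beta for probabilities,
gamma (mean-preserving, chosen coefficient of variation) for costs and
decrements, normal for equation intercepts, with optional joint
multivariate-normal blocks for correlated coefficients. Invalid draws are
rejected and retried a bounded number of times. Iteration `d` uses a
simulation seed derived from (master seed, d), so any subset of iterations
is independently reproducible and results do not depend on execution
order.

## Validation harnesses

*Internal*: a 5,100-patient newly diagnosed cohort is simulated for 20
years; PSA-mean Kaplan–Meier cumulative failure for each comorbidity and
death at years 5/10/15/20 is regressed (OLS, t-based 95 % CIs) on
reference values, pooled and split into microvascular (blindness, renal
failure, amputation, ulcer) and macrovascular (CHF, IHD, MI, stroke)
subsets, with the mean absolute difference reported in percentage points.
Because no trial-observed reference values ship with the package, the
default reference is generated by the model itself at the point-estimate
parameters with an independent seed; internal validation therefore
measures PSA-mean-versus-point-estimate self-consistency (a near-identity
calibration is the expected result, and deviations flag prior asymmetry or
nonlinearity). Passing it does **not** demonstrate agreement with trial
data; supply `observed_curves` to validate against real references.

*External*: a 5,100-patient prediabetic cohort is simulated for 15 years
under placebo and under the intervention; annual cumulative diabetes
incidence is compared with the packaged reference curves via per-year and
average simulated-to-observed ratios (1 = perfect alignment).

The Kaplan–Meier estimator operates on the discrete annual grid: events in
cycle `t` are timed at `t+1`; death (for non-mortality endpoints) and the
horizon censor; an event tied with censoring in the same year counts as an
event. The estimator is verified exhaustively against a brute-force
product-limit oracle on small cohorts and cross-checked against lifelines.

## What the synthetic generator does and does not emulate

It reproduces the structural features the method needs — two health
states, heterogeneous correlated risk factors, state-dependent event and
mortality processes, caps and chronic persistence, intervention effects on
modifiable factors — with realistic marginal distributions. It does not
emulate baseline correlation between characteristics (unless configured),
measurement error, secular treatment trends, sub-annual event timing,
competing-risk timing within a year, or diagnosis delay. Green tests
therefore demonstrate correctness of the machinery and internal
consistency of the statistics, not predictive validity on real
populations.

## Numerical and design choices

* Probabilities are computed with `expm1/log1p` guards and clipped to
  [0, 1]; hazards are nonnegative by construction.
* Risk-factor truncation bounds keep downstream equations in-domain;
  values at the bounds are clamped, not resampled.
* Problem sizes in the shipped harnesses (5,100 patients; 100 PSA
  iterations in the acceptance script; 1,000 by default in config) were
  chosen so the full pipeline runs comfortably on a single core while
  keeping Monte-Carlo error small relative to the quantities reported.
* The per-patient API (`simulate_year`, `simulate_patient`) delegates to
  the vectorised cohort engine with a cohort of one, so there is a single
  code path to trust.

## Known limitations

* All quantitative outputs depend on the synthetic parameterisation; they
  are internally consistent but not estimates for any real population.
* The pre-onset layer models only three comorbidities and no
  renal/ophthalmic progression before diagnosis.
* No treatment modelling beyond the standard-of-care assumption embedded
  in the post-onset equations; no diagnosis delay.
* Single-year cycles make event ordering within a year a modelling device
  rather than a timing claim.
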