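# Methods

## Estimand and procedure

The package estimates per-protocol effects of dynamic cholesterol-lowering
regimes by the parametric g-formula on a one-year discrete grid. Time is
years since each participant's own baseline, 0-based; an event during
`[k, k+1)` is recorded at index `k`. The estimand is the **total effect**:
competing events (non-CVD deaths) reduce the outcome's cumulative incidence
and are never treated as censoring, because eliminating them would define an
unrealistic counterfactual. Within every one-year interval the outcome hazard
acts first and the competing hazard applies to the outcome-free; this
ordering is declared once and shared between the estimator and the synthetic
generator's oracle, so both target the identical quantity. The identifying
assumptions are the usual ones — no unmeasured confounding given the modelled
history, positivity, consistency and correct model specification; the
natural-course diagnostic (maximum absolute gap between the nonparametric
discrete cumulative incidence of the fitting data and the simulated
natural-course curve) probes the last of these.

## Model specification

Each time-varying covariate is modelled in the declared order smoking → BMI →
SBP → DBP → TG (log scale) → HDL-C → non-HDL-C → LDL-C → glucose → diabetes →
antihypertensive use → lipid-lowering use. The history summary is Markov
order 1: intercept, baseline age and sex, the lag-1 value of every
time-varying covariate, current-year values of covariates earlier in the
order, and `k, k², k³`. The lag of a log-scale covariate enters both raw and
log-transformed so that models linear on either scale are nested. Binary
covariates use pooled logistic regression; diabetes, antihypertensive use and
lipid-lowering use are absorbing, with their transition models fitted only on
person-years where the state was previously absent. Hazard models are pooled
logistic with cubic time. Under the default `concurrent` exposure ordering
the hazards use current-year covariates (interventions act within the year);
the `lagged` sensitivity ordering replaces them with lag-1 values, delaying
intervention effects by one interval, which attenuates estimates toward the
null when true effects are immediate. Risk stratum is recomputed
deterministically from covariates each simulated year rather than modelled.

Continuous simulation draws are truncated to each covariate's observed
range in the fitting data; triggered truncations are counted on the trace.
LDL-C is additionally capped at non-HDL-C and `TC = non-HDL-C + HDL-C` is
maintained as an identity. At `k = 0` the lag-1 value is defined as the
baseline value itself.

## Regimes

Treat-to-target eligibility is re-evaluated every year with an OR trigger
(either lipid fraction at/above its bound); assignment draws each lipid
uniformly on `[0.5 × bound, bound)` — the protocol states only the upper
bound, so the lower bound is a configurable convention (`lb_fraction`,
default 0.5) that keeps assignments positive and below target. Assigned
values never exceed current values and never violate non-HDL-C ≥ LDL-C. The
stop rule is implemented as per-year ineligibility while below target; drift
back above a bound triggers re-intervention. The 50%-reduction rule for
high-risk diabetics references the wave-0 (study baseline) LDL-C. Feasible
adherence is drawn independently per eligible person-year (a per-person mode
is available). Treat-to-target interventions also set the lipid-lowering
medication flag; the static reduction is a pure lipid displacement with a
0.5 mmol/L floor and leaves the flag alone. Adherence draws come from a
dedicated random stream, so all regimes run under common random numbers and
a regime that never intervenes reproduces the natural course bit for bit.

The default 10-year risk scorer is a documented monotone point table on age
band (sex-specific), total-cholesterol band, HDL-C band, smoking and
hypertension (SBP ≥ 140 or DBP ≥ 90 mmHg or treated); the guideline's exact
published point system is deliberately not reproduced, and the table is
swappable from YAML. Step-2 category boundaries are `[5%, 10%)` for
intermediate and `≥ 10%` for high (inclusive at 10%).

## Estimands and inference

RMET uses the right-endpoint rule `horizon − Σ_{t≤horizon} R(t)` on the
outcome's cumulative incidence (area above the CIF). With competing risks
this is one of two defensible readings — the alternative, overall event-free
time, uses `R + competing` and can be computed from the same curves. NNT is
computed from unrounded RMETs and ceiling-rounded (with a 1e-9 float guard)
only at presentation; a zero RMET difference renders as "undefined", never a
number; negative values are numbers needed to harm with sign preserved
internally. Because "participants who would have to receive the
intervention" is ambiguous between person-time and ever-treated readings,
both are reported: intervened person-years / event-free person-years
(survival-weighted) and the share of pseudo-individuals ever intervened.
Bootstrap CIs resample participants (whole histories — the exchangeable
unit), re-run fitting and simulation per replicate with deterministic
derived seeds, and take 2.5/97.5 percentiles; replicates whose models fail
are dropped and counted, and more than 10% failures aborts the run.

## The synthetic generator

The generator emulates the *shape* of a long community cohort: baseline
moments matching the study population at wave 0 (age 46.6 (SD 7.7) years,
61% women, LDL-C 2.7 (0.8) mmol/L, non-HDL-C ≈ 3.3 mmol/L, 24% smokers, 2%
diabetes, 1.4% on lipid-lowering drugs), sparse examination waves (default
years 0/10/15/20) with covariates unobserved between waves, rising lipid,
glucose, blood-pressure and medication trajectories, and annual discrete
hazards producing 29-year cumulative incidences of about 0.25 (primary
event) and 0.29 (all-cause death), inside the targeted 0.15–0.30 band.
Continuous covariates are Gaussian AR(1) around linearly trending means
(TG log-normal); binary states are absorbing or near-absorbing logistic
transitions driven by current glucose, SBP and LDL-C; being on
lipid-lowering treatment shifts the next year's non-HDL-C by −0.5 mmol/L.
LDL-C obeys `LDL = non-HDL − TG/2.2 − gap` with the remnant gap an AR(1) in
observed lagged lipids, keeping the lipid identities internally consistent
and the structural equation linear in observables (hence inside the
estimator's model class) even under intervention.

Several generator parameters are free — the source study reports no
observed-data law beyond baseline moments — and were fixed once for
testability: the non-HDL-C dynamics use weak year-to-year tracking (ρ = 0.2,
innovation SD 0.8 mmol/L) so that intervention effects do not compound
toward physiologic floors, and natural lipid-drug uptake is substantial
(≈25% by year 10, more than the study's mid-study waves show) so the drug
coefficient and the lipid hazard coefficients are well identified at n ≈
5,000. These choices trade some longitudinal realism for sharp
identifiability; wave-0 moments are unaffected. The log-odds of the primary
event increase by 0.30 per mmol/L LDL-C (hazard also on age, sex, smoking,
SBP, diabetes); competing death is lipid-independent. A negative-control
parameterisation makes the primary event "cancer death" with exactly zero
lipid coefficients.

What the generator does **not** emulate: loss to follow-up (censoring is
administrative at 29 years only), baseline cross-correlations between risk
factors (baseline covariates are drawn independently apart from the lipid
identities), measurement error, within-person seasonal variation, regional
sub-cohorts, or event adjudication. Passing tests therefore show that the
estimator recovers the truth when its assumptions hold and degrade sensibly
when they are broken — not that any real cohort satisfies those assumptions.
With the default sparse waves, last-observation-carried-forward covariates
are stale proxies of the current values driving the hazard, so fitted lipid
coefficients and estimated effects attenuate relative to the annually
observed case; this mirrors the measurement reality of the emulated design
and is visible in the headline run of `scripts/acceptance.py`.

## Numerical and testing choices

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`, fanned out to independent streams for the
generator, baseline resampling, covariate innovations, regime draws and
bootstrap replicates; RNG consumption per stream is fixed per year
regardless of regime, which is what makes common-random-number comparisons
and the exact null-regime identity possible. Model fits go through
statsmodels GLM/OLS; non-convergence, separation with non-finite
coefficients, constant covariates and zero-event outcomes raise a
`ModelFitError` naming the model. The eligibility boundaries are age ≥ 35
(inclusive) and TG < 4.52 mmol/L (exclusive); BMI 24.0 falls in the ≥ 24
subgroup arm.

Validation uses deliberately scaled problems: recovery of the known
counterfactual risk runs at n = 5,000 participants with annual examinations
and 10,000 Monte Carlo individuals (the annually observed variant is the
correctly specified case; sparse waves + LOCF are exercised separately);
the adherence-ordering check runs at n = 2,500 with 3,000 Monte Carlo
individuals; the negative control uses 700 participants and 50 bootstrap
replicates; the bootstrap coverage experiment uses 20 replications of a
300-participant, 12-year, all-cause configuration. Exact checks (eligibility
counts, event-tree enumeration at ≤ 5 intervals, RMET/NNT algebra,
byte-level determinism) carry tolerances of 1e-12 or none.

## Known limitations

The doubly-robust / ICE estimator and the guideline's exact point scores are
out of scope. The time-zero convention simulates from baseline with
interventions initiating whenever conditions are met; aligning time zero at
first initiation per participant is a documented alternative that is not
implemented. The all-cause mortality outcome treats the generator's primary
event as fatal. Pooled logistic hazards approximate continuous-time hazards
only while per-year risks are small. Bootstrap percentile intervals carry no
small-sample correction (no BCa), and subgroup analyses are not adjusted for
simultaneous inference.
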