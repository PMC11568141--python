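# lipidgf

Parametric g-formula pipeline for emulating a target trial of **risk-based,
treat-to-target cholesterol-lowering interventions** on longitudinal cohort
data with discrete-time competing risks.

## The problem

Guidelines recommend lowering LDL-C / non-HDL-C to stratum-specific targets
that depend on each person's evolving cardiovascular risk. Estimating the
long-term effect of *sustained adherence* to such a dynamic rule from an
observational cohort is hard: cholesterol levels, risk stratum and treatment
feed back on one another over time, so standard regression adjustment is
biased (time-varying confounding affected by prior treatment). The parametric
g-formula handles this by modelling the joint evolution of the confounders
and the event hazards, then standardising over Monte Carlo simulations of the
cohort under each hypothetical intervention.

This package is aimed at epidemiologists and biostatisticians who want a
tested, reproducible implementation of that analysis — together with a fully
synthetic longitudinal cohort whose counterfactual truth is *known*, so every
stage can be validated without access to private cohort data.

## The method

For person-years `k = 0..28` with covariates `L_k`, intervention state `A_k`,
outcome indicator `Y_k` and competing event `C_k` (non-CVD death):

1. **Step 1 — pooled models.** One regression per time-varying covariate, in
   a declared order (lifestyle → metabolic → glycaemic → medications), each
   on baseline covariates, all lag-1 covariates, earlier-in-order current
   covariates and cubic time; pooled logistic discrete-time hazard models for
   `Y_k` and `C_k` (fitted among the outcome-free).
2. **Step 2 — Monte Carlo standardisation.** Resample baselines with
   replacement, draw covariates forward year by year from the fitted models,
   and apply the intervention rule whenever its conditions are met.
3. **Step 3 — competing-risk cumulative incidence** (total effects; competing
   events are never censored):

   `R(t) = E[ Σ_{k≤t} h_Y(k) Π_{j<k} (1−h_Y(j))(1−h_C(j)) ]`

4. **Step 4 — estimands and inference.** 29-year risk, risk difference and
   risk ratio versus the natural course, the restricted mean event-free time
   `RMET = Σ_{t≤29} (1 − R(t))`, the RMET-based number needed to treat
   `NNT = RMET_nat / (RMET_int − RMET_nat)`, the average % of person-years
   intervened, and percentile bootstrap CIs over participants.

Regimes: **natural course** (no intervention); **treat-to-target** (when
LDL-C or non-HDL-C is at/above its stratum-specific bound, assign a level
drawn uniformly below the bound; bounds 1.8/2.6 mmol/L for high-risk
diabetics — or half the baseline LDL-C if lower — 2.6/3.4 for
intermediate-to-high, 3.4/4.2 for low risk; the rule re-evaluates every year
and stops while targets are met); **feasible** treat-to-target (each eligible
person-year intervened with probability 0.8, or a 20–70% sweep); **static
1 mmol/L reduction** (positive control). Risk strata come from a 3-step
guideline procedure (direct high-risk criteria, a pluggable monotone 10-year
score, and a lifetime-risk upgrade under age 55).

## Worked example

```python
import lipidgf as lg

params = lg.DGPParams(n_participants=2000, seed=42)   # synthetic cohort
waves = lg.generate_cohort(params)                    # sparse waves 0/10/15/20
eligible, tally = lg.apply_eligibility(waves)
pp = lg.locf_fill(lg.expand_person_periods(eligible), eligible)
fitted = lg.fit_all(pp)

regimes = [lg.natural_course(), lg.treat_to_target(), lg.feasible(0.8)]
curves, traces = lg.estimands.simulate_regimes(fitted, regimes, n_mc=10_000, seed=7)
table = lg.EstimandTable(lg.estimands.table_from_results(curves, traces, horizon=29))
print(table.formatted().to_string(index=False, float_format=lambda v: f"{v:.2f}"))

diag = lg.natural_course_diagnostic(pp, fitted, n_mc=10_000, seed=7)
print(f"natural-course diagnostic gap: {100 * diag.max_abs_gap:.2f} pp")
```

which prints

```
         regime  risk_pct  rd_pct   rr  rmet_years       nnt  pct_py_intervened  pct_ever_intervened
 natural_course     26.27    0.00 1.00       26.09 undefined               0.00                 0.00
treat_to_target     21.28   -4.99 0.81       26.66        46              12.38                97.40
    feasible_80     21.40   -4.87 0.81       26.64        48              11.36                96.81
natural-course diagnostic gap: 0.39 pp
```

Read: under no intervention 26.3% of this synthetic cohort develops the
primary event within 29 years; full adherence to the treat-to-target rule
lowers that by 5.0 percentage points (risk ratio 0.81), buying 0.57 years of
event-free time on average, so treating 46 people for 29 years prevents one
event; 12% of event-free person-years carry an active intervention. The
diagnostic gap (0.39 pp between the observed and the simulated natural-course
risk curve) indicates the fitted models reproduce the observed cohort well.

The same analysis is scriptable from the shell:

```bash
lipidgf run-all --outdir runs/demo            # default config
lipidgf bootstrap --outdir runs/ci --n-boot 500
```

Every run directory contains a `manifest.yaml` that reproduces the run
exactly; all randomness is governed by explicit seeds.

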