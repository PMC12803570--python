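# t2dsim

Patient-level microsimulation of cardiovascular outcomes in type 2 diabetes,
plus the external-validation battery used to judge such models against
cardiovascular outcome trial (CVOT) data.

`t2dsim` is aimed at health-economic modellers and trial statisticians who
need to (a) run a discrete-time illness–death outcomes model over a trial
cohort and (b) quantify how well its simulated event rates match what the
trial observed.

## What it implements

**Simulation engine.** A probabilistic, discrete-time illness–death model.
Each participant is advanced in annual cycles over the trial's median
follow-up; within a cycle, the configured event and death equations are
evaluated in a uniformly random order, each firing with its annual
probability from an independent uniform draw. For a hazard-form equation
with linear predictor $\eta = \beta_0 + \sum_j \beta_j x_j$ the cycle
probability is

$$p = 1 - \exp\!\left(-e^{\eta'} \int_{t}^{t+c} \lambda_0(u)\,du\right),$$

with exponential, Weibull or Gompertz baselines $\lambda_0$ integrated
exactly over the cycle (a fractional final cycle, e.g. the 0.2 years left of
a 3.2-year horizon, enters through the integration limits). A death
truncates the cycle; fired events enter the covariate state for later
cycles. Risk factors advance from observed annualized measurements when
available, otherwise via linear autoregressive progression equations.
Equation coefficients are supplied as JSON (see
`src/t2dsim/data/coefficients.schema.json`); the shipped set is synthetic
and clearly labelled — it is **not** the published coefficient values of any
real model.

**Cohort handling.** CSV ingestion (one row per participant-year), the
prior-event convention that all historical events occurred one year before
baseline, and the missing-data policy common in this setting:
age/sex-adjusted mean substitution for low-missingness factors (HbA1c,
systolic BP, weight, heart rate, eGFR), stratified imputation for factors
missing not at random (HDL, LDL, haemoglobin), out-of-range values treated
as missing, and progression-equation fill-in of missing annual follow-up.
Ischemic heart disease and heart failure are modelled as first events only:
participants with the prior event are excluded from those endpoints'
numerators and denominators.

**Validation metrics.** Observed vs simulated counts and proportions with
the between-arm relative risk (ratio of cumulative incidences, active over
placebo), the unadjusted Cox hazard ratio (Efron ties, Wald CI),
Kaplan–Meier cumulative incidence, the Brier score at the horizon,
calibration intercept and slope (logistic recalibration; intercept fitted
with the slope fixed at 1), and Harrell's C. Slope 1 / intercept 0 denote
perfect calibration; a negative intercept means overestimation; Brier
< 0.25 is conventionally "informative".

**Synthetic trial cohorts.** Generators for CVOT-like cohorts with known
ground truth: two built-in profiles mimic the published shape of a
sitagliptin safety trial (14 671 participants, all with ASCVD, median
follow-up 3.0 years) and an exenatide outcomes trial (14 752, 73.1% ASCVD,
median 3.2 years), including the published missing-data frequencies (HDL
19.8%, LDL 25.6%, haemoglobin 39.7%, missing not at random).

## Worked example

Self-validation: generate a two-arm cohort of 2 000, let the *same*
coefficient set play both the data-generating truth (one replication) and
the simulation model (200 replications), then validate:

```python
from t2dsim import *
from t2dsim.synthetic import tecos_profile

eqs = illustrative_coefficients()
cohort = generate_cohort(tecos_profile(1000, 1000), seed=7)
cohort = impute_mean_substitution(cohort)
cohort = impute_stratified(cohort, seed=8)
cohort = generate_followup_trajectories(cohort, eqs, noise_sd=0.1, seed=9,
                                        years=3, gap_rate=0.3)
cohort = fill_followup(cohort, eqs, 3.0)

observed = generate_outcomes_from_engine(cohort, eqs, 3.0, seed=10)
simulated = simulate_cohort(cohort, eqs, 3.0, replications=200, seed=11)
print(first_event_summary(simulated, "mace3"))
report = build_validation_report(observed, simulated,
                                 endpoints=["mace3"], subgroups=None)
r = report.endpoints["mace3"]
print(f"RR={r.rr:.2f}  Brier={r.brier:.3f}  C={r.c_statistic:.2f}  "
      f"slope={r.calibration.slope:.2f}  intercept={r.calibration.intercept:.2f}")
```

prints

```
         expected_events  denominator  proportion
arm
active           127.530         1000    0.127530
placebo          128.255         1000    0.128255
RR=0.99  Brier=0.092  C=0.68  slope=1.09  intercept=-0.18
```

The simulated 3-point MACE proportions are ~12.8% in both arms (RR 0.99 —
the engine applies identical equations to both arms, so any departure from
1.00 is Monte-Carlo and covariate-sampling noise), the Brier score is well
inside the informative range, and calibration slope/intercept are within
sampling error of their ideal values of 1 and 0, as they must be when the
generating and simulating models coincide. At this n the observed arm
difference (11.7% vs 10.2%) is pure sampling noise, which the wide HR
interval (0.88–1.50) reflects.

The same pipeline is available from the shell:

```bash
t2dsim synth --profile tecos --seed 7 --out cohort.csv
t2dsim impute --cohort cohort.csv --horizon 3.0 --out imputed.csv
t2dsim simulate --cohort imputed.csv --horizon 3.0 --reps 200 --seed 42 --out sim/
t2dsim validate --observed observed.csv --simulated sim/ --out report/
t2dsim all --config config.json     # everything, reproducibly, from one file
```

## Layout

```
src/t2dsim/
  cohort.py      ingestion, limits, imputation policies
  equations.py   equation specs, annual probabilities, coefficient JSON I/O
  engine.py      the illness-death microsimulation
  metrics.py     RR/HR, KM, Brier, calibration, Harrell's C, report assembly
  synthetic.py   cohort/outcome/trajectory generators with ground truth
  pipeline.py    end-to-end orchestration (deterministic per config)
  cli.py         `t2dsim` command-line verbs
docs/methods.md  modelling and statistical conventions, in detail
```
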