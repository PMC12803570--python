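# Methods

This note records the modelling and statistical conventions the package
implements, the choices made where more than one reasonable convention
exists, and what the synthetic-data experiments do and do not demonstrate.

## The simulation model

The engine is a probabilistic, discrete-time illness–death microsimulation.
State per participant and replication: alive/dead, a vector of continuous
and boolean risk factors (weight, smoking, HDL- and LDL-cholesterol,
systolic blood pressure, HbA1c, heart rate, white cell count, haemoglobin,
eGFR, atrial fibrillation, peripheral arterial disease, albuminuria),
demographics (age, sex, diabetes duration, height), and a history flag per
clinical event category (ischemic heart disease, heart failure, amputation,
blindness, kidney failure, MI, stroke, foot ulcer).

Each annual cycle:

1. Every applicable event/death equation is assigned an independent
   Uniform(0,1) *position*; equations are visited in position order — a
   fresh uniformly random permutation every cycle.
2. Each visited equation fires if an independent uniform draw falls below
   its cycle probability (below).
3. A death — a death equation, or an MI/stroke resolved as fatal by the
   equation's case-fatality probability — truncates the cycle: equations
   positioned later do not fire. Nonfatal events positioned earlier stand.
   The random order makes this truncation rule unbiased on average.
4. Fired events update the history flags *for subsequent cycles*; within
   the firing cycle they act only through the truncation rule. This keeps
   each cycle's hazard matrix a function of the start-of-cycle state, which
   both matches the annual-cycle interpretation and allows the per-cycle
   computation to be vectorized across replications.
5. Risk factors advance to the next year: observed annualized measurements
   are used when present and in range, otherwise the progression equations,
   clamped to the model limits.

### Cycle probabilities

Event/death equations are proportional-hazards forms with exponential,
Weibull or Gompertz baselines, or logistic. With linear predictor `lp` and
cycle `[t0, t0+c]` on the diabetes-duration timescale:

- exponential: `H = exp(lp) * c`
- Weibull (shape g): `H = exp(lp) * ((t0+c)^g - t0^g)`
- Gompertz (shape g): `H = exp(lp) * (exp(g*(t0+c)) - exp(g*t0)) / g`
- probability `p = 1 - exp(-H)`; logistic: `p_c = 1 - (1-p)^c` with
  `p = expit(lp)`.

The baseline is integrated exactly, so survival composes: simulating two
half-cycles equals one full cycle for any of the hazard forms (a unit
test asserts this to 1e-12). A fractional horizon (e.g. 3.2 years) is one
partial cycle with `c < 1`; this is the natural extension of an
annual-cycle model to the non-integer median follow-up of a trial, which
the model's description leaves open.

### Endpoints and composites

Equation names `mi`, `stroke`, `ihd`, `heart_failure`, `cv_death`,
`noncv_death` are canonical. Derived per replication: `cv_death` (the CV
death equation, or a fatal MI/stroke), `all_cause_death`, `mace3 = CV death
∨ MI ∨ stroke`, and `mace4 = mace3 ∨ unstable-angina proxy`. The model
described has no dedicated unstable-angina equation, so MACE-4 uses a
configurable proxy: each IHD event registers a hospitalization for unstable
angina with probability `ua_proxy_share` (default 0, i.e. MACE-4 = MACE-3).
This is a documented limitation, not a claim about how any published
analysis produced its 4-point composite.

IHD and heart failure are first-event-only: participants with the prior
event cannot fire those equations and are excluded from the endpoint's
numerator *and* denominator in summaries (the restriction the trial tables
footnote as "in those without prior heart failure").

### Randomness and reproducibility

One substream per participant, keyed by `(seed, crc32(id))`; all
replications for a participant are drawn jointly from that substream,
vectorized. Results are therefore deterministic given the seed and
independent of cohort ordering. The default replication count is 200; the
inner-loop count of the real model's published applications is not stated,
and 200 makes the replication-frequency risk estimate's binomial noise
small relative to the event probabilities of interest.

## Cohort policies

- **Prior events** are entered as having occurred exactly 1 year before
  baseline (trial case-report forms did not record event dates).
- **Mean substitution** (HbA1c, systolic BP, weight, heart rate, eGFR —
  the low-missingness factors): missing or out-of-range baseline values are
  replaced by the mean of valid values from participants of the same sex
  and age band (<55, 55–64, 65–74, ≥75; configurable — the adjustment
  granularity is a package choice), falling back to the whole-study mean,
  then to a configured population average.
- **Stratified imputation** (HDL, LDL, haemoglobin — missing not at
  random): draws from the empirical distribution (or mean) of observed
  values within sex × age band × prior-CV-event strata, with a fallback
  chain dropping prior-CV status, then age band, then sex. Deterministic
  given the seed; every imputed cell is flagged. The strata are a package
  choice; the method name alone does not pin them down.
- **Out-of-range values** are treated as missing and re-imputed (replaced,
  not clamped). The admissible ranges ship as an editable default table
  (e.g. HbA1c 4–15%); the real model's prespecified limits are not printed
  and can be supplied via config.
- **Follow-up fill-in** runs forward from the *last observed* value, so an
  observed mid-trial measurement anchors all later imputed years. Boolean
  factors are carried forward (last observation carried forward) — whether
  the original analyses imputed these at all is unstated, so the package
  does the conservative thing and flags the cells.

## Validation conventions

- **Relative risk** = (active events / active n) / (placebo events /
  placebo n), rounded half-up to 2 decimals; proportions half-up to 0.1%.
  These match the granularity of published trial tables, and the worked
  examples in the acceptance tests reproduce the printed values exactly.
- **Hazard ratio**: unadjusted Cox arm effect, Efron ties, Wald 95% CI
  (via lifelines; tests cross-check a no-ties instance against independent
  maximization of a hand-coded partial likelihood).
- **Predicted risk per participant** = frequency of the event across
  engine replications. How the original analyses computed patient-level
  risks is unstated; the replication frequency is the natural estimate a
  probabilistic model exposes.
- **Brier score and calibration** are computed at the fixed horizon on
  participants who either had the event by the horizon or were followed to
  it; earlier-censored participants are excluded (IPCW weighting is a
  possible extension, not implemented). Calibration slope is the
  coefficient of logit(pred) in a logistic regression of the outcome;
  the intercept is refitted with logit(pred) as a fixed offset (slope
  pinned at 1) — the standard recalibration framework. Predictions are
  clipped to [1e-6, 1-1e-6] before the logit.
- **Harrell's C** uses censoring-comparable pairs (the shorter time must
  be an event), ties in risk count 1/2 (via lifelines'
  `concordance_index`; tests cross-check exhaustive pair enumeration).
- Degenerate inputs (no placebo events, constant predictions, no
  comparable pairs, separation in the Cox fit) yield flagged/NaN results
  rather than exceptions wherever a report should still be producible.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *published shape* of two CVOT cohorts: arm
sizes (7332/7339 and 7356/7396), ASCVD prevalence (100% and 73.1%),
median follow-up (3.0 and 3.2 years) via uniform censoring over the
printed interquartile ranges (2.3–3.8, 2.2–4.4), and the stated
missing-data frequencies (HDL 19.8%, LDL 25.6%, haemoglobin 39.7%).
Missing-not-at-random cells use a logistic link on the standardized factor
value (slope −0.7: lower values more likely missing) with the intercept
solved at generation time so the marginal rate equals the configured one —
which is what makes the configured rates empirically recoverable.

Baseline marginals (normal/lognormal with plausible type 2 diabetes
parameters, e.g. HbA1c lognormal around 7.3%, correlated through a
Gaussian copula with modest cardiometabolic correlations) are
*illustrative by design*: the trials' actual baseline tables are not
reproduced here, and no test or acceptance quantity depends on the
specific marginal parameters. Passing the synthetic-data tests therefore
shows the pipeline's internal consistency and statistical correctness —
not that the shipped coefficient set would reproduce any real trial's
event rates. Real-data use requires the published coefficient values,
supplied as JSON.

Outcome generation has two routes. The parametric route draws event times
per endpoint by inverse-CDF from a single hazard equation (endpoints
independent, no competing risk), with a multiplicative arm hazard ratio —
used for parameter-recovery experiments (a true HR of 0.9 at full trial
scale is recovered within sampling error). The engine route runs the
simulation engine itself at one replication with a disjoint seed, so the
generating model *is* the simulation model with all its linkage and
competing mortality — used for the master self-validation experiment.

## The self-validation experiment

With generating model = simulation model and a null arm effect at
5 000 participants per arm, the pipeline must report: simulated RR within
[0.97, 1.03], calibration slope within 3 SE of 1, intercept within 3 SE of
0, Brier < 0.25, and simulated proportions within binomial error of
observed. One numerical subtlety: the replication frequency is an unbiased
but noisy estimate of a participant's model risk, and noise in a
regressor attenuates a regression slope — by the factor
`Var(logit p) / (Var(logit p) + 1/(R·p·(1-p)))` to first order. The
experiment therefore uses R = 600 replications, at which the attenuation
(~2%) is well inside the slope's sampling error at this n; the engine
default of 200 is fine for rate estimation but would bias this particular
slope check by roughly 5–10%.

Problem sizes used by the checked experiments: the analytic anchor runs
one participant × 20 000 replications against `1 − exp(−hT)`; the
self-validation runs 10 000 participants × 600 replications over 3 annual
cycles; missingness and HR-recovery checks run at the full published
cohort sizes (14 671 / 14 752).

## Known limitations

- Lifetime extrapolation, costs and QALYs are out of scope; the engine
  simulates only to the trial horizon.
- Both arms use identical equations (the between-arm RR design); there is
  no treatment-effect modelling.
- The shipped coefficient set is synthetic. Its intercepts were calibrated
  so that typical-profile annual hazards are plausible for a
  secondary-prevention type 2 diabetes population (MI ≈ 1.5%/yr, stroke ≈
  0.8%/yr, CV death ≈ 0.9%/yr, non-CV death ≈ 1.3%/yr at the typical
  covariate profile including typical prior-event prevalences), but no
  claim of clinical validity attaches to it.
- Within-cycle event interactions are limited to death truncation; an
  MI and a stroke in the same cycle are treated as independent given the
  start-of-cycle state.
- Multiple imputation (with between-imputation variance) is out of scope;
  the stratified imputation is single-draw, as in the emulated policy.
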