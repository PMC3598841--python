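# Methods

## Model structure

The model is a discrete-time Markov state-transition model with eleven
health states and a one-year cycle: asymptomatic, acroparesthesia,
symptomatic, the three single end-organ complications (end-stage renal
disease, cardiac complication, cerebrovascular accident), the three pairs,
the triple state, and death.  Progression adds exactly one complication at
a time; the single regression is the kidney-transplant edge
(ESRD → symptomatic).  Death is absorbing and reachable from every state.
The cohort enters asymptomatic at birth and is followed for 70 cycles.

The transition matrix is assembled per sex, age and treatment status.
Listed exit probabilities fill the off-diagonal entries; the death entry is
the cohort-based death probability floored by the general-population
probability for that age and sex (`max(p_model, q_x)`); the residual mass
stays on the diagonal.  Exit probabilities summing above one are rejected
as a parameter error rather than renormalised.  Age enters only through
that mortality floor — all other probabilities are age-constant per state,
because each transition is summarised by a single annual probability.

## Parameter derivation

**Medians to probabilities.** Each annual probability derives from the
Kaplan–Meier median sojourn time under a constant hazard:
`p = 1 − 2^(−cycle/median)`, so a 1-year median maps to exactly 0.5.  When
the product-limit survival never reaches 0.5 within follow-up (rare
transitions), the estimator falls back to the constant-hazard person-time
rate `1 − exp(−events/person-years)` and flags the estimate
`median_unreached`; taking the last observed event time instead badly
overestimates rare-transition probabilities, and the person-time estimator
is the consistent constant-hazard alternative.

**Utilities.** EQ-5D-3L profiles are valued with a time-trade-off tariff
(UK MVH tariff by default; a Dutch tariff ships alongside for sensitivity
analysis — it penalises most profiles less, so disease progression costs
fewer QALYs and ICERs rise).  Utilities are averaged per patient per
disease-state cluster first, then across patients, so patients with many
questionnaires do not dominate.  Five clusters are used (asymptomatic,
acroparesthesia/symptomatic, single complication, multiple complications,
dead) because per-state patient numbers are small.

**Costs.** Quarterly resource counts are costed with Dutch unit costs and
multiplied by four; annual per-patient cluster means are averaged across
patients.  Production loss follows the friction-style questionnaire rules:
sick-leave days per fortnight × 26 × the overall mean working hours per day
among employed patients × €30/hour; permanent disease-related sick leave
counts a full-time-equivalent year; not employed for unrelated reasons
counts zero.  Production loss is excluded from the base case and added
(from age 18) only in scenario 6.

**Uncertainty.** Annual probabilities are treated as beta-distributed.
Confidence intervals come from a percentile bootstrap resampling patients
(not records); beta shape parameters come from the bootstrap mean and
variance by method of moments.  Degenerate (zero-variance) estimates
collapse to point masses.

## Treatment effect

The effect of ERT is an odds ratio *per treatment-year* for progressing to
the next complication: 0.82 (first complication), 0.52 (second).  The
transform to a per-cycle relative risk reduction (RRR) is:

1. cumulate the untreated annual probability over the median treatment
   duration `d`: `P0 = 1 − (1 − p)^d`;
2. compound the odds ratio: `odds1 = P0/(1−P0) · OR^d`, giving the treated
   cumulative risk `P1` and cumulative RRR `1 − P1/P0`;
3. de-cumulate under a constant hazard: `p1 = 1 − (1 − P1)^(1/d)`, giving
   the per-cycle RRR `1 − p1/p`.

The treated probability is `p · (1 − RRR)`.  The first-complication effect
acts on the three symptomatic → single-complication edges, the
second-complication effect on the six single → double edges; no effect is
assumed on double → triple or death edges, because only those two odds
ratios are reported.  The composition is exactly invertible: re-cumulating
the treated annual probability over `d` reproduces `P1` to 1e-12.

**Median treatment durations** per state are not published.  The synthetic
presets set both (symptomatic and single-complication) to 1.0 year, an
assumption: at `d = 1` the per-cycle RRRs are ≈ 0.18 and ≈ 0.46, and the
resulting lifetime gains (ΔYFEOD ≈ 1.8 years) sit at the reported effect
scale, whereas longer windows compound the odds ratio into much larger
per-cycle effects than the study observed.  The durations are ordinary
parameter-file fields and can be set freely.

## Engine

The deterministic cohort engine advances an occupancy vector through 70
cycles and accrues life-years, YFEOD, QALYs and costs from the
*post-transition* occupancy of each cycle.  No half-cycle correction is
applied by default (a `half_cycle` switch exists); discount factors are
`1/(1+r)^t` with `t = 0` for the first model year, at 1.5%/year for effects
and 4%/year for costs in the discounted variant (both variants are always
computed; the base case reports the undiscounted one).  ERT drug cost
accrues on alive, treated occupancy only.  Treatment status is a
deterministic predicate over (state, age) — `no_ert`, `ert_at_symptoms`,
`ert_at_40`, `ert_stop_after_2` — consistent with the memoryless model;
transplant returnees resume the symptomatic-state profile and the
first-complication treatment effect.

The microsimulation samples individual state paths from the same per-cycle
matrices (vectorised categorical sampling), converges to the cohort
expectation as `1/√n`, and is bitwise reproducible under a fixed seed.
Deterministic headline results come from the cohort expectation; the
microsimulation provides the first-order stage of the PSA and
patient-level heterogeneity.

## Economics and PSA

ICERs divide the lifetime cost difference by the difference in YFEOD or
QALYs, with dominance quadrants labelled instead of reported as bare
ratios.  NMB is `λ·ΔQALY − Δcost` over a willingness-to-pay grid of 25
log-spaced points from €20,000 to €10,000,000 (the range is stated by the
design, the spacing is ours).  The PSA is a two-stage Monte Carlo: 1,000
outer draws of every beta-distributed transition probability
(independently — no correlation structure is given) × 10 inner
microsimulated patients per strategy, with common random numbers across
the two arms by default (variance reduction; a flag disables it).
Utilities and costs stay fixed in the PSA, mirroring the stated design;
switches exist to vary them.  The CEAC reports the fraction of outer draws
with positive NMB at each willingness-to-pay.

A noteworthy interaction: with only 10 inner trials per draw, patient-level
noise dominates the per-draw QALY difference and flattens the CEAC so that
it stays at or below ~0.5 up to €10M per QALY even though the deterministic
ICER is ≈ €7M.  A large inner sample sharpens the curve into a step at the
deterministic switching value.  Scaled-down runs therefore reduce the
*outer* stage (e.g. 200 draws) and keep the 10-trial inner stage, which
preserves the curve's shape.

The break-even calculation divides an incremental lifetime cost by
(willingness-to-pay × treatment window): with the reported cost differences
at €80,000/QALY over a 46-year window it returns ≈ 0.66 discounted and
≈ 2.6 undiscounted QALYs required per treatment year.

## Scenarios

1. **Start at 40** — treatment additionally requires age ≥ 40.
2. **Utility gap** — the untreated comparator arm's cluster utilities are
   reduced by 0.1 (floored at 0), interpreting the reported mean utility
   difference additively across all alive clusters in the comparator arm.
3. **Classical phenotype** — an alternative preset with faster progression
   (the attenuated/atypical course removed); a parameter preset, not a
   patient filter, since the package holds no registry.
4. **ACE-ARB comparator** — standard care is assumed as effective as ERT
   for first-complication risk reduction: the comparator arm's
   symptomatic → single-complication probabilities get the same per-cycle
   RRR as the treated arm; the ERT arm is unchanged.  This is an
   interpretation of a stated assumption whose full derivation is not
   public.
5. **Stop after two complications** — double/triple states are untreated
   (no drug cost; transitions there carry no effect in the base case
   either, so effects barely move).
6. **Production loss** — indirect non-medical costs added to both arms for
   cycles at ages ≥ 18.

Every scenario reduces to the base case exactly when its override is
neutral.  Univariate sensitivity analyses cover the ERT price (€200,000 →
€150,000: the ICER falls by ≈ 25%, confirming drug-cost dominance) and the
utility tariff (UK vs Dutch).

## Synthetic data and calibration

The study cohort's patient-level records and the per-transition
supplementary tables are not public.  The package therefore ships:

- **A synthetic life table** (`life_table_synthetic_nl.csv`), a
  Gompertz–Makeham stand-in for the Dutch national table (infant term +
  `A + B·e^{c·age}`), with male mortality above female.
- **Three parameter presets** as versioned YAML data files.  The `base`
  preset was calibrated once so the untreated lifetime run lands in the
  published neighbourhood — ≈ 55 untreated YFEOD (males ≈ 53, females
  ≈ 57), ≈ 46 untreated QALYs, lifetime incremental costs ≈ €9.3M, ICERs in
  the millions with males more favourable — with males progressing ~25-50%
  faster than females per edge and plausible bootstrap-style CI widths
  (±33% relative).  `classical` scales progression up; `null-effect` sets
  both odds ratios to 1.  Exact published per-transition values are
  unknown; the presets are stand-ins, not transcriptions.
- **Patient-level generators** with known ground truth: event histories
  with exponential sojourns whose medians match the preset probabilities
  (so KM estimation is exact in expectation), EQ-5D profiles sampled by
  tariff-table lookup with randomisation between the two profiles
  bracketing a target utility (cluster means are matched in expectation),
  and Poisson resource-use counts with cluster-specific rates plus
  employment/sick-leave fields.

What passing recovery tests show: the estimation stage is consistent for
data generated under the model's own assumptions (independent exponential
competing risks, non-informative censoring, cluster-homogeneous utilities
and costs).  What they do not show: robustness to real-data features the
generator omits — confounding by indication, informative censoring,
non-constant hazards, measurement error in charts and questionnaires, or
cohort sizes as small as the real one (the real study had 142 patients;
recovery experiments here use hundreds to thousands).

## Numerical choices

- Matrix rows must sum to 1 within 1e-12 at assembly and 1e-9 during
  simulation; violations abort with the cycle index.
- The KM median uses the first time the survival function is ≤ 0.5 with a
  1e-12 tolerance, guarding exact-tie medians (S = 1/2) against float
  round-off.
- Beta method-of-moments shapes are clipped away from the zero-variance
  boundary (variance ≥ 99.9% of the Bernoulli maximum is treated as
  degenerate).
- Treated probabilities are clipped to [0, 1] with a warning if a harmful
  RRR (< 0) pushes them above 1.
- Seeds: every stochastic component takes an explicit seed or Generator;
  the PSA, microsimulation and generators are bitwise reproducible.

## Known limitations

- Kidney-transplant follow-up costs are excluded by design (only the
  first transplant year is costed, via the state-cost table).
- No tunnel states: time-in-state effects (e.g. first-year complication
  costs) cannot be represented beyond the cluster cost averages.
- The treatment predicate is memoryless; "stop after two complications"
  works only because it is state-determined.
- The synthetic presets reproduce the published *neighbourhood*, not the
  published tables; one-decimal agreement with the original results would
  require the unpublished supplementary parameter tables.
- Odds ratios are taken as inputs; re-estimating them from patient data
  (a companion analysis) is out of scope.
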