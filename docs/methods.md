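# Methods

## Model structure and assumptions

The simulator is a discrete-time individual-based model with a monthly
step. The state of each woman of reproductive age (15–49 inclusive,
evaluated at the month's start) is her contraception category — one of
`not_using` plus ten methods, the categories used in DHS contraceptive
calendars — together with pregnancy status and appointment history. Men
and children carry no contraception state; they are simulated only for
demography (deaths, the dependency ratio, and population-proportional
implementation costs). Male condom use is attributed to the female
partner, as in calendar data.

Each eligible woman takes **exactly one transition outcome per month**:

* **Non-users** face a single categorical draw over pregnancy, initiation
  of each method, and staying. Making pregnancy and initiation mutually
  exclusive within a month is a modelling choice; at monthly
  probabilities of a few percent the induced bias is second-order.
* **Users** face sequential competing draws in the order failure →
  discontinuation → switching. Discontinuation being conditional on not
  switching-out-by-failure, and switching conditional on neither, mirrors
  the conditional definition of the switching probability; placing
  failure first is this package's convention (the alternatives differ at
  order `p_fail · p_disc` ≈ 10⁻⁴ per month). The enumerated outcome
  distribution for probabilities (pf, pd, ps) is
  {pf, (1−pf)·pd, (1−pf)(1−pd)·ps, rest}, which the test suite checks by
  Monte Carlo at 10⁶ draws.
* **Pregnant women** are inactive until the scheduled end-of-pregnancy
  event exactly nine calendar months after conception; only then is live
  birth vs early termination decided (`live_birth_probability`, default
  1.0 and exposed as a parameter). On conception the woman's method is
  set to `not_using` for the duration — a failure implies the method
  ended, and the source of a non-user conception was non-use — and the
  postpartum initiation draw happens the month after resolution.

Multiplicative modifiers stack on the base monthly probabilities: age
effects stored as proportional deviations (multiplier `1 + δ(a)`),
per-year secular trends applied as `τ^(years since 2010)` (initiation
typically upward, stopping downward), the age-group scaling factor on all
pregnancy risks, a failure risk ratio of 2.2 below age 25, an HIV
fertility multiplier for non-using HIV-positive women, and the Pop/PPFP
intervention multipliers from their start month. If a woman's non-stay
probabilities sum above 1 after multipliers, they are rescaled
proportionally and the occurrence is counted in the run diagnostics
(large multipliers on rare methods make this legitimate rather than an
error). Female sterilization is absorbing: it never discontinues or
switches.

**Sterilization age restriction.** Initiation of female sterilization is
zeroed below an eligibility age (default 30). To preserve the
population-expected number of sterilizations, the probability at eligible
ages is scaled by Σw / Σw≥cut for a given age-weight vector, and within
each age the other methods are rescaled multiplicatively so the total
initiation probability at that age is unchanged. The transform is applied
to both the from-non-use and the postpartum initiation tables and
produces age-expanded matrices; both weighted invariants are property-
tested to 10⁻¹².

**Demography.** The first nine months are seeded by scheduling births
directly from age-specific fertility rates (assignment probability
ASFR·9/12, due month uniform over months 1–9, conception backdated),
because nobody is pregnant at initialization. Mortality converts annual
probabilities to monthly hazards via 1 − (1 − q)^(1/12); the additive
ASFR/12 form is used for the initial scheduling, matching the rate-like
use of fertility rates. Women exit the risk set at 50 (state forced to
non-use). Newborns draw sex 50/50 and age into the risk set if the
horizon is long enough.

## Randomness and coupled runs

Random numbers are organized as one counter-based stream per (month,
purpose), with draws indexed by person id. Two runs with the same seed
but different interventions therefore give each woman the same uniforms
each month (common random numbers), and the categorical draw orders
initiation intervals before the pregnancy interval so that enlarging
initiation probabilities converts pregnancy/stay outcomes into
initiations rather than reshuffling them. This makes with/without
comparisons nearly noise-free: coverage dominance holds month-by-month in
practice, and cumulative births, end-horizon population, and the
dependency ratio all fall under the interventions. Identical seeds give
byte-identical event logs.

## Synthetic default parameters

Full survey-derived tables for the method-level probabilities are not
shipped; the generator synthesizes a realistic set around the scalar
vectors that are fixed inputs: the HIV fertility multipliers
(1.4/0.9/0.8/0.7/0.5/0.4/0.3 by five-year group), age-specific fertility
rates (0.144/0.239/0.213/0.174/0.123/0.061/0.022), pregnancy scaling
factors (1.227/0.799/0.829/0.809/0.749/0.645/0.941), the under-25 failure
risk ratio 2.2, and the maintenance intervals (IUD 4,383 d; implant
1,461 d; injection, pill, condoms, other modern 91 d). The synthetic
method tables encode the qualitative structure of contraception in Malawi
around 2010: injection is the highest-initiation and most-used modern
method, sterilization is rare and rises with age, traditional methods are
minor; overall use peaks in the thirties. The seed perturbs the age
curves only slightly (±2 % smooth noise), so every seed yields a valid,
qualitatively identical set. Secular trend defaults (1.02 initiation,
0.98 stopping per year) encode the expected gradual rise of uptake. The
default age structure is an expansive pyramid (≈3.5 % exponential decline
per year of age), adult HIV prevalence ≈10 %, and the mortality schedule
a stylized high-mortality life table.

What the generator does **not** emulate: covariate structure beyond age
(wealth, education, marital status), unmet need, seasonality, supply
interruptions, or survey reporting error. Tests passing on this synthetic
world demonstrate the mechanics and the estimators, not Malawi-specific
forecasts; national-scale statements require the real survey-derived
tables as input files.

## Calibration

Fitting runs against an expectation-mode companion of the engine that
propagates expected state fractions per single year of age through the
identical transition structure (including the nine-month pregnancy
pipeline and postpartum draw). It ignores mortality and HIV, and holds
the inflow of 15-year-olds at its initial size; it exists to make
objectives deterministic and cheap, and the stochastic engine remains the
arbiter of any calibrated set.

1. **Scaling factors** — iterative proportional fitting of the seven
   age-group factors so the expected monthly live-birth probability at
   baseline matches ASFR/12; the objective is linear in each factor, so
   convergence is immediate (tolerance 1 % relative, cap 200 iterations).
2. **Secular trends** — damped least squares on the vector of annual
   birth residuals over the target years. The two trends trade off along
   a narrow valley, so a Jacobian-based search replaces naive coordinate
   descent, which stalls; recovery of known trends from self-generated
   trajectories is exact to ≲10⁻⁶.
3. **Intervention multipliers** — proportional updates
   (multiplier ← multiplier · target/achieved share at the horizon) until
   all targets are within tolerance; postpartum multipliers, having no
   dynamics, are solved directly as target/base.

Fit quality against a reference births trajectory is reported as
100 · RMSD(model, reference) / RMSD(alt-reference, reference), i.e. the
model error as a percentage of the spread between projection variants.

## Costing

Costs accrue per appointment event: an initiation appointment (on
initiation, switching, or postpartum uptake of a modern method, and for
users present at initialization with no appointment history) dispenses
the method package plus a pregnancy slide test (32 MWK); maintenance
appointments dispense the package whenever the days since the last visit
strictly exceed the method interval. Sterilization accrues its package
once, at initiation. Weighted unit costs average over dispensed product
alternatives (pill cycle 493 MWK from an 80/20 mix; implant device 760
MWK from a 50/50 two-rod/one-rod mix, which also fixes the four-year
appointment interval). Accounting is in real-valued 2021 MWK; USD at
790 MWK/$; rounding (nearest MWK for unit costs, 0.1 % for shares,
thousand users, cents per capita) is display-only. Implementation costs
(2,400 M and 264 M MWK per year for the two interventions, at the
base-year population 15–49) scale proportionally with the simulated
population each year. Personnel, facility and supply-chain costs are out
of scope, and consumables are assumed always available.

A small table of published scenario cost figures is embedded as reference
*input* for ledger arithmetic (column totals, cost ratios, per-capita
summaries); it is never presented as simulation output.

## Calendar estimation

`simulate_calendars` produces month-by-month state strings using the
engine's sampling kernels with the method-level baseline probabilities
only — no age effects, HIV, scaling factors or trends — so the
occurrence-exposure estimator's target is exactly the generating table.
Estimates mirror the engine's conditional structure (failure per exposed
month; discontinuation conditional on no failure; switching conditional
on neither; destinations from observed switch counts). Zero-exposure
estimates are reported as undefined, not zero. Recovery tests use the
null standard error √(p(1−p)/exposure) computed from the generating
probability, which stays defined when zero events are observed for very
rare outcomes (e.g. sterilization failure). Discontinuation reason codes
are recorded (failure vs other) but finer reasons are not modelled.

## Problem sizes and numerical choices

Default experiment sizes: Monte-Carlo kernel checks at 10⁶ draws;
estimator recovery at 20,000 women × 60 months; calibration on a
2010–2030 expectation horizon; coupled intervention comparisons at 15,000
agents over 2010–2040; the engine handles 50,000 agents over 40 years in
well under a minute on one CPU. Probability-sum overflows rescale rather
than error; switch-matrix rows must be stochastic to 10⁻⁹; ties in
categorical draws are impossible almost surely and resolved by interval
order (initiations, then pregnancy, then stay). Seeds are plain integers;
all derived streams use counter-based seed sequences, so results are
platform-stable for a given numpy generation.

## Known limitations

* Pregnancy is a fixed nine-month block; preterm birth, terminations and
  postpartum infecundability are not modelled, slightly overstating
  exposure time.
* The expectation-mode calibrator's stationary inflow understates cohort
  growth over multi-decade horizons; trends fitted to very long
  trajectories inherit that approximation.
* Implementation-cost inflation to 2021 MWK is taken from the published
  inflated amounts, not recomputed from a price index.
* The dependency-ratio convention counts ages ≥65 as dependents (the
  conventional 65+ definition; "over 65" in some figure captions is read
  inclusively, a one-line discrepancy documented here).
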