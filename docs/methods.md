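# Methods

## State space and classification

Each subject-visit record is mapped to a component profile under the CDS
criteria and then to one of seven mutually exclusive, collectively
exhaustive states, indexed 0–6 in the fixed order used by every matrix in
the package: no component, isolated overweight/obesity, isolated
hypertension, isolated dyslipidemia, isolated hyperglycemia, two-component,
MS.

Component rules (all units fixed: kg/m², mmHg, mmol/L; no unit inference):

| component | rule (any clause suffices) | default cut |
|---|---|---|
| overweight/obesity | BMI ≥ cut | 25.0 kg/m² |
| hypertension | SBP ≥ cut, or DBP ≥ cut, or prior diagnosis | 140 / 90 mmHg |
| dyslipidemia | TG ≥ cut, or HDL < cut | 1.7 / 0.9 mmol/L |
| hyperglycemia | FPG ≥ cut, or 2-h PG ≥ cut (when measured), or prior diagnosis | 6.1 / 7.8 mmol/L |

Boundary semantics follow the inequalities exactly: `≥` everywhere except
the strict `<` for HDL.  A value at its cut counts as present.  Prior
diagnosis flags are sufficient on their own for hypertension and
hyperglycemia.  The 2-h post-meal glucose is optional; its absence never
changes a classification already decided by FPG or the diagnosis flag.
The mapping from profiles to states is total on the 16 profiles (0
components → state 0; exactly one → the matching isolated state; two →
state 5; three or four → state 6) and surjective with multiplicities
1/4/6/5 across the four kinds.

Exclusions are subject-level: a history of coronary heart disease, type I
diabetes or familial hyperlipidemia at any visit, a missing mandatory
measurement at any visit ("incomplete information"), or age under 18 drops
the subject entirely, and the counts per reason are logged.  Dropping the
whole subject (not just the affected visit) is the conservative reading of
an exclusion criterion phrased about individuals; it costs events but
cannot bias the remaining transitions.

Strata are sex × age group with the half-open age partition [18,40),
[40,50), [50,60), [60,∞).  The source labels overlap at 40; half-open
intervals give a single-valued mapping consistent with the "≥60" phrasing.
By default a transition event is assigned to the subject's stratum at the
first year of the year pair, keeping age current over up to six years of
follow-up; freezing the baseline stratum is available as a configuration
switch (`stratum_mode="baseline"`), since either reading is defensible.

## Transition estimation

For each stratum, transitions are counted between every pair of adjacent
calendar years (y, y+1); visits separated by a gap contribute no event
across the gap, and calendar adjacency — not visit ordinality — defines
"consecutive", which is what makes the rates annual.  Each year pair gives
a row-conditional incidence matrix in percent; the stratum's annual
transition matrix is the cell-wise unweighted mean over year pairs, which
is the primary estimator because it weights each year equally regardless of
how many subjects it contributed.  Count-weighted pooling (summing counts
before forming rates) is provided as a sensitivity alternative; the two
coincide exactly when the year-pair row denominators are equal, an
algebraic identity the tests check on constructed inputs.

Rows unobserved in a year pair are excluded from that row's mean rather
than zero-filled (zero-filling would bias persistence downward); rows never
observed at all are emitted as NaN with zero support, and projecting
through such a row is a hard error.  Averaged rows are renormalized to sum
to exactly 100 — averaging of individually normalized rows already
preserves the sum, so this only guards against exclusion-induced drift.
Matrices are reported in percent with two-decimal display; full precision
is retained internally.

## Projection and validation

Occupancy is propagated by `π_{t+1} = π_t P` over a default 10-cycle
horizon, time-homogeneously and without age-group migration (a cohort
projected under the 18–40 matrix stays under it; the per-stratum figures
this mirrors are defined that way).  Two numeric regimes are deliberate:

* **verbatim** (`renormalize=False`): printed rows are used as-is
  (percent/100), so a one-cycle projection from a unit vector reproduces
  printed cells bit-for-bit even though printed rows sum to 100 only up to
  rounding;
* **renormalized** (default): each row is divided by its own sum before
  propagation, so every `π_t` sums to 1 within 1e-9 over any horizon.

The stationary distribution is computed by repeated squaring of the
renormalized matrix to a 1e-9 fixed-point tolerance; on the packaged
matrices (irreducible and aperiodic) all seven starting states converge
toward it, which is why 10-year MS occupancy is nearly start-independent.
An independent microsimulation oracle steps n chains forward individually
and must agree with the matrix-power result to binomial Monte-Carlo error.

Validation compares, per baseline stratum, the MS share of the occupancy
vector projected `h` cycles from the baseline distribution with the MS
prevalence observed among subjects actually seen at follow-up year `h`
(default 5).  The report is descriptive — projected, observed, absolute
gap — with no pass/fail threshold, since none is defined for the model;
strata with nobody at the horizon are marked not validatable.

## Synthetic cohort generator

The generator emulates the study design: per stratum, subjects start in a
state drawn from a baseline distribution, evolve annually under the
stratum's ground-truth matrix, and attend between 2 and 6 visits inside a
6-calendar-year window with staggered enrolment.  Defaults:

* **dropout 0.30 per visit after the second** (independent Bernoulli;
  retained visits = 2 + the run of successes).  This yields a mean of
  ≈3.77 visits, matching the studied cohort's mean follow-up of ~3.74
  visit-years; the true visit-count distribution is unknown, so the
  Bernoulli mechanism is a modelling choice, not an inference.
* **940 subjects per stratum** in the demo model, ≈ the studied cohort of
  7,510 spread over 8 strata.
* **baseline distribution** = the stratum matrix's stationary distribution
  pulled halfway toward the no-component state: a screening cohort
  healthier than the long-run mix, whose MS prevalence rises over
  follow-up as observed in such cohorts.
* **ages** uniform within the stratum interval at baseline (the open-ended
  ≥60 group capped at 75) and incremented by one per visit.

Measurements are rendered so that classification returns exactly the
latent state: each present component is triggered through one randomly
chosen clause of its rule (e.g. hypertension via high SBP, high DBP or the
diagnosis flag), each absent component fails every clause, and values are
drawn uniformly within ranges that sit strictly on one side of their
threshold with a margin wide enough that 2-decimal rounding cannot cross
it (a range straddling its threshold is rejected as a configuration
error).  Composite states pick their component combination uniformly among
the valid ones (6 pairs; 4 triples + 1 quadruple) — downstream
classification depends only on the count, so the choice is immaterial
there.  All randomness flows from a single seed, making cohort CSVs
byte-identical across runs.

What the generator does *not* emulate: realistic joint biomarker
distributions (only threshold-consistency is guaranteed), within-subject
biomarker tracking over time, mortality and competing risks, and
state-dependent dropout.  Passing tests therefore demonstrate that the
pipeline recovers known dynamics from CDS-consistent panel data, not that
it is robust to measurement noise near thresholds or informative
missingness in real check-up data.

One known artifact of per-pair stratification: subjects simulated under
one stratum's matrix can age across a stratum boundary mid-follow-up, so in
a full multi-stratum simulation boundary-crossing events are counted in
the next stratum while still following the previous stratum's dynamics.
Parameter-recovery checks therefore simulate one stratum at a time, where
crossing only moves events (all governed by the same matrix) out of the
target stratum without biasing it.

## Packaged matrices

Five fixtures are the study's printed per-stratum tables, stored in
percent exactly as printed and renormalized row-wise only on use —
preserving the printed cells while guaranteeing stochasticity.  The three
remaining strata (women 50–59, men ≥60, women ≥60) are synthetic
stand-ins, constructed as blends of adjacent printed strata (with one
extra cycle of progression for the ≥60 groups) and labelled as such in the
data file and their provenance field; they exist so the 8-stratum demo
pipeline runs end to end and carry no evidential weight.

## Problem sizes

Default checks use 200,000 simulated subjects per stratum for parameter
recovery (sampling error well inside ±0.5 percentage points per cell),
100,000 chains for the microsimulation oracle (3-binomial-SE agreement per
state per cycle over 10 cycles), and 100,000 subjects for the 5-year
validation self-consistency run; the demo pipeline uses 940 subjects per
stratum to mirror the studied cohort's scale.

## Known limitations

* Gap handling (no event across non-adjacent years) is one reading of an
  under-specified procedure; pooled-count weighting is the other and is
  exposed as an option.
* No confidence intervals for transition probabilities; none are defined
  for the estimator here.
* Continuous-time intensity models (e.g. `msm`-style panel estimation) are
  out of scope: the model is cycle-based with an annual step by design.
* Exact 10-year occupancy values for the studied cohort's figures were
  never printed numerically; projection output reproduces their structure
  (curves per starting state), not pixel values.
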