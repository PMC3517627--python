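# Methods

## Disease process

Airway impairment per patient is a shot-noise process: between trigger
events, `I(t)` relaxes exponentially toward the unimpaired state at rate
`γ` (per day); at Poisson-timed triggers (rate `λ` per day) it jumps by an
exponentially distributed effect size with patient-specific mean
`mean_alpha`. The Dirac impulse is realized as an exact additive jump — no
smoothing. All times are in days and all rates per day. Two closed forms
drive everything downstream:

- the stationary law of `I` is Gamma(shape `λ/γ`, scale `mean_alpha`), so
  the long-run mean is `λ·mean_alpha/γ` and the occupancy above any level
  has an incomplete-gamma expression;
- the upcrossing rate of a level `L` by jumps is
  `λ·e^{−L/θ}(L/θ)^k / Γ(k+1)` with `k = λ/γ`, `θ = mean_alpha`.

The effect-size family is exponential by default (single positive
parameter, heavy-enough tail); the sampling hook accepts any positive
family if a different tail is wanted.

## Pulmonary function and behavior

Pulmonary function is `Q = exp(−I/σ)`, with `Q = 1` the personal best
(`I = 0`) and `Q → 0` the floor; `σ ≥ 1` is the bronchodilator factor,
additive in the strengths of active β₂-agonist episodes (an optional
`kappa` hook attenuates bronchodilation at high inflammation; default 0).
This form was chosen because it honors the stated anchors, makes `Q`
increase with `σ`, and — with piecewise-constant `σ` and `γ` — confines
downward threshold crossings to jump/coverage instants, which is what
makes the event-driven engine exact rather than approximate.

Care-seeking is threshold-driven on the `Q` scale with personal thresholds
`0 < q_ed < q_md < q_relief < 1`:

- below `q_relief`: take a reliever immediately and again at each expiry of
  the previous dose (4 h default) until back above the threshold;
- below `q_md`: an unscheduled physician visit; also the treatment-failure
  definition (first passage);
- below `q_ed`: an ED presentation; admission with fixed probability
  `p_admit` irrespective of function at presentation; length of stay is
  geometric on whole days (mean 3.0 by default); function is held stable
  while inpatient; every discharge (and, by default, every unscheduled
  visit and ED discharge) is followed by a 5-day oral-steroid course.

Two deliberate behavioral conventions:

- *Thresholds see controller-adjusted function only.* An active reliever
  dose raises `Q` but does not mask the decision to seek care. Besides
  being clinically defensible (symptomatic relief does not cancel an
  exacerbation), this keeps all downward crossings at event instants.
- *Washout with re-presentation.* After an encounter, the same encounter
  type cannot recur until `I` has recovered above the corresponding
  threshold and a washout (2 days) has passed; if the patient is again
  (or still) below threshold when the washout expires, they re-present at
  that moment. An ED visit subsumes the physician-visit channel for the
  same excursion.

## Medications

| class | effect | duration | schedule |
|-------|--------|----------|----------|
| SABA | `σ += broncho_beta` (0.40) | 4 h | as needed (cascade) |
| LABA | `σ += broncho_beta` (0.25 start value) | 12 h | 2/day |
| ICS | `γ ×= gamma_mult` (2.0 start), `mean_alpha ×= sens_mult` (0.60 start) | 24 h | 2/day |
| OCS | `γ ×= 3.0`, `mean_alpha ×= 0.50` | 24 h | 5-day course |

Corticosteroids never change `I` itself, only its rate of change, so their
start/stop leaves the trajectory continuous. Adherence is the fraction of
days a prescribed controller is used, realized as one Bernoulli coin per
calendar day (both daily doses share the coin), matching the survey
definition. Consecutive taken days merge into coverage intervals.
Dose-level labels (low/medium/high) are carried as data; the default
catalog gives them equal effect.

The ICS/LABA magnitudes above are *starting values* of conventional size
for the population-level tuning procedure, not fitted constants: the full
pipeline calibrates patients under them and then tunes the catalog against
a perfect-adherence outcome column. We ship starting values rather than a
tuned fixed point deliberately — the calibrate→tune iteration has a
feedback loop (a stronger catalog makes recalibrated users intrinsically
sicker, weakening scenario contrasts), and the out-of-sample scenario
prediction is best at one calibrate→tune pass, which is also how the
pipeline is documented to be run.

## Event-driven engine and its oracle

The engine advances analytically between discrete events (trigger jumps,
coverage boundaries, steroid-course ends, discharges, washout expiries);
reliever cascades inside an interval are emitted in closed form, so heavy
reliever users cost no more than light ones (~1–5 ms per patient-year).
The initial condition is the stationary mean `λ·mean_alpha/γ` (a 30-day
burn-in alternative and an explicit `initial_I` are available; the trial
harness uses the latter to chain phases).

A brute-force fixed-step reference engine re-implements every behavioral
rule as a per-step state machine and consumes the same pre-sampled inputs.
On 50 random treated patients over 60 days (dt = 10⁻³ d) the two agree
exactly on all encounter counts; reliever counts agree to ≤ 3 uses and the
final impairment to ~2×10⁻³ relative — the residual is steroid-course
boundaries quantized to the reference grid, so the test tolerance is
5×10⁻³ on final impairment rather than 10⁻³. The medication-free
trajectory oracle does meet 10⁻³ (jump placement at the first grid point
at/after the jump keeps the discretization error ≲ γ·dt).

## Synthetic population

The generator emulates a national-survey sample of 4,930 patients aged
12+: two age strata (83% adults), quota-matched (exact to ±1) sex, smoking
(adults only), and controller-prescription categories (ICS 43.2% overall,
combination ICS+LABA users a subset), continuous marginals (age, FEV1 %
predicted, rescue use/day, past-year unscheduled visits / ED visits /
hospital stays) matched in mean and SD per stratum. Joint structure comes
from one latent severity factor `z ~ N(0,1)` per patient: counts are
negative binomial with a lognormal frailty `exp(b·z − b²/2)` on the mean
(b = 1.1), moment-matched so the frailty-mixed marginal variance equals
the target SD²; rescue use is gamma with the same style of frailty
(b = 0.9); FEV1 % predicted declines with `z` (loading 0.4). Adherence per
prescribed patient is Beta with the stratum mean and concentration 10.

Prescription status is tilted *away* from severity (weights `e^{−z}` in
the quota draw). This is the prescribing gap the survey exhibits — with
independent assignment, the fraction of untreated patients reporting a
serious exacerbation or ≥2 rescue uses/day cannot reach the observed
~27% qualifying fraction, because NB moment matching pins the zero
probabilities. All link slopes were fixed once against the marginal table
and are not per-run knobs.

What the generator does *not* emulate: survey weights, children under 12,
zero-inflation beyond NB, item nonresponse, and any real-data joint
structure beyond the single factor. Tests passing on this population show
the pipeline is faithful to the stated marginals and qualifying rule — not
that the factor model captures the true survey dependence.

## Calibration

Each patient is calibrated by accept-reject search: candidate parameter
vectors `(λ, mean_alpha, γ, q_relief, q_md, q_ed)` are simulated for 3
replicate-years under the patient's observed prescriptions and adherence,
and the first candidate whose weighted normalized L1 distance to the
patient's past-year targets (weights 1 for the three encounter rates, 0.5
for rescue use — a secondary target; per-target normalization by
`max(target, floor)`) falls below the tolerance (0.2) is accepted, with
best-of-budget (500) as fallback. Calibration is stochastic by design:
recalibrating the same individual yields a different, equally acceptable
parameterization.

Candidates are not drawn blindly: the stationary closed forms above are
inverted per patient (a 1-D grid over `k` with `θ` eliminated through the
ED/physician-visit ratio and `λ` through the ED upcrossing rate), and
damped multiplicative corrections of the *pseudo-targets* fed to that
inversion absorb what the stationary algebra cannot see — washout dead
time, post-encounter steroid courses, partial controller coverage (the ED
and reliever corrections start above 1 for this reason). Jitter around the
corrected center makes the proposal; thresholds are drawn with an
ordering-safe jitter around (0.85, 0.60, 0.40). The admission probability
is a care-system parameter fitted once from the population-level
hospitalization/ED target ratio, not per patient.

Treatment-effect tuning is coordinate descent over a grid for
(`ICS.gamma_mult`, `ICS.sens_mult`, `LABA.broncho_beta`), minimizing the
normalized error of simulated population rates against a target outcome
column (reliever weight 0.5 again), with common random numbers across
candidate catalogs so the search surface is noise-free, and with the
non-controller subpopulation's contribution cached (catalog changes cannot
affect it).

## Scenarios, survival statistics, national scaling

The four scenarios modify prescriptions only: perfect adherence sets every
controller's adherence to 1; expanded prescribing adds a medium-dose ICS
to guideline-qualifying untreated patients (≥1 ED visit or hospitalization
in the past year, or ≥2 rescue uses/day), with adherence drawn from the
current-user pool (EO) or 1 (EP). Trigger and effect-size streams are
keyed by patient only, so all scenarios share them; adherence coins are
scenario-keyed; the care-disposition stream is patient-keyed so the k-th
ED presentation draws the k-th admission coin in every scenario — this
makes the monotone-benefit property (more coverage can never produce more
admissions, given no extra ED visits) hold pathwise, not just in
expectation.

Kaplan-Meier, the one-degree-of-freedom log-rank test and the
Mantel-Haenszel hazard ratio `(O_A/E_A)/(O_B/E_B)` with CI
`exp(log HR ± 1.96·√(1/E_A + 1/E_B))` are computed from pooled risk sets
and cross-checked in the tests against an independent survival library and
hand-enumerated risk tables. National event counts multiply per-capita
rates by a represented-population weight (default 9.59×10⁶ persons,
back-solved from the published national table against its per-capita
baseline; user-overridable) and round to hundred-thousands.

The trial harness resamples a calibrated population with replacement to
the trial size, simulates a run-in under observed medications, then the
assigned arm's phase schedule (carrying the impairment level across
phases; washout state resets at phase boundaries, a documented
simplification). The corticosteroid dose-reduction transform halves the
recovery-rate boost and moves the sensitivity reduction halfway to 1.

## Problem sizes and reproducibility

The shipped analysis sizes are: the full n = 4,930 survey-scale
population in the reproduction script and n = 450 in the acceptance test fixture,
with tolerance bands that widen by the reduced cohort's sampling SE. All
randomness flows from one master seed through named per-patient substreams
(`SeedSequence(master, patient_id, purpose[, scenario])`); identical seeds
give bit-identical populations, calibrations and event logs.

## Known limitations

- Encounter rates respond to `γ` only weakly (jump-crossing rates depend
  on `λ` and the jump tail); `γ` is identified mostly by reliever
  occupancy. Patients with extreme utilization (≈99th percentile) may be
  matched only to best-of-budget accuracy.
- The baseline reliever rate is anchored to the survey target (~1.1
  uses/day) by calibration; analyses that quote reliever *reductions*
  against a baseline of ~1.4 uses/day are therefore not reproduced, even
  though optimized-scenario reliever levels agree (see the scenario-table
  note below).
- The published scenario table's baseline controller-use rate (0.27/day)
  is inconsistent with its own user-fraction × adherence (≈0.35/day); we
  define controller use-days/day as fraction-of-days-used averaged over
  all patients and document rather than force the match.
- Hospitalization reductions are tied to ED reductions through the fixed
  admission probability; a scenario cannot reduce admissions
  proportionally more than ED presentations, in expectation.
- No seasonality, no mortality or dropout, no circadian structure, no
  direct (non-ED) admissions, single inflammation compartment, smoking
  carried as data with no physiological effect by default.
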