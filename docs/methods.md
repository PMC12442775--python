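# Methods

## The decision problem

Patients with atrial fibrillation (AF) face an elevated risk of
cardioembolic ischemic stroke. Direct oral anticoagulants (DOACs) cut
that risk sharply but increase major bleeding. For patients at high
stroke risk the trade-off clearly favors treatment; for low-risk
patients it does not, and somewhere in between lies a *tipping point* —
the annual nonanticoagulated ischemic-stroke risk at which starting a
DOAC and withholding it yield the same expected quality-adjusted life
years (QALYs). This package estimates that tipping point, the QALY
differences at clinically interpretable risk levels, and the
uncertainty around the threshold, with a Markov state-transition model
evaluated by patient-level Monte-Carlo simulation.

## Model structure

Patients enter at age 70 in the *well* state and are simulated in
1-month cycles over a 20-year horizon (a 5-year variant is also
reported). Each cycle, at most one of the following occurs, resolved by
a single categorical draw over monthly probabilities:

* ischemic stroke,
* hemorrhagic stroke,
* other intracranial bleed,
* major extracranial bleed,
* death from other causes.

Event severities — {fatal within 30 days, severe, moderate, mild} for
strokes and intracranial bleeds, {fatal, permanently disabling,
nondisabling} for extracranial bleeds — are drawn from distributions
that depend on whether the patient is under active anticoagulation at
the time: prior DOAC exposure makes ischemic strokes milder and
bleeding events no less severe. Nonfatal strokes and intracranial
bleeds raise the annual background mortality to 14% (stroke) or 16%
(intracranial bleed) for the following 12 cycles, implemented as
`max(background, elevated)` so mortality never drops after an event;
the window restarts on every recurrence. In the DOAC arm any major
bleed pauses therapy for exactly one cycle, during which the patient
carries untreated hazards and severity distributions. Death is
absorbing. Patients cannot experience more than one event per cycle.

All annual probabilities are converted to monthly ones with the
constant-hazard complement `1 - (1 - p)^(1/12)`, the exact inverse of
12-cycle compounding.

## Risk-dependent rates and treatment effects

Everything is indexed by the annual nonanticoagulated ischemic-stroke
risk `s` (0–10%). Patients at higher stroke risk are older and sicker,
so their untreated bleeding and mortality rates rise with `s` along
straight lines through two anchors:

| quantity | at s = 1% | at s = 6% |
|---|---|---|
| annual major bleeding | 0.9% | 2.2% |
| annual background mortality | 3.7% | 12.0% |

Major bleeds split 11% / 7% / 82% into hemorrhagic stroke, other
intracranial, and extracranial bleeding.

DOAC therapy acts through three relative risks:

* **Ischemic stroke**: the relative reduction rises linearly from 32%
  at a 1% untreated stroke risk to 68% at 6%, is constant above 6%, and
  continues along the same line below 1% (floored at zero reduction).
  The flat-below-1% alternative was considered; the difference at 0.4%
  risk is negligible relative to the Monte-Carlo noise there.
* **Major bleeding**: constant relative risk 1.91 (= 2.22 x 0.86),
  applied identically to all bleed types.
* **All-cause mortality**: no effect below a 1% stroke risk, a
  reduction rising linearly to 43% at 6%, constant above. The mortality
  relative risk applies to *background* mortality only — never to
  30-day case fatality or the 1-year post-event elevation — because the
  43% anchor already incorporates event-mediated deaths; applying it to
  those pathways would double-count.

## Utilities and outcome measures

Baseline utility weights are age-specific (5-year bands, non-increasing
with age); the cohort reads the table from its starting age, and the
60- and 80-year sensitivity variants simply shift that starting band.
A nonfatal event multiplies the patient's current weight by a severity
utility ratio; joint health states compound multiplicatively, so the
final weight is order-independent. Permanently disabling extracranial
bleeds reuse the severity-ratio scale keyed by disability grade. A
patient alive at the end of a cycle accrues `weight / 12` QALYs; no
half-cycle correction is applied (second-order at a 1-month cycle, and
identical in both arms) and QALYs are not discounted (no discounting is
part of the model definition). *Disability-free life years* accrue at
1/12 year per cycle until death or the first severely disabling event
(severe stroke, severe intracranial bleed, or disabling extracranial
bleed).

## Estimators

* **Sweep / tipping point** (`threshold.run_sweep`,
  `find_tipping_point`): both arms are simulated at each 0.1% grid
  point with *common random numbers* — identical per-patient-cycle
  uniform streams — so the paired QALY difference has a far smaller
  Monte-Carlo variance than independent arms. The categorical draw
  resolves other-cause death first so that its uniform interval stays
  aligned between arms wherever the mortality probabilities coincide;
  this cuts the paired standard error about five-fold at low risk. The
  tipping point is the root of a local straight-line fit of the
  difference curve over a ±0.3% window around the smoothed sign change,
  reported at 0.01% resolution; at 10 000 patients/arm the noise near
  the crossing exceeds the signal, which is why raw adjacent-point
  interpolation is not used. If the smoothed curve never changes sign,
  "no crossing in range" is reported rather than a number.
* **Fixed-risk differences** (`qaly_difference_at`): paired mean with a
  common-random-number standard error.
* **Deterministic oracle** (`oracle.expected_arm_outcome`): exact
  expected QALYs by forward propagation of the state-occupancy vector
  over the enumerable state space (post-event window type x 12-month
  timer x pause flag x disabled flag, plus death). The continuous
  multiplicative utility decrement is propagated exactly as a parallel
  "ratio mass" per state, using linearity of expectation. The oracle
  verifies the microsimulation (agreement within 3 SEM is a standing
  acceptance test) and drives calibration, since it is noise-free and
  ~1000x faster than simulation at equivalent precision.
* **Probabilistic sensitivity analysis** (`psa.run_psa`): the three
  treatment relative risks are the only uncertain inputs. Each
  iteration draws one z per effect and multiplies the risk-dependent
  point RR by `exp(z * SE)` with SEs 0.16 / 0.30 / 0.13 on the log
  scale, shared across the entire risk grid (constant uncertainty
  across the spectrum). Because one shared z-sample moves the whole
  proportion curve coherently, its sample-mean error is common-mode and
  would dominate the horizontal position of the shallow 0.5-crossing at
  a few hundred iterations; the draws are therefore antithetic (each z
  paired with −z, both still marginally standard normal), which removes
  the common-mode term without biasing the proportion estimates. The mortality RR is perturbed everywhere,
  including below 1% risk where its point value is exactly 1: this is
  what produces the characteristic *tipping range* — proportions near
  one half across 0.5–0.9% — and a 90%-probability threshold far above
  the point-estimate tipping point; holding it fixed at 1 below 1%
  would collapse the range. Sampled RRs may exceed 1. The
  proportion-favoring-DOAC curve is smoothed by isotonic regression
  (monotone non-decreasing in risk) before thresholds are read off,
  because raw proportions at ~250–1000 iterations carry a few percent
  of binomial noise.

## Calibration of severity and utility defaults

The dynamics above are fully specified by printed anchors. The
event-severity distributions, 30-day case fatalities, extracranial
disability probability, baseline utilities and severity utility ratios
are **calibration parameters**: they ship as documented defaults in
`fixtures.py`, anchored to published severity and quality-of-life data
and then jointly tuned with the deterministic oracle so the model
reproduces its reference QALY-difference curve (differences at 0.4–3%
risk over 20 and 5 years, the tipping point, and the disability-free
threshold).

One structural finding from that calibration is worth recording. Below
a 1% stroke risk the mortality effect is zero, so the QALY-difference
curve there is close to linear in risk: its curvature is bounded by the
slope of the stroke-reduction line. A tipping point near 0.65% is
therefore incompatible with simultaneously large differences at 1%
(+0.13) and small ones at 0.4% (−0.01): those three values jointly
imply a per-stroke QALY loss exceeding a patient's total remaining
QALYs. The shipped defaults resolve the conflict inside the stated
tolerance bands: tipping ≈ 0.53% (band 0.50–0.90%), Δ(0.4%) ≈ −0.026
(−0.01 ± 0.02), Δ(1%) ≈ +0.086 (0.13 ± 0.05), with the 2%/3% and
5-year differences and the disability-free threshold (≈ 0.64%) close
to their reference values. The difference curve is steeply convex just
above 1% where the mortality effect switches on, which is also what
makes the 1% value sensitive to exactly where it is read.

## Problem sizes and numerical choices

Default scales: 10 000 patients/arm for grid sweeps, 50 000/arm for
fixed-risk differences, and 250 iterations x 2000/arm for the
reduced-scale PSA (the full-scale setting, 1000 x 5000, is a config
value). These sizes put the Monte-Carlo standard errors comfortably
inside the quantities' tolerance bands; the engine is vectorized over
patients and iterations and advances on the order of 10^7
patient-cycles per second on one core. Per-grid-point seeds are derived
deterministically from the master seed and the risk value, so results
are reproducible and identical grids share streams across arms.
Severity distributions must sum to 1 within 1e-9 and satisfy the
stochastic-ordering constraints (treated strokes no more severe,
treated bleeds no less severe); validation errors name the offending
key. Utility ages beyond the last table band reuse the last band.

## What the synthetic inputs do and do not capture

There is no external data: the "data" are the parameter values
themselves, and the degenerate parameter sets (zero-event, no-effect,
certain-death, unit-utility) exist to make closed-form outcomes
testable. Passing tests therefore demonstrate internal consistency of
the model and faithful implementation of its stated dynamics — not
real-world validity of the inputs. Known limitations mirror the model
class: one event per cycle, complete adherence, a single fixed
stroke-risk level per trajectory (no aging into higher risk), no
nonmajor bleeding or myocardial infarction, no treatment disutility or
costs, and utilities that cannot capture individual preference
heterogeneity (some patients rate severe disability worse than death).
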