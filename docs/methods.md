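# Methods

## Model structure

`crcscreen` is a discrete-time (annual-cycle) multistate cohort model of
colorectal cancer (CRC) natural history and screening.  The health states
are: no lesion, non-advanced adenoma, advanced adenoma, preclinical
(asymptomatic, undiagnosed) CRC, clinical (diagnosed) CRC, death from CRC,
and death from other causes.  Clinical CRC is subdivided by mode of
detection (screen- vs symptom-detected) and by integer years since
diagnosis, because the CRC-specific mortality schedule depends on both.

The cohort is propagated as expected state-occupancy fractions rather than
by simulating individuals.  For a finite-state Markov process the expected
occupancy evolves exactly by the one-year transition probabilities, so the
deterministic propagation produces the same expectations as an arbitrarily
large microsimulation while being reproducible bit-for-bit; all outcomes
are scaled to a standard reporting population of 100,000 people alive at
model start.

### Within-year event order

The model applies, in a fixed documented order within each simulated year:

1. the screening event scheduled at the current age, if any;
2. lesion progression, one step along the sequence per year (the
   preclinical-to-clinical transition books a symptom-detected diagnosis);
3. CRC-specific death, applied only to diagnosed CRC substates by mode and
   years since diagnosis (newly diagnosed mass faces its year-0 hazard in
   the diagnosis year);
4. other-cause death, applied multiplicatively to every alive state at the
   all-cause rate;
5. the years-since-diagnosis increment.

Competing risks are therefore composed multiplicatively in that order, not
as joint exponential rates; the order itself is a convention, chosen once
so that results are exactly reproducible.  Screening before progression
means a lesion arising in year *t* is first detectable at the offer in
year *t* + 1.  There is no half-cycle correction.

Preclinical CRC carries no CRC-specific mortality: only diagnosed cancer
does.  Years since diagnosis are tracked up to a cap (default 14 years);
mass surviving past the cap pools in a long-term-survivor substate with
zero excess CRC mortality, reflecting the time-limited nature of
detection-mode-specific survival differences.  The cap is a parameter-set
field, which also lets oracle tests raise it so that a constant
CRC-mortality chain stays exactly age- and duration-independent over a
50-year horizon.

## Screening

Primary colonoscopy detects a fraction `sensitivity(state)` of the
participating mass in each lesion state: detected adenomas are removed
(polypectomy) and the subjects return to the lesion-free state; detected
preclinical cancer becomes screen-detected clinical cancer at years-since-
diagnosis 0.  FIT is modelled as a two-stage filter: participants with a
lesion test positive at the FIT sensitivity for their state, positives
receive a diagnostic colonoscopy whose own sensitivity determines
detection (detected fraction = FIT sensitivity × colonoscopy sensitivity),
and lesion-free participants trigger false-positive diagnostic
colonoscopies at rate 1 − specificity with no state change.  Subjects with
diagnosed CRC and the dead are outside the eligible pool.

Two simplifications are deliberate: subjects re-enter the lesion-free
state after polypectomy and continue on the scenario's ordinary offer
schedule (no separate post-polypectomy surveillance track), and colonoscopy
complications, costs and other harms are not modelled.

## Adherence patterns

Overall adherence over the horizon is
(people screened / people invited) × (tests used / tests offered).
Two pure patterns are implemented:

* **selective(p)** — a fraction *p* attends every offer; the rest never
  attend.  Implemented as two weighted sub-cohorts (weight *p* on the full
  schedule, 1 − *p* unscreened), which makes every cumulative outcome an
  exact convex mixture of the full-adherence and no-screening outcomes.
  This linearity is a structural identity and is asserted to 1e-10.
* **sporadic(A)** — the whole population attends exactly the ages in *A*.
  The "every *k* years" constructor anchors at the first offered age
  (50, 50+k, … within the offer range), the natural reading of an
  unanchored interval.

Matched pairs follow the published pairing of rounded level labels (1/k
selective vs every-k sporadic): because annual FIT from 50 to 75 offers 26
tests, the exact sporadic level |A|/26 can differ from 1/k by up to ~3
percentage points (every-5 gives 6/26 ≈ 23%); levels are matched by the
pairing, not recomputed.

## Outcomes

Cumulative CRC cases, CRC deaths, and years of potential life lost (YPLL)
over the horizon, each per 100,000 starting population, plus percentage
reductions versus the matched no-screening baseline and
sporadic/selective ratios of *prevented* (baseline − scenario) counts.
YPLL weights each CRC death by the remaining life expectancy at the
integer age at death.  Ratios are computed from unrounded prevented
counts; rounding happens only at display time.  A selective scenario that
prevents nothing (within floating precision, relative 1e-9) has its ratio
flagged undefined (NaN) rather than reported.

## Parameters

A parameter set bundles: starting lesion prevalences by sex and age band;
annual transition probabilities per edge of the sequence by sex and age
band; test sensitivities per lesion state and specificity per modality;
all-cause death probabilities, CRC-specific death probabilities by mode
and years since diagnosis, and remaining life expectancy by sex and single
year of age.  Prevalences and transition rates carry optional 95%-CI
columns used by the sensitivity analyses (`point`, `ci-lower`, `ci-upper`
variants); variants are resolved at lookup time so a written parameter
directory always round-trips bit-exactly.

Age bands are half-open [lo, hi); ages at or beyond the last band's upper
edge extrapolate the last band — an explicit, conservative choice for the
80+ ages where source evidence is thin.  The supported age range is
45–100; scenarios run up to 50 years (start 50 → age 100, or the earlier
start at 45 used as a sensitivity analysis).

## Synthetic parameter generation

The registry-derived parameter tables behind the published model are
distributed separately, so the package generates synthetic sets with the
same structure: monotone age trends (log-linear interpolation between
anchor values drawn at ages 50 and 75), women's rates scaled below men's,
test sensitivity increasing along the lesion sequence, Gompertz all-cause
mortality with the life table computed self-consistently from it (curtate
expectation plus a half-year), and CRC mortality declining exponentially
in years since diagnosis with screen-detected hazards at 45% of
symptom-detected ones.  Default ranges were chosen once so that an
unscreened cohort starting at 50 accumulates a lifetime CRC risk of
roughly 4–7% (checked across 26 seeds: 4.0–6.6%), the order of magnitude
of average-risk Western populations, and so that screening moves outcomes
by large, stable margins suitable for tight monotonicity tests.

What the generator does *not* emulate: numerical agreement with any
registry estimate, CRC stage detail, adenoma multiplicity or location,
surveillance colonoscopy, and behavioural adherence dynamics.  Passing
tests therefore demonstrate the correctness and internal consistency of
the machinery and the robustness of the qualitative
sporadic-vs-selective conclusion on structurally realistic inputs — not a
numerical forecast for any real population.

Degenerate sets ("null", "deterministic-chain", "perfect-test",
"useless-test") give closed-form behaviour used as oracles: e.g. with unit
transition rates and no mortality a subject in non-advanced adenoma at age
*a* is diagnosed at exactly *a* + 3, and a zero-sensitivity test makes
every screening scenario reproduce the baseline bit-for-bit.

## Numerical choices

* Mass conservation is asserted to 1e-12 at every step.
* The selective-mixture linearity is exact up to floating summation; the
  suite asserts 1e-10 relative.
* The matrix-power oracle compares the engine to the 50th power of the
  explicit one-year matrix (progression ∘ CRC death ∘ other-cause death)
  for an age-independent chain, at 1e-10 absolute.
* Validation requires every probability in [0, 1], CI bounds bracketing
  point estimates, per-state outflow (progression + all-cause) ≤ 1,
  strictly decreasing life expectancy; softer plausibility checks
  (screen-detected mortality ≤ symptom-detected; colonoscopy sensitivity ≥
  FIT sensitivity) warn rather than fail.

## Known limitations

Annual cycles with single-step progression understate very fast sojourn
times; the FIT two-stage product rule means a positive FIT followed by an
imperfect colonoscopy can miss a lesion, with no short-interval re-test;
no surveillance after polypectomy; no stage structure within CRC; sporadic
schedules are deterministic age sets rather than stochastic attendance
processes; and the ratio comparisons inherit the discreteness of small
offered-age sets (consecutive every-k schedules can share a test count,
producing small local reversals in the ratio-vs-level trend — visible in
published tables of this design as well).
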