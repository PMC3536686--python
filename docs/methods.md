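# Methods

## Model structure

The model is a static decision tree for a birth cohort entering a
newborn hearing screening programme with a four-stage test procedure:

1. **Test 1** — two-stage in-hospital screen (OAE or AABR, then
   confirmatory AABR for bilateral first-stage failures).
2. **Tests 2–3** — office-based ENT re-tests (OAE, AABR or both) for
   newborns who bilaterally failed the previous test and were not lost to
   follow-up.
3. **Test 4** — the pediatric audiologist's diagnostic visit (lump sum +
   middle-ear impedance test + AABR). Bilateral failure here is a
   confirmed, *detected* case. After failing test 2 or test 3 a child may
   also be referred directly to this diagnostic visit ("early diagnosis",
   probabilities `d2`, `d3`); those referrals count as detected with
   certainty and accrue one diagnostic-visit cost.

Exits — not screened, lost to follow-up, pass, unilateral fail — leave the
procedure undetected; pass and unilateral fail are merged into one
complement branch per stage because they behave identically downstream.
Such children may be diagnosed later outside the programme, so they
contribute zero cost and zero effect but stay in the denominator: all
expectations are per cohort newborn. There is no latent disease state —
the model works with *observed* bilateral failures, so test sensitivity
and specificity are out of scope, as are long-term outcomes, QALYs and
discounting (the horizon ends at diagnosis).

The tree has 11 terminal paths. Expected cost and effect are computed both
by closed-form rollback and by enumerating those paths; the two routes are
required to agree to 1e-12 and the terminal probabilities to sum to 1.

## Parameters

* **Probabilities** (14): loss to follow-up before tests 1–4, separately
  per arm; bilateral failure at tests 1–4 (each conditional on attending,
  shared between arms); early-referral probabilities `d2`, `d3`. Each
  carries a 95% CI. Failure probabilities are conditionally independent
  of earlier results given attendance.
* **Stage costs** (EUR per performed test): composed from tariff fee items
  (points × point value) weighted by the modality mix. Fee items are
  rounded to the cent *before* composition — tariffs reimburse whole
  cents, and the composite values (42.22 / 38.99 / 43.39 / 91.83) are
  reproducible only from cent-priced items. Children tested with both
  modalities at stages 2–3 are billed the AABR item.
* **Tracking fee**: the tracking centre's itemised budget (€78,025 per
  period: €65,635 personnel, €12,390 non-personnel) divided by the number
  of newborns screened per period. That denominator is a configuration
  input, defaulting to 17,148 — the value consistent with the published
  €4.55 per newborn — because no source value exists. The fee is charged
  once per newborn who bilaterally fails the first test (attachment
  `fail1`). This choice is deliberate: varying the fee by ±€2.28 moves
  total per-newborn cost by only ≈ €0.02–0.03, which pins the fee's weight
  near P(screened)·P(fail test 1) ≈ 0.006; charging every screened newborn
  (weight ≈ 0.955) is numerically excluded. Alternative attachments
  (`per_screened`, `each_followup`) remain available behind a switch.

All arithmetic is unrounded past that point; rounding (costs to cents,
effects to five decimals, ratios to whole euros) happens only at
reporting, with unrounded values emitted alongside. The per-case cost
(ACER) is additionally offered at display precision — computed from
cent-rounded costs and five-decimal effects — because that is how the
published per-case figures were derived.

Residual differences from the published base case (≈ €0.01–0.02 in costs,
≈ 1% in the ICER: 1,713 vs 1,697) stem from the two-to-three-decimal
precision of the published inputs and the unstated fee-attachment node;
the one-way analysis reproduces all 21 published rows within €0.03,
0.00002 and 2% respectively.

## Sensitivity analyses

* **One-way**: each of the seven key parameters (loss to follow-up before
  tests 2–4 in both arms; the tracking fee) is evaluated at 0.5× and 1.5×
  its base value, *rounded half-up to two decimals first* so the evaluated
  values are exactly the tabulated ones (0.26/0.77, 2.28/6.83, …).
  Probabilities are clamped to [0, 1]. Arm-specific parameters vary only
  within their arm.
* **Structural**: scenario A sets `d2 = 1` (every failed second test goes
  straight to diagnosis); scenario B sets `d2 = 0, d3 = 1`. Whether the
  original scenarios also suspended loss to follow-up before the
  diagnostic visit is unknowable, so these ICERs (≈ €993 and ≈ €1,410) are
  expected to match the published €954 / €1,309 only within ≈ 10%; both
  fall below the base-case ICER, as they must.
* **Probabilistic** (second-order Monte Carlo, default 10,000 iterations):
  every probability is drawn from a beta distribution whose first two
  moments match the point estimate and the symmetric-normal SE implied by
  its CI width (SE = width/3.92; infeasible combinations, SE² ≥ m(1−m),
  are rejected before sampling). Every cost is drawn from a gamma
  distribution with mean at base and a coefficient of variation defaulting
  to 0.2 — the dispersion of the costs is not identified by any source
  number, so the CV is an explicit knob affecting only PSA spread, not any
  deterministic result. Shared parameters use a single draw for both arms
  within an iteration; the arm-specific loss-to-follow-up parameters are
  distinct parameters with their own CIs and are drawn independently.
  Draws are reproducible from a single integer seed.

  Consequence of the CV choice: with CV 0.2 the acceptability of tracking
  at a willingness to pay of €2,500 per additional case is ≈ 0.948 and the
  central 99% of ICER draws spans roughly €950–€3,200 — wider than the
  published scatter (€1,060–€2,769) and acceptability (99.5% at €2,500),
  which evidently used a tighter cost dispersion. The acceptability at
  €2,000 (≈ 0.75) is likewise below the published 83.8%. These are
  properties of the stated uncertainty inputs, not of the sampler.

## Synthetic cohort generator

`cohort.simulate_cohort` draws each newborn's path through the tree with
independent Bernoulli branches at the published probabilities and accrues
the composed stage costs — it emulates the registry's per-child screening
records (screened / failed / attended / referred flags, cost, outcome).
It does **not** emulate latent hearing status, within-family or
within-hospital correlation, calendar time, or per-child modality billing
(a per-child modality draw would change within-stage cost variance only,
never the mean, so composed expected costs are used). Passing tests
therefore demonstrate internal consistency of the model and recoverability
of its parameters from data *of the model's own structure* — not the
fidelity of the tree to any real programme.

`cohort.estimate_params` inverts the generator: each probability is the
appropriate conditional relative frequency (e.g. failing test 2 among
attenders of test 2) with a Wilson 95% CI (Wald available). Stages never
reached give NaN, not zero. At 10⁶ children per arm the re-estimated
parameters reproduce the base-case ICER within ≈ 10%; the binding noise
source is the ≈ 100–500 children who reach tests 3–4 in the no-tracking
arm.

## Numerical and design notes

* Problem sizes: analytic results are exact and instantaneous; validation
  uses 10⁶-child simulations and 100 replicate simulations of 2×10⁵
  children for CI-coverage checks; the PSA default is 10,000 iterations.
* Two-decimal half-up rounding of one-way variation values pre-rounds
  floats to nine decimals so that exact half-cents (1.5 × 0.29 = 0.435)
  round up rather than to even.
* ICER edge cases: a zero incremental effect yields an explicit undefined
  marker, never a division error; sign conflicts are reported as dominance
  flags rather than a misleading ratio; ties at the willingness-to-pay
  threshold count as *not* cost-effective in the CEAC.
* The willingness-to-pay grid defaults to €0–5,000 in €100 steps (the
  range is given, the step is a choice).
* Known limitations: no efficiency frontier beyond the two strategies; no
  EVPI; no unilateral-impairment pathway; no time-to-diagnosis outcome;
  tornado data are exported as tables, not rendered.
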