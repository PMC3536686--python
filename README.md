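# trackcea

Decision-analytic cost-effectiveness of a **tracking system** within a
newborn hearing screening programme.

Universal newborn hearing screening aims to find bilateral hearing
impairment (≥ 35 dB) in the first months of life. A screen-positive newborn
is only helped if the family actually returns for the follow-up tests — and
without an active recall system ("tracking": registry, letters, telephone
calls, public-health office) roughly half of screen-positive children are
lost before a diagnosis is made. This package models that trade-off for
health economists and screening-programme planners: tracking costs money
(≈ €4.55 per newborn screened, charged here to screen-positive children)
but sharply cuts loss to follow-up, so more cases are detected.

## The model

A static decision tree follows one newborn through a four-stage test
procedure. With `s = 1 − p_ltfu1` the probability of being screened,
`f_k` the probability of bilaterally failing test *k* (conditional on
attending), `a_k = 1 − p_ltfu_k` the probability of attending test *k*
after failing test *k−1*, and `d_2, d_3` the probabilities of direct
referral to a pediatric audiologist after failing test 2 or 3, the expected
detected cases per cohort newborn are

```
E = s·f1·a2·f2·[ d2 + (1−d2)·a3·f3·( d3 + (1−d3)·a4·f4 ) ]
```

and expected cost accrues the per-stage test costs (composed from German
DKG-NT / EBM tariff items as points × point value, weighted by the
OAE/AABR modality mix) along every branch, plus the tracking fee in the
tracking arm. The two strategies differ only in the loss-to-follow-up
probabilities and the fee. Strategies are compared by the incremental
cost-effectiveness ratio

```
ICER = (C_tracking − C_no_tracking) / (E_tracking − E_no_tracking)
```

in EUR per additional case of bilateral hearing impairment detected.
Uncertainty is handled three ways: one-way variation of each key parameter
by ±50%, structural scenarios (guaranteed diagnosis after test 2 or 3),
and a second-order Monte Carlo (beta distributions for probabilities
moment-matched to their 95% CIs, gamma distributions for costs) feeding a
cost-effectiveness acceptability curve. An individual-level
microsimulation of the same tree serves as an independent oracle and as a
synthetic-data generator from which all event probabilities can be
re-estimated.

## Worked example

```python
>>> import trackcea as tc
>>> inputs = tc.default_inputs()
>>> t = tc.expected_outcomes(tc.StrategyParams.from_inputs(inputs, "tracking"))
>>> nt = tc.expected_outcomes(tc.StrategyParams.from_inputs(inputs, "no_tracking"))
>>> round(nt.expected_cost, 2), round(nt.expected_effect, 5)
(40.13, 0.00021)
>>> round(t.expected_cost, 2), round(t.expected_effect, 5)
(40.65, 0.00052)
>>> comp = tc.icer(t.expected_cost, t.expected_effect,
...                nt.expected_cost, nt.expected_effect)
>>> round(comp.icer)
1713
```

Screening one newborn costs ≈ €40.13 without tracking and ≈ €40.65 with it;
per 100,000 newborns the programme detects about 21 cases without tracking
and about 52 with it, so each *additional* detected case costs ≈ €1,713.
The same numbers come from the command line:

```bash
trackcea basecase            # per-arm costs, effects, ACERs, ICER
trackcea univariate          # 7 parameters × {−50%, base, +50%}
trackcea structural          # guaranteed-early-diagnosis scenarios
trackcea psa --n-iter 10000 --seed 0
trackcea ceac --seed 0       # acceptability curve data
trackcea simulate --cohort-size 100000 --arm tracking
trackcea all --out-dir results
```

or from the numbered drivers in `analysis/` (`01_cost_inputs.py` …
`06_microsim_validation.py`), which write their tables under `results/`.

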