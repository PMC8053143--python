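# Methods

This note records the model as implemented: its assumptions, the places
where the published description leaves structure open and what this package
chose, the synthetic mortality fixture and its consequences, and the
numerical conventions. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Model structure

An individual state-transition (microsimulation) model with annual cycles.
Each woman starts at age 70, 75, or 80 with a prior vertebral fracture and
is followed until death or age 105. Within a cycle the order of operations
is fixed:

1. **Treatment continuation** is sampled (while on a drug) from the annual
   continuation probability `S(y)/S(y−1)` implied by the cumulative
   persistence curve. A woman benefits from treatment only if she persists
   to the end of the cycle; in the cycle she discontinues, her fracture risk
   multipliers are 1.
2. **Relative-risk multipliers** are computed: on treatment,
   `1 − a(y)·(1 − RR)`; in the offset phase, a linear interpolation from
   the effective RR of her final persisted year back to 1 over the offset
   length; otherwise 1.
3. **Fracture** is sampled — hip first, then vertebral conditional on no
   hip. At most one fracture per cycle; at most two hip fractures per
   lifetime; vertebral fractures are unlimited.
4. **Death** is sampled last, so the fracture-year excess hazard applies in
   the cycle of the fracture itself.
5. **Costs and utility** for the cycle are written to a ledger.

Events are end-of-cycle: a death cycle contributes zero utility and no
half-cycle correction is applied, but all of that cycle's costs (treatment,
fracture, long-term care) are booked — the woman was alive during the year.

## Treatment phases and schedules

* **Sequential strategy**: teriparatide years 1–2, then alendronate years
  3–10. Only completers of the teriparatide phase start alendronate; a
  teriparatide discontinuer exits therapy and enters the (proportional)
  teriparatide offset. On switching, the alendronate adherence and
  persistence schedules restart at their year-1 values, and the alendronate
  initiation visit fee is charged once.
* **Monotherapy**: alendronate years 1–10.
* **Persistence interpolation**: the alendronate curve is anchored at 55%
  (year 1) and 10% (year 7); between anchors a constant annual continuation
  ratio `(0.10/0.55)^(1/6)` is used — the constant-hazard reading of two
  cumulative anchors. No dropout occurs from year 8 onward except death.
* **Adherence interpolation**: alendronate declines linearly from 70.6%
  (year 1) to 60.9% (year 5) and stays flat; teriparatide uses 70.2% and
  67.8% in its two years. The underlying study values are used rather than
  their two-decimal roundings because the schedule construction is defined
  in terms of them.
* **Offset**: after stopping with `y` of `D` years completed, risk returns
  linearly to baseline over `offset_full × y/D` years (full offsets:
  teriparatide 2 years — 3 in the scenario analysis — alendronate 10).
  The decay starts from the effective RR of the final persisted year; a
  woman who never completes a year has a vacuous offset.

Discontinuation costs: in any discontinuation year the woman is charged one
3-month drug supply (a single filled prescription, annual cost / 4) and one
physician visit, and nothing else. The published rule states the 3-month
supply for first-year discontinuers and is silent about later years; with
annual persistence sampling, every discontinuation is resolved at a year
boundary, so the same single-prescription charge is applied uniformly.

## Mortality

Baseline mortality is a life-table `qx` converted to a hazard
`h = −ln(1 − qx)`. After any hip fracture the hazard is multiplied by
`m = 1 + f·(RH − 1)` with `RH = 2.87` while the fracture-year clock reads
zero (a recurrent hip fracture resets it) and `1.73` lifelong thereafter;
`f = 0.25` is the fraction of observed post-hip excess mortality attributed
to the fracture itself rather than comorbidity. In the
vertebral-excess-mortality scenario the identical construction applies to
vertebral fractures; when both histories exist the two multipliers combine
on the hazard scale.

## Utilities and costs

Cycle utility = age-band baseline EQ-5D (0.862 / 0.810 / 0.771 / 0.769 /
0.684 for 65–69 / 70–74 / 75–79 / 80–84 / 85+) × hip multiplier × vertebral
multiplier, where each multiplier is the first-year value in a fracture
cycle and the lifelong value in every later cycle.

Healthcare-sector costs while persisting: annual drug cost × adherence,
prescription charge, four physician visits (the drug's first visit at the
initiation fee), two blood tests (¥2,900 each), and a ¥4,500 DXA scan at the
end of treatment years 2, 5, and 10 (counted over the whole strategy, and
only while still on treatment). Fracture treatment costs: hip ¥1,726,000;
first in-model clinical vertebral fracture ¥420,000 regardless of the
baseline fracture's type; subsequent vertebral ¥842,000. No visit or test
costs accrue during the offset phase.

Long-term-care (non-healthcare sector) costs: ¥876,000/year from the first
hip fracture until death, or ¥213,000/year in the post-vertebral state.
When both states apply only the hip amount is charged — the larger single
care package rather than the sum, to avoid double-counting care for the
same person. In the cycle of the state-defining first fracture, half the
annual amount is charged.

Both cost streams and QALYs are discounted at 2%/year with integer-cycle
exponents, cycle 0 undiscounted. All accounting is in 2020 yen; dollars are
derived at ¥105/$ for reporting only, ICERs rounded to the nearest $100 and
costs to the nearest $10 for display (raw values retained in CSV/JSON).

## Sensitivity analyses

Every varied parameter has a stable identifier in
`osteocea.params.PARAM_REGISTRY` carrying its deterministic range and
probabilistic distribution:

* Efficacy RRs and disutility multipliers: beta distributions fitted so the
  2.5%/97.5% quantiles equal the published 95% CI bounds (the bounds are the
  only stated facts; mean and mode are left free).
* Prior-fracture RRs and mortality relative hazards: gamma, fitted the same
  way (shape via a 1-D root find on the scale-free quantile ratio).
* First-year adherence: triangular on the printed range; the ratio of the
  drawn value to the year-1 base rescales the whole schedule, capped at 1.
* Persistence: a ±15% triangular multiplier on the annual continuation
  rates, capped at 1.
* Fracture medical costs and long-term-care costs: two grouped ±50%
  triangular multipliers (one per printed block), preserving the published
  row grouping; incidence: ±10% (hip) and ±25% (vertebral) triangular
  multipliers for the PSA, ±50% deterministic ranges; baseline utilities: a
  single ±15% multiplier capped at 1; attributable fraction: triangular
  0–0.5; discount rate: one triangular 0–4% draw applied to both costs and
  QALYs. Efficacy RRs are sampled independently per printed row.

Common random numbers are used throughout: each woman's random stream is
derived from (seed, index) with a fixed per-cycle draw layout
(continuation, hip, vert, death), so the same seed yields aligned histories
across strategies, sweep grid points, and PSA simulations. An identity grid
point therefore reproduces the base case bit-for-bit, and threshold
estimates (e.g. the smallest teriparatide discount that is cost-effective)
are stable at moderate cohort sizes. The price sweep leaves event
trajectories untouched (price affects no probability), so its QALY
differences are exactly constant across the grid.

The published PSA design is 1000 simulations × 100,000 trials; the
package's desk-scale default is 200 × 10,000 (`osteocea psa --sims/--trials`
to change). Test-suite runs use a few thousand women per arm — large enough
to separate the directional contrasts they assert from Monte-Carlo noise —
and the acceptance script uses the full 100,000 per arm for the validation
quantity.

## Synthetic mortality fixture

No national life table is distributed with the package. The default
mortality input is a Gompertz–Makeham schedule
`qx(age) = 1 − exp(−(c + a·e^{b·age}))` with a = 1e−5, b = 0.11, c = 2e−4 —
a standard monotone adult-mortality family with invented constants, chosen
so that death by age 105 from any starting age of 70–80 is >99%. It is a
fixture, not an estimate of Japanese female mortality, and it is
substantially heavier than the 2018 Japanese schedule at these ages.
Consequently, runs on the synthetic table validate the model's mechanics
(near-certain death by the horizon, event accounting, directional
responses) but not the published magnitudes: lifetime QALYs, fracture
probabilities, and ICER levels all shift when real mortality is supplied.
Exact reproduction runs require the real life table as a user-supplied
`age,qx` CSV (abridged 5-year tables are expanded assuming constant qx
within each band — which part the original analysis used is not stated;
single-year expansion is assumed).

## Numerical conventions and degenerate inputs

* Beta CI fitting: 2-D `scipy.optimize.root` in log-shape space seeded from
  the normal approximation; fits are verified to relative 1e−6 and cached.
  Near-degenerate intervals concentrate mass at the midpoint as expected.
* Rate-to-probability conversion `1 − exp(−r)` throughout (incidence tables
  are person-year rates); at these magnitudes the difference from using the
  rate directly is below 1%.
* Adherence/persistence scaling above 1 is capped at 1 at evaluation time.
* Cohort standard errors are sample SD/√n of the discounted per-woman
  totals.
* ICERs are only formed within a quadrant; dominance is labelled, never
  silently divided. A zero QALY difference with positive cost difference is
  reported as dominated (infinite ICER), not an error.

## Known limitations

* Only hip and clinical vertebral fractures are modelled (no forearm or
  humerus fractures, no morphometric incidence); adverse events and
  BMD-based risk stratification are out of scope.
* Costs are age-invariant; the societal perspective is not implemented.
* The one-fracture-per-cycle rule with hip precedence slightly undercounts
  vertebral fractures in high-risk cycles.
* No efficiency frontier: comparisons are strictly pairwise, and no EVPI is
  computed.
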