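# Methods

## Model structure

A discrete-time Markov cohort model with weekly cycles (exactly 1/52 year per
cycle; a 50-year horizon is 2600 cycles). States:

* `NONEXAC` — non-exacerbation; the whole cohort starts here at age 41.
* `EXAC_SCS`, `EXAC_ED_SCS`, `EXAC_INPATIENT` — severe exacerbation,
  modelled as three typed transient sub-states (occupancy lasts exactly one
  cycle; survivors return to `NONEXAC`; no exacerbation→exacerbation
  persistence). Splitting by management type is equivalent in expectation to
  one state with expected-value costs but keeps per-type mortality and
  disutility explicit. The type shares are fixed over the horizon.
* `DEATH` — absorbing; accrues no cost and no utility (death-related costs
  excluded).
* Variants: `WITHDRAWN` (absorbing except to death; accrues stepped-up drug
  cost and the non-exacerbation utility) and `MODERATE_EXAC` (transient,
  one-cycle stay), both off in the base case.

Transitions from `NONEXAC`: to exacerbation sub-state *i* with probability
`(1 − exp(−r/52))·share_i` where `r` is the arm's annual severe exacerbation
rate; to death with the background weekly probability; the remainder stays.
Treatment effects are fixed (no waning). From an exacerbation sub-state the
death probability is background **plus** the weekly-converted annual
asthma-death risk of that type (asthma-related death occurs only from
exacerbation states), clamped to ≤ 1; the remainder returns to `NONEXAC`.

Rate→probability conversions use `p = 1 − exp(−r/52)`; probability→
probability conversions use compounding `1 − (1 − p)^{1/52}`, which
preserves probability semantics (0↦0, 1↦1, monotone). Background mortality
is the sex-mix-weighted average of the per-sex weekly conversions; the
life-table row switches at integer ages while age itself advances
continuously. The cohort is a sex-mix-weighted average (default 50 % female
— the source trials do not report the mix) rather than two parallel cohorts;
the difference is second order because the weekly probabilities are tiny.

## Accrual conventions

Costs and QALYs are accrued on **start-of-cycle occupancy**, discounted by
`(1 + rate)^{−t/52}` at cycle index `t` (1.5 %/year for both costs and
outcomes by default). No half-cycle correction by default; a
`half_cycle_correction` flag averages start- and end-of-cycle occupancy when
wanted, and is off for all reproduction runs. Per cycle:

* **Drugs**: alive, non-withdrawn occupancy × per-day acquisition cost × 7.0
  days (a literal weekly cycle, not 365.25/52). Per-day costs are kept
  unrounded internally (e.g. $0.391560 and $0.728917/day); rounding to cents
  is display-only.
* **Monitoring (non-exacerbation state cost)**: charged to *all alive*
  occupancy — patients experiencing an exacerbation still incur the weekly
  monitoring cost. The printed $38.40 is interpreted as **per year**
  (38.40/52 per cycle) by default: the published category total
  (≈ $1,146 over ≈ 29.9 discounted life-years) is consistent only with the
  annual reading, although the input table labels it weekly. A `per_week`
  reading remains selectable via `EconomicInputs.nonexac_cost_basis`.
* **Severe exacerbations**: per-type occupancy × direct event cost
  ($155.14 / $490.81 / $9,399.94).
* **Adverse events**: `NONEXAC` occupancy × Σ (annual proportion / 52 ×
  cost per event). The printed annual proportions are read as expected
  annual event counts allocated uniformly over the year's cycles; compounding
  conversion would slightly overstate event counts (the proportions describe
  patients with ≥ 1 event). AEs attach to the non-exacerbation state only,
  for costs and (zero-by-default) disutilities alike, since the rates are
  defined for that state.
* **QALYs**: utility-weighted occupancy / 52, with utility 0.867 in
  `NONEXAC` (and `WITHDRAWN`), plus the per-type disutility during an
  exacerbation cycle (−0.10 / −0.15 / −0.20; moderate −0.05) — disutilities
  apply for exactly the one-cycle duration of the event.
* **Societal perspective** (Scenario 5): adds alive occupancy × 0.19 lost
  work-days per year / 52 × daily wage. The default wage ($166.84/day) is
  **back-solved** so the productivity loss is ≈ $31.7 per patient-year,
  matching the published societal totals; it is a calibrated placeholder and
  overridable.

## Synthetic inputs and what they imply

Two inputs are not publicly deposited and are replaced by synthetic,
clearly flagged fixtures:

1. **Life table.** Background mortality follows a Gompertz–Makeham law
   `h(age) = makeham + a·e^{b·age}` (male hazard ×1.5, doubling time
   ≈ 7.3 years — a realistic contemporary shape). The hazard *level* is
   calibrated with Brent's method so the discounted life expectancy from age
   41 at 1.5 %/year over the 50-year horizon equals **29.92 years**, the
   value implied by the published discounted QALY totals (25.923 ≈
   0.867 × LY minus small exacerbation-disutility and asthma-mortality
   corrections). Any real `age,sex,qx` table can be supplied instead via
   CSV.
2. **Asthma-mortality risks per exacerbation type.** Placeholders
   SCS-only 0.2 %, ED+SCS 2.53 %, inpatient 5 % (annual risks). The level
   and split are back-solved so the deterministic 50-year incremental QALY
   equals the published 0.002; the ordering (inpatient > ED+SCS ≫ SCS-only,
   all ≤ 5 %) keeps out-of-hospital exacerbation mortality high, consistent
   with national reviews finding most asthma deaths occur without hospital
   admission. Because the intervention arm has the *higher* inpatient share,
   the published QALY gain is only reachable with substantial ED+SCS
   mortality — this is the single most influential synthetic assumption.

Consequently, passing reproduction tests show that the model mechanics
(transitions, accrual, discounting, uncertainty propagation) reproduce the
published analysis *given inputs consistent with it*; they do not validate
the synthetic mortality inputs themselves against Canadian data.

## Known input/result inconsistencies

* The published adverse-event category totals ($28,013.94 / $34,384.33) are
  not derivable from the published per-event inputs under any
  annual→weekly conversion: a direct calculation gives ≈ +7 % for the
  intervention arm and ≈ −3 % for the comparator, in opposite directions.
  This is the dominant reason the deterministic incremental cost computed
  from the published inputs is ≈ −$6,800 rather than the published
  −$9,882.90 (the AE increment is −$3.3k from the inputs vs −$6.4k in the
  results table). Reproduction tests therefore check each cost category at
  ±3 % (adverse events ±10 %) and incremental costs within those category
  tolerances propagated.
* The PSA beta printed for the intervention's viral-URTI proportion
  (α = 95.53, β = 1157.83) has mean 0.0762, not the 0.074 point estimate;
  every other printed AE beta matches its point value exactly. Printed
  values are used verbatim.
* The printed disutility betas (e.g. α = 110.1, β = 1211.1 for −0.10) have
  analytic means (0.083 / 0.115 / 0.143) inconsistent with their point
  estimates; they are likewise used verbatim, which pulls the PSA mean
  incremental QALY slightly below the deterministic value.
* These input-level gaps also bound the CEAC: the model yields ≈ 0.92 at
  $50,000/QALY and ≈ 0.92–0.93 at $100,000 versus the published 94 %/95 %,
  because the mean cost saving is smaller while its spread is similar.

## Probabilistic sensitivity analysis

1000 Monte Carlo iterations by default. Each uncertain input is drawn from
its assigned distribution: printed betas for exacerbation rates, AE
proportions, utility, and (negated) disutilities; printed gammas for
inhalations/day; Dirichlet for the type shares (concentrations = shares ×
100, a documented configurable default — none are printed); gamma for event
costs, monitoring cost and start age; beta for the asthma-death placeholders.
Where no parameters are printed, the fallback is a **10 % coefficient of
variation** (method of moments) — this reading of the "variance-to-mean
10 %" rule reproduces the printed `Gamma(shape = 100)` specifications
exactly; a literal variance/mean reading is available by passing the
corresponding CV.

Drug acquisition costs are fixed by design and never sampled. Parameters on
shared records (exacerbation-type costs, disutilities, death risks, utility,
monitoring cost) are drawn once per iteration and applied to both arms;
per-arm records (rates, shares, AE proportions *and AE unit costs*, doses)
are drawn independently per arm. Each iteration consumes its own random
stream spawned from the master seed, so results are bit-identical under a
fixed seed and adding a parameter does not reshuffle other iterations.

The CEAC counts strictly positive net monetary benefit (`NMB = 0` counts as
not cost-effective — deterministic and conservative); at λ = 0 it equals the
fraction of cost-saving draws exactly. The default λ grid is $0–$200,000 in
$1,000 steps.

## One-way sensitivity and scenarios

The tornado analysis re-runs the deterministic model at each parameter's
printed lower/upper bound (rates, start age, event costs, monitoring cost,
utility, disutilities, ICS dose, discount 0 %/3 %), everything else at base,
reporting incremental-cost and NMB swings sorted by cost swing. Withdrawal
rates have no printed bounds and need the structural variant, so they are
exercised through the withdrawal-variant API rather than as tornado rows.

The eight scenarios are declarative overrides (discounts 0 %/3 %; horizons
2 y/10 y; societal perspective; budesonide as maintenance ICS — its price is
a back-solved placeholder of ≈ $0.572/inhalation since none is published,
so that scenario's check is qualitative; ICS utilization 62.8 %; AEs
removed). They can run probabilistically (the published mode) or
deterministically; reproduction runs use deterministic mode, whose value is
the PSA mean up to Monte-Carlo error, at a fraction of the cost. The
scenario table's "dominant strategy" column is decided at the table's print
precision (dollars, 3-decimal QALYs): at short horizons the exact
incremental QALY is a ~10⁻⁵ negative (disutilities bite before the mortality
benefit accrues) while the published table reports 0.000 and dominance.
Exact quadrant labels remain available from `incremental_result`.

## Numerical choices and degenerate inputs

* Occupancy conservation is enforced (row sums within 1e-9); transition rows
  are built with an explicit remainder so they sum to 1 to machine precision.
* The engine matches an independent scalar per-cycle oracle to 1e-12 on
  short horizons (tested), including both structural variants.
* Validation collects *all* invariant violations, not just the first.
* Ages beyond the life table's terminal row clamp to it with a logged
  warning; hazards saturating `qx = 1` before the terminal age are clamped
  with a warning.
* Parameter files round-trip through YAML at full float precision
  (bit-identical re-save).
* Ties: ΔQ = 0 with ΔC ≠ 0 yields a cost-difference-only verdict, never an
  ICER; ΔC = ΔQ = 0 is a tie.

## Problem sizes

Default runs: 2600 weekly cycles per arm (50 years), 1000 PSA iterations,
13 tornado parameters, 8 scenarios. A two-arm deterministic evaluation takes
≈ 6 ms; the full 1000-iteration PSA ≈ 15 s on one CPU. Reproduction
scripts run the scenarios deterministically and the PSA at n = 1000.

## Limitations

Cohort-level (no microsimulation); no time-in-state or sequence dependence;
fixed treatment effect over 50 years extrapolated from 1-year trials; no
correlated parameter sampling; no EVPI; two strategies only. The synthetic
life table and asthma-mortality placeholders stand in for unavailable
national inputs — analyses of real decisions should substitute Statistics
Canada life tables and literature-based mortality risks through the
documented CSV/YAML interfaces.
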