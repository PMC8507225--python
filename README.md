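# asthma-cea

A Markov cohort cost-utility model comparing **as-needed
budesonide-formoterol** against **low-dose maintenance inhaled corticosteroid
(ICS) plus as-needed SABA** in mild asthma, from the Canadian public-payer
perspective (2019 CAD). It is written for health economists and modellers who
want a reproducible, scriptable implementation of this comparison: the
deterministic base case, a probabilistic sensitivity analysis (PSA) with
cost-effectiveness acceptability curves (CEAC), one-way tornado analysis, and
eight scenario/structural variants.

## The model

A discrete-time cohort model with weekly cycles over a 50-year horizon.
States: *non-exacerbation* (everyone starts here at age 41), three transient
*severe exacerbation* states (systemic corticosteroids only; emergency
department + SCS; inpatient), and absorbing *death*; optional variants add a
*withdrawal* state and a transient *moderate exacerbation* state.

Annual severe-exacerbation rates (0.11 vs 0.12 events/person-year) convert to
weekly probabilities as `p = 1 − exp(−r/52)` and split over the three
management types with fixed arm-specific shares. Mortality combines
age-/sex-specific background risk `q_x` (converted weekly by compounding,
`1 − (1 − q_x)^{1/52}`) with an asthma-related risk that applies only during
exacerbation cycles. Each cycle accrues drug acquisition costs, monitoring
costs, event costs, adverse-event (AE) costs and utility-weighted life-years
(utility 0.867; per-type exacerbation disutilities −0.10/−0.15/−0.20),
discounted at 1.5 %/year. The headline quantities are the discounted
incremental cost ΔC and incremental QALYs ΔQ, the ICER ΔC/ΔQ or a dominance
verdict, the net monetary benefit `λ·ΔQ − ΔC`, and the CEAC
`P(λ·ΔQ − ΔC > 0)` over willingness-to-pay values λ.

No national life table or supplementary asthma-mortality table is bundled;
the package generates a calibrated Gompertz–Makeham life table and carries
clearly flagged FIXTURE placeholders for the asthma-mortality risks (see
`docs/methods.md` for exactly what is synthetic and what that implies).

## Worked example

```bash
asthma-cea base-case --out-dir results/
```

prints the deterministic 50-year decomposition (costs in 2019 CAD per
patient, QALYs discounted at 1.5 %/year):

```
      category cost_intervention cost_comparator incremental_cost qaly_intervention qaly_comparator incremental_qaly
       nonexac          1,148.54        1,148.49             0.06            25.877          25.871            0.006
   severe_exac          3,015.26        2,852.48           162.78             0.048           0.052           -0.004
         drugs          4,263.01        7,935.50        -3,672.49
adverse_events         30,045.54       33,336.67        -3,291.13             0.000           0.000            0.000
         total         38,472.35       45,273.13        -6,800.78            25.925          25.923            0.002

incremental cost -6,800.78, incremental QALY 0.002 -> as-needed budesonide-formoterol
```

Reading the output: as-needed budesonide-formoterol saves about $6,800 per
patient over 50 years — mostly lower drug-acquisition and adverse-event
costs — while gaining 0.002 QALYs (slightly fewer exacerbations and fewer
exacerbation-related deaths), so it *dominates* the maintenance-ICS strategy:
no ICER is reported for a cheaper, more effective option.

The same analysis is available as a library:

```python
import asthma_cea as ac

params = ac.default_parameter_set()
life_table = ac.default_life_table()
result = ac.evaluate(params, ac.RunConfig(), life_table)
psa = ac.run_psa(params, ac.RunConfig(), life_table, n=1000, seed=1)
print(result.incremental_cost, psa.ceac.at(50_000.0))
```

Other commands: `asthma-cea psa` (CE plane, CEAC, per-iteration export),
`asthma-cea dsa` (tornado table over the published one-way ranges),
`asthma-cea scenarios` (the eight published scenarios), and
`asthma-cea init-inputs` (writes the editable parameter YAML and life-table
CSV so you can substitute your own inputs).

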