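# bpcea

Markov cohort cost-effectiveness model of **intensive (SBP 110–130 mm Hg) vs
standard (130–150 mm Hg) blood pressure control** in adults aged 66+ with
hypertension at high cardiovascular risk, for health economists and
modellers who want a tested, scriptable re-analysis pipeline rather than a
spreadsheet.

The model follows the STEP-trial-based evaluation design: a deterministic
yearly-cycle cohort moves through six health states — event-free, chronic
coronary heart disease, post-stroke, chronic heart failure, chronic atrial
fibrillation, and death (split internally into cardiovascular and
non-cardiovascular causes) — accruing direct medical costs and
quality-adjusted life-years (QALYs) from age 66 until extinction.  The
first four cycles use yearly transition probabilities estimated from the
trial; afterwards cardiovascular risk is extrapolated with a
proportional-hazards risk equation (SCORE2-style) and non-cardiovascular
death comes from a national life table as a competing risk.

## Model core

Yearly probabilities and rates interconvert under constant hazards,
`r = −ln(1−p)/t`, `p = 1 − e^{−rt}`; all blending and competing-risk
arithmetic happens in rate space.  Ten-year cardiovascular risk is
`1 − S₀^{exp(Σᵢ βᵢ(xᵢ − x̄ᵢ))}`, annualized and split across the six event
types by each arm's trial event mix.  Arm-level effectiveness mixes
on-target and off-target patients: during the trial by the observed
target-attainment fractions (70% / 75%), afterwards by the adherence
scenario (base 70/75, worst 0/100, best 100/75), with the off-target
fraction at standard-arm rates.  Outcomes are summarized as

- **ICER** = ΔC/ΔE (costs per QALY gained),
- **NMB(λ)** = λ·ΔE − ΔC at each willingness-to-pay threshold,
- cardiovascular **events averted** per 1000 patients,

with one-way (±10% tornado) and probabilistic sensitivity analysis
(moment-matched Beta/Gamma draws, cost-effectiveness acceptability curve,
CE-plane quadrants), a 12-scenario battery per country and subgroup strata.

## Worked example

`python examples/01_base_case.py` (synthetic China-like inputs, seed 0):

```
Lifetime horizon, CN, discount 3.0%
  intensive: cost     125205 CNY   QALYs 10.261
  standard : cost     113357 CNY   QALYs 10.080
  increments: dC +11848 CNY, dE +0.181 QALYs
  ICER 65,281 CNY/QALY  (dominance: none)
  NMB at WTP 89,300: +4,359 CNY  -> cost-effective
  NMB at WTP 267,900: +36,775 CNY  -> cost-effective
  cardiovascular events averted: 223 per 1000 patients
```

The intensive target costs ¥11 848 more per patient over a lifetime and
returns 0.181 QALYs — ¥65 281 per QALY gained, below the lower
willingness-to-pay threshold (1× GDP per capita), so the strategy is
cost-effective under these synthetic costs.  The other scripts in
`examples/` demonstrate trial-period validation, the PSA/CEAC, the tornado
ranking, the scenario/subgroup batteries and the text-file input bundles.
Costs and utilities in the synthetic bundles are order-of-magnitude
plausible stand-ins, not national estimates; swap in real tables via the
YAML/CSV interface (`examples/06_synthetic_inputs.py`).

A thin CLI wraps the same library:

```bash
bpcea run-base --country CN --synthetic --seed 7 --outdir out/
bpcea validate --country CN --synthetic
bpcea run-psa --country UK --synthetic --n 1000
```

## Layout

- `src/bpcea/params.py` — domain types, table I/O, probability↔rate calculus
- `src/bpcea/markov.py` — the yearly-cycle cohort engine
- `src/bpcea/risk.py` — risk equations, competing mortality, adherence blending
- `src/bpcea/econ.py` — discounting, accrual, ICER/NMB, events averted
- `src/bpcea/sensitivity.py` — tornado and probabilistic sensitivity analysis
- `src/bpcea/scenarios.py` — scenario battery and subgroup runners
- `src/bpcea/synthetic.py` — synthetic input generation (trial rates embedded)
- `src/bpcea/validation.py` — trial-period incidence validation
- `docs/methods.md` — modelling assumptions, parameters and limitations
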