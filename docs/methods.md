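# Methods

## Model structure

A closed cohort of patients aged 66 with hypertension and high
cardiovascular risk is simulated in yearly cycles under two strategies:
intensive systolic blood-pressure control (target 110–130 mm Hg) and
standard control (130–150 mm Hg).  Health states are event-free
(`no_cvd`), four chronic sequela states (`chronic_chd`, `post_stroke`,
`chronic_hf`, `chronic_af`) and death.  Death is represented internally by
two absorbing states, `dead_cv` and `dead_noncv`, so that cardiovascular
deaths (an outcome event) and life-table competing mortality can be
tallied separately; any "death" summary is their union.

Within a cycle, events resolve in a fixed order, each drawn from the mass
surviving the previous step:

1. **Death.**  Cardiovascular and non-cardiovascular death rates compete
   in rate space; the combined probability is split by rate share.
2. **One acute cardiovascular event at most** (stroke, acute coronary
   syndrome, acute heart failure, coronary revascularization, atrial
   fibrillation) as a competing multinomial built from the marginal yearly
   rates, with the residual staying put.  The new event's sequela state
   becomes the person's state ("last event defines the state"); one-year
   cycles and small yearly risks make the one-event-per-cycle
   approximation mild.
3. **Adverse events** (hypotension, dizziness, syncope, fracture, acute
   kidney injury): state-preserving, affecting only costs and utilities.

The engine is a deterministic fraction-of-cohort recursion; the nominal
cohort of 10 000 only scales reported counts.  A seeded individual-level
microsimulation using the same transition matrices serves as an
independent oracle in the test suite (agreement within 3 Monte Carlo
standard errors at 200 000 individuals).

## Trial phase (cycles 1–4)

Yearly transition probabilities for all thirteen events come from the
trial table embedded in `synthetic.py`.  Arm-level effectiveness is a
fixed mix of patients at and off the assigned target: at the end of the
trial roughly 70% of the intensive arm and 75% of the standard arm had
reached target, so each arm's effective rate is the rate-space blend of
its own table rates (attainment fraction) with standard-arm rates
(remainder).  This mix is what lets a 4-year run reproduce the reported
model-validation incidences (≈1.14 and ≈1.39 per 100 person-years against
observed 1.00 and 1.40); with unblended table rates the intensive arm
lands near 0.99.  The attainment fractions are structural constants of
the trial phase; the *adherence scenario* varies only the post-trial mix,
which keeps the worst-case scenario's meaning ("intensive arm abandons
treatment immediately after the trial") intact.

Validation incidence counts first composite events (the six
cardiovascular event types leaving the event-free state) over event-free
person-years; exits contribute half a cycle at risk (mid-cycle timing,
switchable to full-cycle).

## Post-trial extrapolation

After cycle 4 the standard arm's composite cardiovascular rate follows
the proportional-hazards risk equation evaluated at the cohort's current
age: ten-year risk `scale × (1 − S0^exp(β·(x − x̄)))`, annualized via the
rate transform.  The intensive arm applies the trial's composite rate
ratio (≈0.66) to that level — the proportional treatment effect is
carried forward while the *level* comes from the risk equation, which is
deliberately higher than the protocolized within-trial rates (risk
equations describe routine-care older populations).  The composite is
split across the six event types by each arm's trial event mix in rate
space, so per-event rates sum exactly to the composite rate.  Adverse
event probabilities are held at trial values (flagged option), and
adherence blending works exactly as in the trial phase but with the
scenario fractions.  A degenerate risk equation (zero predicted risk with
non-zero trial risk) triggers a flat extrapolation of trial rates with a
logged warning rather than an error.

Non-cardiovascular death is the life-table all-cause probability minus
the modelled cardiovascular death, subtracted in rate space and floored
at zero; ages beyond the life table (or past the terminal age, default
100) have death probability 1.

Chronic states carry two multipliers on cardiovascular rates:
`repeated_cvd_multiplier` (default 1 — recurrent event risk equals
first-event risk, the base-case assumption, varied in scenarios) and
`chronic_cv_death_multiplier` (default 4) for the excess case fatality of
established cardiovascular disease.  The second is a structural parameter
this package adds: without it, averting a nonfatal event buys almost no
survival and the QALY gain collapses to the small fatal share of the
composite, which contradicts both the epidemiology of post-stroke/heart
failure survival and the magnitude of QALY gains such models report.

## Costs, utilities, discounting

Costs are health-care-payer, one currency per country: yearly
intervention cost per arm (drugs, visits, monitoring; blended across the
on-/off-target mix like the event rates), one-time acute-event costs,
yearly chronic-state costs, and a yearly background cost for all alive
states.  Utilities are additive: baseline 0.80 at 66 minus 0.003 per year
of age minus a chronic-state decrement; acute events subtract
`decrement × weeks/52` in the event cycle only (acute kidney injury 4
weeks, fracture 12, other adverse events 2, acute cardiovascular events 4
— all < 1 cycle).  Whether the age decrement should be multiplicative is
genuinely open; additive is implemented and documented here.

Accrual uses start-of-cycle occupancy (no half-cycle correction by
default; a flag enables occupancy averaging), so chronic-state costs and
utilities begin the cycle *after* the causing event, while acute costs
and decrements land in the event cycle.  Costs and QALYs share one
discount rate per country (3.0% China/US, 3.5% UK) with the first cycle
undiscounted: cycle k carries `(1+d)^−(k−1)`.  This convention makes the
two-state model's discounted QALYs equal the geometric series
`u(1+d)/(d+p)` exactly, which the tests exploit.

ICER is reported only when ΔE ≠ 0, with dominance flags otherwise;
reported ICERs round half-away-from-zero to whole currency units.
Purchasing-power conversion to USD is a display-only multiplier.

## Sensitivity analysis

*One-way*: every scalar input (probability means, costs, utilities,
discount rate) is rerun at ×0.9 and ×1.1 (probabilities and utilities
capped at 1); parameters are ranked by ICER interval width.  Perturbations
producing invalid inputs are skipped with a warning.

*Probabilistic*: n independent draws — Beta moment-matched to each
probability's (mean, SD); log-normal rows moment-matched log-normal;
Gamma for costs (coefficient of variation 0.20); Beta for the baseline
utility (SD 0.03) and decrements (20% relative).  An SD incompatible with
the Beta support falls back to a clipped normal with a warning; draws
failing validation are excluded and counted, not resampled, preserving
seed reproducibility.  The CEAC is the fraction of retained draws with
strictly positive NMB (ties count against), evaluated on 101 points from
0 to 1.5× the upper threshold plus the exact thresholds.  Parameters are
drawn independently; no correlation structure is imposed.

## Scenarios and subgroups

The packaged battery (`data/scenarios.yaml`) holds twelve named scenarios
— adherence best/worst, discount 0%/5%, repeated-event risk ×1.5/×2, a
trial-period hazard ratio of 0.68 on the intensive arm (the older-patient
effect reported in the other major intensive-control trial), 10- and
20-year horizons, and ±25%/−20% post-trial risk-level scaling standing in
for substituting higher-/lower-predicting risk equations (with the level
anchored to the equation, swapping coefficient files changes levels
directly too).  Scenario and subgroup runs deep-copy the inputs; the base
bundle's content hash is asserted unchanged.

Subgroup strata (age bands, sex, enrollment SBP, diabetes, measurement
mode) are parameter sets: a scaled event-rate table (both arms scaled
equally, preserving the arm ratio), a start age (65 for ages 60–69, 75
for 70–80 — the strata midpoints, recorded in output metadata), and
risk-profile tweaks.  The stratum rate scales are synthetic but ordered
as trial subgroups order their risks (men > women, older > younger,
higher SBP > lower).

## Synthetic data: what it does and does not show

The generator emulates: the trial's yearly event probabilities (embedded
verbatim — these are real), Gompertz life tables per country (China-like
highest old-age mortality), cost sets anchored to the order of magnitude
of published lifetime totals (e.g. ≈¥10⁵ per patient in China), utility
anchors, and plausible risk-equation coefficients (positive age and SBP
effects, S0 ≈ 0.75, calibration scale 1.4, i.e. a ten-year composite risk
near 35% at the covariate means).  Every number is deterministic in the
seed; same seed, byte-identical files.

It does **not** reproduce the confidential national cost/utility tables
or published risk-equation coefficients.  Passing tests therefore
demonstrate the *mechanics* (conservation, convergence, reproducibility,
directional responses: cost of treatment as top ICER driver, best < base
< worst adherence, higher repeated risk → lower ICER, men < women) and
the trial-phase validation — not that the synthetic lifetime ICERs equal
published country results.  With real input tables the same pipeline
produces the real analysis.

## Numerical choices

- Mass conservation is exact by construction (transition rows sum to 1);
  the trace asserts |Σ occupancy − 1| < 1e-10 per cycle.
- Probability↔rate transforms use `log1p`/`expm1`; round trips hold to
  1e-12 across [0, 1−1e-9].
- Lifetime horizon runs until the alive mass drops below 1e-9 or the
  terminal age passes; fixed horizons run exactly that many cycles.
- Ties at NMB = 0 count as not cost-effective; ICER rounding is
  half-away-from-zero.
- Blending short-circuits at adherence 0 and 1 so infinite terminal-age
  death rates never meet a zero weight.

## Limitations

Single representative covariate profile per arm (no individual
heterogeneity beyond subgroup parameter sets); no tunnel states longer
than one year; kidney-disease progression excluded; adverse-event risks
held at trial values post-trial; no parameter correlations in the PSA; no
EVPI; currency inflation outside scope (inputs assumed already in one
price year).  The chronic-state case-fatality multiplier is a scalar
applied uniformly across the four chronic states; state-specific values
would be better with data to support them.
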