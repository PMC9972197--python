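"""Trial-period validation: does the model reproduce the observed
primary-outcome incidence?

Runs both arms over the 4-year trial window only and compares the modelled
first-composite-event incidence (per 100 person-years, mid-cycle event
timing) with the incidences observed in the trial (1.00 intensive, 1.40
standard).
"""
from bpcea import SyntheticProfile, generate_inputs, validate_trial_period

inputs = generate_inputs(SyntheticProfile(country="CN", seed=0))
report = validate_trial_period(inputs)

print(f"4-year trial window, tolerance ±{report.tolerance} per 100 person-years")
for arm in ("intensive", "standard"):
    print(f"  {arm:9s}: model {report.model_incidence[arm]:.2f}  "
          f"observed {report.observed_incidence[arm]:.2f}  "
          f"difference {report.difference[arm]:+.2f}")
print(f"  verdict: {'PASS' if report.passed else 'FAIL'}")
print("  cumulative incidence (standard):",
      [round(x, 4) for x in report.cumulative_incidence["standard"]])
# Agreement within the tolerance says the trial-phase transition structure
# (probabilities, competing death, target-attainment mix) reproduces what
# the trial actually recorded.
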