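# Scenario battery: twelve named re-analyses run per country (36 in all).
# Unset fields inherit the base case.  "risk_model_high"/"risk_model_low"
# emulate substituting a CVD risk equation that predicts systematically
# higher or lower post-trial risk than the default calibration.
scenarios:
  - name: base
  - name: best_case_adherence
    adherence: best
  - name: worst_case_adherence
    adherence: worst
  - name: discount_0
    discount_rate: 0.0
  - name: discount_5
    discount_rate: 0.05
  - name: repeated_cvd_x2
    repeated_cvd_multiplier: 2.0
  - name: repeated_cvd_x1.5
    repeated_cvd_multiplier: 1.5
  - name: sprint_hr_068
    treatment_effect_hr: 0.68
  - name: horizon_10y
    horizon: 10
  - name: horizon_20y
    horizon: 20
  - name: risk_model_high
    post_trial_risk_scale: 1.25
  - name: risk_model_low
    post_trial_risk_scale: 0.80
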