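# RunConfig fields; either `simulation` or `input_panel` is required
simulation:
  n_patients: 5000
  seed: 1
seed: 1
thresholds: [1, 2, 4, 6]
include_never: true
grace_months: 1
follow_up_months: 12
truncation_percentile: 99
outcomes: [stroke, bleed]
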