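# SimConfig fields; unlisted fields keep package defaults
n_patients: 5000
seed: 1
max_months: 12
score_progression_rate: 0.02
init_intercept: -2.5
init_score_logodds: 0.3
hazard_stroke: 0.010
hazard_bleed: 0.004
oac_stroke_hr: 0.6
oac_bleed_hr: 1.5
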