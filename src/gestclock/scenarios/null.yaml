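# Global null: no predictor drives age acceleration.
n: 400
tissues: [cord_blood]
cohort_id: sim_null
gamma: {}
sigma_a: 0.7
delta: 1.0
sigma_beta: 0.02
rho: 0.0
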