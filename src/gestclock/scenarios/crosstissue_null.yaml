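# Two tissues of the same individuals with uncorrelated accelerations
# (rho = 0) and no predictor effects, so the planted cross-tissue
# correlation of total acceleration is exactly rho.
n: 350
tissues: [cord_blood, placenta_fetal]
cohort_id: sim_xtissue
gamma: {}
sigma_a: 0.7
delta: 1.0
sigma_beta: 0.02
rho: 0.0
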