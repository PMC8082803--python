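# Companion to cordblood_like for transfer-null experiments: the same
# overall effect budget planted on a predictor set that is latently
# uncorrelated with the cordblood_like five, so a score transferred from a
# cordblood_like discovery cohort is uncorrelated with this cohort's EAAR.
n: 400
tissues: [cord_blood]
cohort_id: sim_indep
gamma:
  maternal_age_years: 0.26
  maternal_bmi: 0.25
  maternal_diabetes: 0.24
  parity: -0.24
  hypertensive_disorder: 0.22
sigma_a: 0.7
delta: 1.0
sigma_beta: 0.02
rho: 0.0
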