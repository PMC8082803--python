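# Cord-blood-like scenario: five planted effects (weeks per SD) on the
# predictors reported as stable in term cord blood, with matching signs
# (smoking, mental disorders, aided delivery and birth length accelerate;
# female sex decelerates).
n: 400
tissues: [cord_blood]
cohort_id: sim_cordblood
gamma:
  maternal_smoking: 0.26
  birth_length_cm: 0.25
  delivery_mode: 0.24
  maternal_mental_disorders: 0.24
  child_sex: -0.22
sigma_a: 0.7
delta: 1.0
sigma_beta: 0.02
rho: 0.0
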