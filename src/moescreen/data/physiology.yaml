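# Adult-human physiology behind the steady-state plasma concentration model,
# with population coefficients of variation for the Monte Carlo step.
# gfr: glomerular filtration rate, L/h per kg body weight
# q_liver: liver blood flow, L/h per kg body weight
# hepatocellularity: 10^6 hepatocytes per g liver
# liver_mass: g liver per kg body weight
gfr: 0.1
q_liver: 1.45
hepatocellularity: 110.0
liver_mass: 25.7
cv_gfr: 0.2
cv_q_liver: 0.2
cv_hepatocellularity: 0.2
cv_liver_mass: 0.2
cv_fup: 0.3
cv_clint: 0.3
fup_floor: 0.005
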