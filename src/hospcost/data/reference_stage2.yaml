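# Stage-2 re-estimated coefficients on the ER-complete subsample (n = 249):
# the constant, first-order output terms (now including ER visits),
# own-quadratic output terms, and all output x price interactions.
# Every coefficient not listed here is carried over, fixed, from stage 1.
constant: 0.191
admissions: 0.577
outpatients: 0.337
other_revenues: 0.102
er_visits: 0.034
admissions x admissions: 0.020
outpatients x outpatients: 0.045
other_revenues x other_revenues: 0.022
er_visits x er_visits: -0.038
admissions x price man_adm: 0.001
admissions x price nursing: -0.020
admissions x price paramedical: 0.004
admissions x price auxiliary: -0.009
admissions x price material: 0.029
admissions x price capital: -0.005
outpatients x price man_adm: 0.013
outpatients x price nursing: 0.023
outpatients x price paramedical: -0.005
outpatients x price auxiliary: -0.012
outpatients x price material: -0.033
outpatients x price capital: 0.014
other_revenues x price man_adm: 0.000
other_revenues x price nursing: 0.000
other_revenues x price paramedical: 0.005
other_revenues x price auxiliary: -0.003
other_revenues x price material: 0.003
other_revenues x price capital: -0.004
er_visits x price man_adm: -0.002
er_visits x price nursing: -0.025
er_visits x price paramedical: 0.013
er_visits x price auxiliary: 0.021
er_visits x price material: -0.006
er_visits x price capital: -0.001
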