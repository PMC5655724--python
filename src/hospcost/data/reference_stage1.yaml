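# Stage-1 coefficient estimates of the two-stage translog cost-system fit to
# the Dutch general-hospital panel (2003-2011, n = 682): three services
# (ER visits excluded), six input prices, hedonic case-mix interactions.
constant: 0.203
year 2004: -0.035
year 2005: -0.056
year 2006: -0.081
year 2007: -0.095
year 2008: -0.123
year 2009: -0.138
year 2010: -0.146
year 2011: -0.172
admissions: 0.626
outpatients: 0.353
other_revenues: 0.089
admissions x admissions: -0.085
admissions x outpatients: 0.139
admissions x other_revenues: 0.019
outpatients x outpatients: -0.128
outpatients x other_revenues: -0.036
other_revenues x other_revenues: 0.010
price man_adm: 0.116
price nursing: 0.338
price paramedical: 0.053
price auxiliary: 0.093
price material: 0.302
price capital: 0.098
price man_adm x price man_adm: 0.016
price man_adm x price nursing: 0.094
price man_adm x price paramedical: 0.026
price man_adm x price auxiliary: -0.002
price man_adm x price material: -0.127
price man_adm x price capital: -0.007
price nursing x price nursing: -0.117
price nursing x price paramedical: 0.011
price nursing x price auxiliary: -0.041
price nursing x price material: 0.076
price nursing x price capital: -0.024
price paramedical x price paramedical: -0.014
price paramedical x price auxiliary: 0.015
price paramedical x price material: -0.041
price paramedical x price capital: 0.003
price auxiliary x price auxiliary: -0.008
price auxiliary x price material: 0.047
price auxiliary x price capital: -0.010
price material x price material: 0.063
price material x price capital: -0.018
price capital x price capital: 0.056
admissions x price man_adm: -0.001
admissions x price nursing: -0.022
admissions x price paramedical: 0.011
admissions x price auxiliary: -0.007
admissions x price material: 0.028
admissions x price capital: -0.009
outpatients x price man_adm: 0.011
outpatients x price nursing: 0.016
outpatients x price paramedical: -0.001
outpatients x price auxiliary: -0.003
outpatients x price material: -0.038
outpatients x price capital: 0.015
other_revenues x price man_adm: -0.002
other_revenues x price nursing: -0.003
other_revenues x price paramedical: 0.006
other_revenues x price auxiliary: -0.001
other_revenues x price material: 0.004
other_revenues x price capital: -0.004
trend x price man_adm: 0.087
trend x price nursing: 0.049
trend x price paramedical: 0.061
trend x price auxiliary: 0.028
trend x price material: -0.251
trend x price capital: 0.027
admissions x surgery_ortho: -0.163
admissions x psych_beds: 0.015
admissions x ic_beds: 0.033
admissions x expected_los: 0.254
admissions x neurosurgery: 0.034
admissions x cardiothoracic: 0.123
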