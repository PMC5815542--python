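study_id,catheter_type,n_patients,uti_incidence,followup_months,utis_per_month
cardenas_2011,pvc,114,,4.5,0.477982456140351
sarica_2010,pvc,21,4.00,1.5,
cardenas_2009,pvc,23,1.65,12,
de_ridder_2005,pvc,61,,12,0.38
cardenas_2011,hydrophilic,105,,4.5,0.479047619047619
sarica_2010,hydrophilic,21,1.00,1.5,
cardenas_2009,hydrophilic,22,0.77,12,
de_ridder_2005,hydrophilic,61,,12,0.34
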