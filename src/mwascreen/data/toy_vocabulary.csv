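set_name,role,code,is_prefix
cesarean,OUTCOME,O82,1
cesarean,OUTCOME,669.7,1
preterm,OUTCOME,O60.1,1
preterm,OUTCOME,644.21,0
stillbirth,OUTCOME,Z37.1,0
stillbirth,OUTCOME,Z37.4,0
stillbirth,OUTCOME,656.4,1
infectious_disease,COVARIATE,O98,1
infectious_disease,COVARIATE,647.6,1
obesity,COVARIATE,E66,1
obesity,COVARIATE,278.0,1
cancer,COVARIATE,C50,1
cancer,COVARIATE,174,1
cardiovascular,COVARIATE,I25,1
cardiovascular,COVARIATE,414,1
circulatory,COVARIATE,I87,1
circulatory,COVARIATE,459.8,1
cerebrovascular,COVARIATE,I63,1
cerebrovascular,COVARIATE,434,1
respiratory,COVARIATE,J45,1
respiratory,COVARIATE,493,1
immune_disorders,COVARIATE,D80,1
immune_disorders,COVARIATE,279,1
organ_transplant,COVARIATE,Z94,1
organ_transplant,COVARIATE,V42,1
obstetric_history,COVARIATE,Z87.5,1
obstetric_history,COVARIATE,V23.4,1
maternal_care,COVARIATE,O34,1
maternal_care,COVARIATE,654,1
preeclampsia,COVARIATE,O14,1
preeclampsia,COVARIATE,642.4,1
multiple_birth,COVARIATE,O30,1
multiple_birth,COVARIATE,651,1
drug_allergies,COVARIATE,Z88,1
drug_allergies,COVARIATE,V14,1
procedures,COVARIATE,Z98,1
procedures,COVARIATE,V45,1
drug_resistance,COVARIATE,Z16,1
drug_resistance,COVARIATE,V09,1
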