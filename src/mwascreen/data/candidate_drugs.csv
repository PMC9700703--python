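name,fda_approved,approval_year,hiv_only_indication,pharmaceutical_or_biological,trial_includes_reproductive_age_females
hydroxychloroquine,true,1955,false,true,true
azithromycin,true,1991,false,true,true
oseltamivir,true,1999,false,true,true
famotidine,true,1986,false,true,true
dexamethasone,true,1958,false,true,true
enoxaparin,true,1993,false,true,true
heparin,true,1939,false,true,true
aspirin,true,1950,false,true,true
amoxicillin,true,1972,false,true,true
folic acid,true,1947,false,true,true
methylprednisolone,true,1957,false,true,true
remdesivir,true,2020,false,true,true
baricitinib,true,2018,false,true,true
favipiravir,false,,false,true,true
molnupiravir,false,,false,true,true
lopinavir,true,2000,true,true,true
emtricitabine,true,2003,true,true,true
convalescent plasma,true,2015,false,false,true
mesenchymal stem cells,true,2016,false,false,true
dutasteride,true,2001,false,true,false
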