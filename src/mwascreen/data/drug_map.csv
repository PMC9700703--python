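raw_name,variable
oseltamivir,oseltamivir
Tamiflu,oseltamivir
mefloquine,mefloquine
Lariam,mefloquine
hydroxychloroquine,hydroxychloroquine
Plaquenil,hydroxychloroquine
levofloxacin,levofloxacin
Levaquin,levofloxacin
clindamycin,clindamycin
Cleocin,clindamycin
azithromycin,azithromycin
Zithromax,azithromycin
amoxicillin,amoxicillin
Amoxil,amoxicillin
amoxicillin/clavulanate potassium,amoxicillin-clavulanate
Augmentin,amoxicillin-clavulanate
sulfamethoxazole/trimethoprim,sulfamethoxazole-trimethoprim
Bactrim,sulfamethoxazole-trimethoprim
doxycycline,doxycycline
fluoxetine,fluoxetine
Prozac,fluoxetine
famotidine,famotidine
Pepcid,famotidine
hydrocortisone,hydrocortisone
methylprednisolone,methylprednisolone
Medrol,methylprednisolone
prednisone,prednisone
dexamethasone,dexamethasone
tacrolimus,tacrolimus
Prograf,tacrolimus
folic acid,folic acid
calcium carbonate/folic acid/pyridoxine/vitamin B12,prenatal_multivitamin
Folbecal,prenatal_multivitamin
vitamin D,vitamin D
diltiazem,diltiazem
propranolol,propranolol
enoxaparin,enoxaparin
Lovenox,enoxaparin
heparin,heparin
aspirin,aspirin
ibuprofen,ibuprofen
Motrin,ibuprofen
Advil,ibuprofen
indomethacin,indomethacin
naproxen,naproxen
budesonide,budesonide
montelukast,montelukast
Singulair,montelukast
esomeprazole,esomeprazole
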