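code,description,group
AB001,amoxicillin 500mg capsules (synthetic code),antibiotic
AB002,flucloxacillin 250mg capsules (synthetic code),antibiotic
AB003,trimethoprim 200mg tablets (synthetic code),antibiotic
AB004,doxycycline 100mg capsules (synthetic code),antibiotic
AB005,clarithromycin 500mg tablets (synthetic code),antibiotic
OP001,morphine sulfate 10mg tablets (synthetic code),strong_opioid
OP002,oxycodone 5mg capsules (synthetic code),strong_opioid
OP003,buprenorphine 5mcg/hr patches (synthetic code),strong_opioid
OP004,tapentadol 50mg tablets (synthetic code),strong_opioid
BZ001,diazepam 2mg tablets (synthetic code),benzodiazepine
BZ002,lorazepam 1mg tablets (synthetic code),benzodiazepine
BZ003,temazepam 10mg tablets (synthetic code),benzodiazepine
ZD001,zopiclone 7.5mg tablets (synthetic code),z_drug
ZD002,zolpidem 10mg tablets (synthetic code),z_drug
NS001,ibuprofen 400mg tablets (synthetic code),nsaid
NS002,naproxen 500mg tablets (synthetic code),nsaid
NS003,diclofenac 50mg tablets (synthetic code),nsaid
NS004,celecoxib 200mg capsules (synthetic code),nsaid
UH001,omeprazole 20mg capsules (synthetic code),ulcer_healing
UH002,lansoprazole 30mg capsules (synthetic code),ulcer_healing
UH003,ranitidine 150mg tablets (synthetic code),ulcer_healing
AC001,warfarin 3mg tablets (synthetic code),anticoagulant
AC002,apixaban 5mg tablets (synthetic code),anticoagulant
AC003,rivaroxaban 20mg tablets (synthetic code),anticoagulant
AP001,clopidogrel 75mg tablets (synthetic code),antiplatelet_nonaspirin
AP002,dipyridamole 200mg capsules (synthetic code),antiplatelet_nonaspirin
AS001,aspirin 75mg dispersible tablets (synthetic code),aspirin
AS002,aspirin 300mg tablets (synthetic code),aspirin
NB001,propranolol 40mg tablets (synthetic code),nonselective_beta_blocker
NB002,sotalol 80mg tablets (synthetic code),nonselective_beta_blocker
NB003,carvedilol 6.25mg tablets (synthetic code),nonselective_beta_blocker
LA001,salmeterol 25mcg inhaler (synthetic code),laba
LA002,formoterol 12mcg inhaler (synthetic code),laba
LC001,salmeterol+fluticasone combination inhaler (synthetic code),laba_ics_combo
LC002,formoterol+budesonide combination inhaler (synthetic code),laba_ics_combo
IC001,beclometasone 100mcg inhaler (synthetic code),ics
IC002,budesonide 200mcg inhaler (synthetic code),ics
PS001,risperidone 1mg tablets (synthetic code),antipsychotic
PS002,quetiapine 25mg tablets (synthetic code),antipsychotic
PS003,haloperidol 500mcg capsules (synthetic code),antipsychotic
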