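icd10_prefix,condition
J45,asthma
J46,asthma
E10,diabetes complications
E11,diabetes complications
E13,diabetes complications
E14,diabetes complications
J41,copd
J42,copd
J43,copd
J44,copd
I50,heart failure
I11.0,hypertensive heart disease with heart failure
I10,hypertension
I20,angina
I25,chronic ischaemic heart disease
G40,epilepsy
G41,epilepsy
J81,pulmonary oedema
I48,atrial fibrillation
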