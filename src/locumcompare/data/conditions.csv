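code,description,condition
CN001,asthma diagnosis (synthetic code),asthma
CN002,asthma annual review (synthetic code),asthma
CN101,peptic ulcer disease (synthetic code),peptic_ulcer
CN102,gastric ulcer (synthetic code),peptic_ulcer
CN201,heart failure diagnosis (synthetic code),heart_failure
CN202,left ventricular dysfunction (synthetic code),heart_failure
CN301,dementia diagnosis (synthetic code),dementia
CN302,alzheimers disease (synthetic code),dementia
CN401,schizophrenia (synthetic code),psychosis
CN402,psychotic episode (synthetic code),psychosis
CN501,type 2 diabetes mellitus (synthetic code),diabetes
CN601,chronic obstructive pulmonary disease (synthetic code),copd
CN701,essential hypertension (synthetic code),hypertension
CN801,depression diagnosis (synthetic code),depression
CN901,epilepsy diagnosis (synthetic code),epilepsy
CNA01,chronic kidney disease stage 3 (synthetic code),ckd
CNB01,atrial fibrillation (synthetic code),atrial_fibrillation
CNC01,coronary heart disease (synthetic code),coronary_heart_disease
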