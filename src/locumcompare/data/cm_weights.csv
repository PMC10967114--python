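condition,weight
asthma,0.19
peptic_ulcer,0.20
heart_failure,1.04
dementia,2.50
psychosis,0.64
diabetes,0.75
copd,1.11
hypertension,0.08
depression,0.91
epilepsy,0.92
ckd,0.53
atrial_fibrillation,1.03
coronary_heart_disease,0.55
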