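# Demo-scale pipeline configuration: a small English-style cohort (3 regions,
# 24 practices, ~150 patients each, three financial years) with the default
# study-condition truth table (observed outcome base rates and locum
# contrasts). Used by the shipped worked example and the determinism checks.
cohort:
  n_regions: 3
  n_practices: 24
  patients_per_practice: 150
  study_start: 2010-04-01
  study_end: 2013-03-31
  consultation_rate: 4.0
  locum_share: 0.10
  other_staff_share: 0.20
  practice_sd: 0.15
  patient_sd: 0.30
  seed: 12345
pipeline:
  alpha: 0.01
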