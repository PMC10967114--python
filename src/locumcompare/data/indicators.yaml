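# Default registry of the ten prescribing-safety indicators (A-J).
#
# Each indicator defines, declaratively:
#   index:   which face-to-face GP consultations form the at-risk denominator
#            (drug group prescribed that day, optional age bound, optional
#            condition history requirements, optional concurrent co-prescription)
#   trigger: when an at-risk consultation counts as potentially hazardous
#            (numerator). Kinds:
#              no_mitigation     - hazardous unless a mitigating drug group was
#                                  prescribed at the index consultation or within
#                                  `lookback_days` before it (inclusive)
#              condition_present - hazardous iff the patient has a qualifying
#                                  condition recorded on or before the index date
#              co_drug           - hazardous iff a partner drug group is
#                                  prescribed at the index consultation or covers
#                                  it (most recent prescription within
#                                  `coverage_days`)
#              duration_gt       - hazardous iff continuous exposure to the index
#                                  drug group exceeds `min_days`, chaining
#                                  prescriptions whose gaps are <= `grace_days`
#
# Windows are in days and overridable; 91 days operationalises "the preceding
# 3 months", 28-day prescription coverage is the usual concurrency convention,
# and 42 days operationalises "more than 6 weeks".
indicators:
  - id: A
    harm: gi_bleed
    description: Oral NSAID without gastroprotection in a patient aged >= 65
    index:
      drug_groups: [nsaid]
      min_age: 65
    trigger:
      kind: no_mitigation
      mitigation_groups: [ulcer_healing]
      lookback_days: 91
  - id: B
    harm: gi_bleed
    description: Oral NSAID without gastroprotection with a history of peptic ulceration
    index:
      drug_groups: [nsaid]
      conditions: [peptic_ulcer]
    trigger:
      kind: no_mitigation
      mitigation_groups: [ulcer_healing]
      lookback_days: 91
  - id: C
    harm: gi_bleed
    description: Antiplatelet without gastroprotection with a history of peptic ulceration
    index:
      drug_groups: [antiplatelet_nonaspirin, aspirin]
      conditions: [peptic_ulcer]
    trigger:
      kind: no_mitigation
      mitigation_groups: [ulcer_healing]
      lookback_days: 91
  - id: D
    harm: gi_bleed
    description: Warfarin or DOAC in combination with an oral NSAID
    index:
      drug_groups: [anticoagulant]
    trigger:
      kind: co_drug
      co_drug_groups: [nsaid]
      coverage_days: 28
  - id: E
    harm: gi_bleed
    description: Warfarin or DOAC with an antiplatelet, without gastroprotection
    index:
      drug_groups: [antiplatelet_nonaspirin, aspirin]
      co_drug_groups: [anticoagulant]
      co_coverage_days: 28
    trigger:
      kind: no_mitigation
      mitigation_groups: [ulcer_healing]
      lookback_days: 91
  - id: F
    harm: gi_bleed
    description: Aspirin with another antiplatelet, without gastroprotection
    index:
      drug_groups: [aspirin]
      co_drug_groups: [antiplatelet_nonaspirin]
      co_coverage_days: 28
    trigger:
      kind: no_mitigation
      mitigation_groups: [ulcer_healing]
      lookback_days: 91
  - id: G
    harm: asthma
    description: Non-selective beta-blocker prescribed to a patient with asthma
    index:
      drug_groups: [nonselective_beta_blocker]
    trigger:
      kind: condition_present
      conditions: [asthma]
  - id: H
    harm: asthma
    description: Standalone LABA inhaler in asthma without inhaled corticosteroid
    index:
      drug_groups: [laba]
      conditions: [asthma]
    trigger:
      kind: no_mitigation
      mitigation_groups: [ics]
      lookback_days: 91
  - id: I
    harm: heart_failure
    description: Oral NSAID prescribed to a patient with heart failure
    index:
      drug_groups: [nsaid]
    trigger:
      kind: condition_present
      conditions: [heart_failure]
  - id: J
    harm: stroke
    description: Antipsychotic for more than 6 weeks in dementia without psychosis, age >= 65
    index:
      drug_groups: [antipsychotic]
      min_age: 65
      conditions: [dementia]
      conditions_absent: [psychosis]
    trigger:
      kind: duration_gt
      duration_group: antipsychotic
      min_days: 42
      grace_days: 28
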