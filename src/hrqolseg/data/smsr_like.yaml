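n: 1697
seed: 20240001
age_params:
  loc: 47.839
  scale: 15.2833
  lower: 18.0
  upper: 90.0
duration_params:
  shape: 1.02105
  scale: 20.49854
  min_age_at_diagnosis: 16.0
sex_p_female: 0.731
phenotype_probs:
  CIS: 0.041
  PPMS: 0.106
  RRMS: 0.684
  SPMS: 0.161
  unclear: 0.008
severity_loadings:
  duration: 0.035
  noise_sd: 1.0
  phenotype:
    CIS: -0.8
    PPMS: 1.2
    RRMS: 0.0
    SPMS: 1.5
    unclear: 0.0
severity_standardization:
  mean: 0.7444
  sd: 1.2475
symptom_params:
  balance:
  - -0.7444
  - 1.2
  bladder:
  - -1.0357
  - 0.9
  depression:
  - -2.1035
  - 0.7
  fatigue:
  - 0.209
  - 0.9
  gait:
  - -0.8309
  - 1.4
  gastrointestinal:
  - -1.3707
  - 0.8
  memory:
  - -1.399
  - 0.7
  pain:
  - -0.9756
  - 0.8
  paresthesia:
  - -0.2546
  - 0.6
  spasms:
  - -1.0595
  - 1.0
  tremors:
  - -2.446
  - 0.9
  muscle_weakness:
  - -0.9323
  - 1.2
srdss_thresholds:
- 0.5139
- 1.3686
edss_params:
  intercept: 2.071
  slope: 3.51
covariate_effects:
  age_per_year: -0.004
  age_center: 49.0
  duration_per_year: -0.006
  duration_center: 11.0
  srdss:
    4-6.5: -0.45
    '>=7': -1.0
  benefit:
    applied: -0.65
    receives: -0.5
  symptoms:
    balance: -0.15
    bladder: -0.12
    depression: -0.75
    fatigue: -0.4
    gait: -0.2
    gastrointestinal: -0.3
    memory: -0.35
    pain: -0.5
    paresthesia: -0.12
    spasms: -0.2
    tremors: -0.25
    muscle_weakness: -0.4
  vas_scale: 0.8
residual_rho: 0.5415
residual_sd: 1.0
eq5d_marginal:
  anchors:
  - - 0.0
    - 15.0
  - - 0.0625
    - 43.2
  - - 0.125
    - 61.5
  - - 0.1875
    - 78.2
  - - 0.25
    - 80.0
  - - 0.375
    - 86.2
  - - 0.5
    - 90.7
  - - 0.625
    - 94.5
  - - 0.75
    - 96.2
  - - 0.8125
    - 96.7
  - - 0.84
    - 99.8
  - - 1.0
    - 100.0
  ceiling_mass: 0.16
  ceiling_value: 100.0
vas_marginal:
  anchors:
  - - 0.0
    - 5.0
  - - 0.0625
    - 32.0
  - - 0.125
    - 40.0
  - - 0.1875
    - 50.0
  - - 0.25
    - 60.0
  - - 0.375
    - 70.0
  - - 0.5
    - 80.0
  - - 0.625
    - 85.0
  - - 0.75
    - 90.0
  - - 0.8125
    - 91.0
  - - 0.875
    - 95.0
  - - 0.9375
    - 98.0
  - - 1.0
    - 100.0
  ceiling_mass: 0.0
  ceiling_value: 100.0
social_params:
  benefit_probs:
    none: 0.62277
    applied: 0.06357
    receives: 0.31366
  benefit_gammas:
    none: 0.0
    applied: 0.9
    receives: 1.1
  employed:
    intercept: 0.5139
    gamma: -0.9
  citizen_p: 0.895
  education_probs:
    mandatory: 0.038
    apprenticeship: 0.405
    highschool: 0.092
    higher_professional: 0.146
    university: 0.275
    other: 0.044
  living_probs:
    clinic: 0.0035
    family: 0.296
    friends_relatives: 0.026
    alone: 0.219
    parents: 0.021
    spouse_partner: 0.4115
    other: 0.023
  marital_probs:
    divorced: 0.11066
    married: 0.509645
    partnership: 0.02132
    separated: 0.024365
    unmarried: 0.306599
    widowed: 0.027411
  smoking_probs:
    never: 0.438066
    past: 0.215509
    current: 0.346425
  dmt_probs:
    oral: 0.34268
    monoclonal: 0.1929
    injectable: 0.13005
    other: 0.01786
    none: 0.31651
  dmt_gammas:
    oral: 0.0
    monoclonal: 0.35
    injectable: -0.35
    other: 0.3
    none: 0.1
  first_symptom_params:
    visual:
    - 0.401
    - 0.0
    paresthesia:
    - 0.589
    - 0.0
    gait:
    - 0.31
    - 0.3
    spasms:
    - 0.084
    - 0.25
  family_ms_p: 0.141
  comorbidity_probs:
    mononucleosis: 0.145
    hypertension: 0.129
    cancer: 0.026
    diabetes1: 0.004
    diabetes2: 0.016
    cardiovascular: 0.04
  bmi_params:
    median: 24.1
    log_sd: 0.18
    severity_loading: 0.15
missingness:
  phenotype: 0.005
  living_situation: 0.005
  marital_status: 0.015
  education: 0.005
  smoking: 0.006
  bmi: 0.033
msss_fraction: 0.5522
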