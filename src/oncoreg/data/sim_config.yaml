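# Simulation configuration: stratified probability stacks for a synthetic
# institutional cancer registry.  Strata are gender x 5-year age bands; each
# band carries a cumulative stack of diagnosis weights, each diagnosis a
# stack of first-line therapy weights, a monthly disease-course transition
# table and an ICD-10 code distribution.  Weight lists are ordered: the
# cumulative boundaries follow the listed order.
#
# The 60-64 band reproduces the published calibration example: breast 0.23,
# lung 0.17, prostate 0.17, colorectal 0.08 (colorectal therefore occupies
# the cumulative interval [0.57, 0.65)), and colorectal first-line therapy
# teletherapy 0.44, chemotherapy 0.44, surgical treatment 0.12.  All other
# numbers are realistic desk-scale defaults, not estimates from any real
# registry.

index_date: 2010-01-01

age_bands:
  - "0-4"
  - "5-9"
  - "10-14"
  - "15-19"
  - "20-24"
  - "25-29"
  - "30-34"
  - "35-39"
  - "40-44"
  - "45-49"
  - "50-54"
  - "55-59"
  - "60-64"
  - "65-69"
  - "70-74"
  - "75-79"
  - "80-84"
  - "85+"

stratum_weights:
  gender: {M: 0.5, F: 0.5}
  age_bands:
    "0-4": 0.005
    "5-9": 0.005
    "10-14": 0.005
    "15-19": 0.005
    "20-24": 0.01
    "25-29": 0.01
    "30-34": 0.015
    "35-39": 0.02
    "40-44": 0.03
    "45-49": 0.045
    "50-54": 0.065
    "55-59": 0.09
    "60-64": 0.11
    "65-69": 0.13
    "70-74": 0.14
    "75-79": 0.13
    "80-84": 0.105
    "85+": 0.08

# Probability that a patient of the stratum receives more than one diagnosis.
multidx_fraction:
  default: 0.10

diagnosis_weights:
  default:
    Breast_cancer: 0.20
    Lung_cancer: 0.15
    Prostate_cancer: 0.14
    Colorectal_cancer: 0.11
    Melanoma: 0.12
    Pharynx_cancer: 0.05
    Other_cancer: 0.23
  "60-64":
    Breast_cancer: 0.23
    Lung_cancer: 0.17
    Prostate_cancer: 0.17
    Colorectal_cancer: 0.08
    Melanoma: 0.10
    Pharynx_cancer: 0.05
    Other_cancer: 0.20

therapy_weights:
  default:
    Colorectal_cancer:
      Teletherapy: 0.44
      Chemotherapy: 0.44
      SurgicalTreatment: 0.12
    Breast_cancer:
      SurgicalTreatment: 0.40
      Chemotherapy: 0.28
      Teletherapy: 0.20
      Anti-hormonal_anti-estrogens: 0.12
    Lung_cancer:
      Chemotherapy: 0.45
      Teletherapy: 0.35
      SurgicalTreatment: 0.20
    Prostate_cancer:
      SurgicalTreatment: 0.35
      Brachytherapy: 0.25
      Anti-hormonal_anti-androgens: 0.20
      Wait_and_see: 0.20
    Melanoma:
      SurgicalTreatment: 0.60
      Immunotherapy: 0.30
      Chemotherapy: 0.10
    Pharynx_cancer:
      Teletherapy: 0.50
      Chemotherapy: 0.30
      SurgicalTreatment: 0.20
    Other_cancer:
      Chemotherapy: 0.40
      SurgicalTreatment: 0.30
      Teletherapy: 0.20
      Wait_and_see: 0.10

# Number of therapies per diagnosis: geometric stopping rule.
therapy_continue_prob: 0.5
max_therapies: 6

icd10_codes:
  Colorectal_cancer:
    "C17.0": 0.01
    "C17.1": 0.01
    "C17.2": 0.01
    "C17.8": 0.005
    "C17.9": 0.015
    "C18.0": 0.06
    "C18.1": 0.02
    "C18.2": 0.08
    "C18.3": 0.03
    "C18.4": 0.04
    "C18.5": 0.03
    "C18.6": 0.04
    "C18.7": 0.17
    "C18.9": 0.08
    "C19": 0.07
    "C20": 0.25
    "C21.0": 0.02
    "C21.1": 0.02
    "C21.8": 0.01
    "D01.0": 0.015
    "D01.2": 0.015
  Lung_cancer:
    "C34.0": 0.05
    "C34.1": 0.30
    "C34.2": 0.05
    "C34.3": 0.25
    "C34.8": 0.05
    "C34.9": 0.30
  Breast_cancer: {"C50": 1.0}
  Prostate_cancer: {"C61": 1.0}
  Melanoma: {"C43": 1.0}
  Pharynx_cancer: {"C14": 1.0}
  Other_cancer: {"C80": 1.0}

anatomical_structures:
  Breast_cancer: Breast
  Lung_cancer: Lung
  Prostate_cancer: Prostate
  Colorectal_cancer: Colon
  Melanoma: Skin
  Pharynx_cancer: Pharynx
  Other_cancer: ""

# Monthly disease-course Markov model; an event row is recorded whenever the
# state changes.  Death is absorbing.
course_model:
  initial_state: Stable_disease
  absorbing: [Death]
  max_months: 60
  transitions:
    default:
      Stable_disease:
        Stable_disease: 0.70
        Partial_remission: 0.10
        Progression: 0.12
        Complete_remission: 0.05
        Death: 0.03
      Partial_remission:
        Partial_remission: 0.55
        Complete_remission: 0.20
        Progression: 0.15
        Stable_disease: 0.05
        Death: 0.05
      Progression:
        Progression: 0.55
        Death: 0.20
        Partial_remission: 0.10
        Stable_disease: 0.10
        Complete_remission: 0.05
      Complete_remission:
        Complete_remission: 0.92
        Recurrence: 0.08
      Recurrence:
        Recurrence: 0.45
        Progression: 0.25
        Partial_remission: 0.15
        Complete_remission: 0.10
        Death: 0.05
      Death:
        Death: 1.0

patient_condition:
  weight_kg: {M: [82.0, 12.0], F: [70.0, 11.0]}   # mean, sd
  height_cm: {M: [176.0, 7.0], F: [163.0, 6.0]}
  karnofsky_start: 90
  asa_weights: {1: 0.15, 2: 0.35, 3: 0.30, 4: 0.15, 5: 0.04, 6: 0.01}
  menopause_age: 50
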