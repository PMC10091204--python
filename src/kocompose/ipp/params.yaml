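# Synthetic configuration for the preventive-services composite.
#
# Every numeric value here (hazard ratios, relative-risk steps, logistic
# coefficients) is a synthetic placeholder of plausible magnitude; the real
# composite's regression coefficients are unpublished. The architecture —
# which services exist, their kinds, their inclusion criteria, and how they
# are wired — is what this file configures. Criteria constrain RAW input
# features only (never derived ones) so the eligibility submodel stands alone.
#
# kinds:
#   net_benefit     — dedicated net-benefit estimator submodel (15 of these)
#   detection       — detection-gain estimator (HIV testing)
#   diet            — computed by the top-level executive from the diet-risk
#                     executive's outputs
#   inline_behavior — computed inline by the top-level executive by removing
#                     the matching behavioural mortality-adjustment factor
#   inline_hr       — computed inline by the top-level executive from a
#                     configured hazard ratio

services:
  AAA:
    name: aaaScreening
    kind: net_benefit
    hr: 0.97
    background: aaa
    criteria: {min_age: 65, max_age: 75, flags: {ever_smoker: true}}
  ALC:
    name: alcoholReduction
    kind: inline_behavior
    behaviour: alcohol
    criteria: {min_age: 18, max_age: 100, min: {drinks_per_week: 8}}
  ASA:
    name: aspirinPrevention
    kind: net_benefit
    hr: 0.95
    background: cvd_event
    harm_background: bleeding
    criteria: {min_age: 40, max_age: 79, min: {systolic: 130}}
  BP:
    name: bpControl
    kind: net_benefit
    hr: 0.88
    criteria: {min_age: 18, max_age: 100, min: {systolic: 130}}
  BRE:
    name: breastCancerScreening
    kind: net_benefit
    hr: 0.95
    background: breast_cancer
    criteria: {min_age: 40, max_age: 74, sex: Female}
  CRC:
    name: crcScreening
    kind: net_benefit
    hr: 0.96
    background: colorectal_cancer
    criteria: {min_age: 45, max_age: 75}
  DIA:
    name: diabetesControl
    kind: net_benefit
    hr: 0.85
    criteria: {min_age: 18, max_age: 100, min: {a1c: 6.5}}
  DIET:
    name: dietCounseling
    kind: diet
    criteria: {min_age: 18, max_age: 100}
  STA:
    name: statinUse
    kind: inline_hr
    hr: 0.92
    background: cvd_event
    criteria: {min_age: 40, max_age: 75, min: {LDL: 100}}
  SMO:
    name: smokingCessation
    kind: inline_behavior
    behaviour: tobacco
    criteria: {min_age: 18, max_age: 100, flags: {current_smoker: true}}
  WEI:
    name: weightLoss
    kind: inline_behavior
    behaviour: obesity
    criteria: {min_age: 18, max_age: 100, min: {weight: 170}}
  LUN:
    name: lungCancerScreening
    kind: net_benefit
    hr: 0.95
    background: lung_cancer
    criteria: {min_age: 50, max_age: 80, flags: {current_smoker: true}, min: {pack_years: 20}}
  HIV:
    name: hivTesting
    kind: detection
    hr: 0.55
    p_undiagnosed: 0.15
    criteria: {min_age: 18, max_age: 65}
  CER:
    name: cervicalCancerScreening
    kind: net_benefit
    hr: 0.985
    background: cervical_cancer
    criteria: {min_age: 21, max_age: 65, sex: Female}
  OST:
    name: osteoporosisScreening
    kind: net_benefit
    hr: 0.97
    criteria: {min_age: 65, max_age: 100, sex: Female}
  DEP:
    name: depressionScreening
    kind: net_benefit
    hr: 0.99
    criteria: {min_age: 18, max_age: 100}
  CHL:
    name: chlamydiaScreening
    kind: net_benefit
    hr: 0.995
    criteria: {min_age: 18, max_age: 65, sex: Female, flags: {sexually_active: true}}
  HCV:
    name: hepatitisCScreening
    kind: net_benefit
    hr: 0.98
    criteria: {min_age: 18, max_age: 79}
  IMM:
    name: immunizationUpdate
    kind: net_benefit
    hr: 0.97
    criteria: {min_age: 18, max_age: 100}
  FAL:
    name: fallsPrevention
    kind: net_benefit
    hr: 0.96
    criteria: {min_age: 65, max_age: 100}
  PRE:
    name: prediabetesScreening
    kind: net_benefit
    hr: 0.98
    criteria: {min_age: 35, max_age: 70, min: {weight: 170}}

# Behavioural all-cause mortality adjustments, applied in this order.
adjustments:
  obesity:
    kind: step
    feature: bmi
    cuts: [30, 35, 40]
    levels: [1.0, 1.15, 1.3, 1.5]
  alcohol:
    kind: step
    feature: drinks_per_week
    cuts: [8, 15, 22]
    levels: [1.0, 1.1, 1.25, 1.45]
  tobacco:
    kind: smoking
    current_flag: current_smoker
    former_flag: ever_smoker
    feature: pack_years
    cuts: [10, 30]
    levels: [1.6, 1.9, 2.2]
    former_rr: 1.15

# Partial background-risk models: logistic(intercept + sum coef * feature).
background_models:
  lung_cancer:
    intercept: -5.5
    coefficients: {age: 0.03, pack_years: 0.04, current_smoker: 1.0}
  aaa:
    intercept: -5.0
    coefficients: {age: 0.035, ever_smoker: 1.0}
  breast_cancer:
    intercept: -4.5
    coefficients: {age: 0.03, family_history_breast: 0.8}
  colorectal_cancer:
    intercept: -4.8
    coefficients: {age: 0.035, family_history_crc: 0.9}
  cervical_cancer:
    intercept: -4.0
    coefficients: {age: 0.01}
  cvd_event:
    intercept: -6.0
    coefficients: {age: 0.05, systolic: 0.012, current_smoker: 0.6, cvd: 1.5}
  bleeding:
    intercept: -4.0
    coefficients: {age: 0.02}
  diet_disease:
    intercept: -3.5
    coefficients: {age: 0.025, cvd: 0.8}

# Diet-risk configuration: two-level relative risk on adherence; the absolute
# risk baseline is the diet_disease background probability.
diet:
  feature: diet_adherent
  adherent_rr: 1.0
  nonadherent_rr: 1.35

# Synthetic logistic cardiovascular risk score added during feature derivation.
cvd_risk_score:
  intercept: -7.0
  coefficients:
    age: 0.06
    systolic: 0.015
    totalcholesterol: 0.005
    HDL: -0.03
    current_smoker: 0.7
    cvd: 1.2
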