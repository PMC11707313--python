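# Default lifetime-model parameter set.
#
# SYNTHETIC PLACEHOLDER VALUES: the mortality, smoking-attributable cost and
# utility-weight schedules below are plausible, clearly-labelled stand-ins of
# the right shape (Gompertz-like mortality, age-rising smoker costs, modest
# ex-smoker utility gains), NOT estimates from national life tables or
# hospital-episode statistics.  Replace every table before drawing any
# substantive conclusion from the lifetime projection.
cycle_length_years: 1
start_age: 40.5
max_age: 90
sex_mix_female: 0.38
cohort_size: 1000
discount_rate: 0.035
rr_smoker_death: 2.0
natural_quit_rate: 0.02
relapse_rate: 0.08
arm_quit_prob:
  control: 0.041
  intervention: 0.072
treatment_cost:
  control: 0.20
  intervention: 47.52
mortality:
  # annual death probability = a * exp(b * age), capped at 1 (synthetic)
  male: {gompertz_a: 4.5e-5, gompertz_b: 0.085}
  female: {gompertz_a: 2.5e-5, gompertz_b: 0.088}
smoking_attributable_cost:
  # annual cost (GBP) while a smoker, by age band (synthetic)
  male:
    - {age_from: 0, value: 120}
    - {age_from: 35, value: 190}
    - {age_from: 50, value: 330}
    - {age_from: 65, value: 420}
    - {age_from: 75, value: 460}
  female:
    - {age_from: 0, value: 110}
    - {age_from: 35, value: 175}
    - {age_from: 50, value: 300}
    - {age_from: 65, value: 390}
    - {age_from: 75, value: 430}
utility_weights:
  # annual utility weight by smoking status and age band (synthetic)
  male:
    smoker:
      - {age_from: 0, value: 0.89}
      - {age_from: 50, value: 0.83}
      - {age_from: 65, value: 0.77}
      - {age_from: 75, value: 0.71}
    ex_smoker:
      - {age_from: 0, value: 0.92}
      - {age_from: 50, value: 0.86}
      - {age_from: 65, value: 0.80}
      - {age_from: 75, value: 0.74}
  female:
    smoker:
      - {age_from: 0, value: 0.88}
      - {age_from: 50, value: 0.82}
      - {age_from: 65, value: 0.76}
      - {age_from: 75, value: 0.70}
    ex_smoker:
      - {age_from: 0, value: 0.91}
      - {age_from: 50, value: 0.85}
      - {age_from: 65, value: 0.79}
      - {age_from: 75, value: 0.73}
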