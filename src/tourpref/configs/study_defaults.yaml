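# Default study conditions for synthetic-data generation and recovery runs.
#
# `true_coefficients` is the data-generating utility vector on the effects-coded
# scale, keyed by coded column name (the reference level of each attribute is
# implied by the within-attribute zero-sum constraint and listed under
# `implied_reference_levels` for documentation only).  Published point
# estimates fill the printed entries; unprinted levels are completed by the
# zero-sum constraint and the conventions described in docs/methods.md
# (money-level utilities monotone increasing in the amount; a one-night
# relationship the most preferred length).
study:
  n_respondents: 242
  n_tasks: 8
  n_profile_alternatives: 2
  has_opt_out: true

true_coefficients:
  condom_every: 0.679
  condom_half: 0.031
  money_0: -0.45
  money_500: -0.10
  money_1000: 0.15
  pay_immediate: 0.132
  pay_end_of_trip: 0.0
  rel_one_night: 0.424
  rel_3_4_nights: -0.379
  rel_return_visit: -0.300
  age_30_40: 0.212
  age_40_50: -0.012
  opt_out: 0.522

implied_reference_levels:
  condom_never: -0.710
  money_2000: 0.40
  pay_week_after: -0.132
  rel_europe_invite: 0.255
  age_50_60: -0.200

# Random-coefficient standard deviations used when generating under taste
# heterogeneity (mixed-logit truth); zero means homogeneous preferences.
true_sigmas_heterogeneous:
  condom_every: 0.6
  condom_half: 0.3
  money_0: 0.4
  money_500: 0.3
  money_1000: 0.3
  pay_immediate: 0.3
  pay_end_of_trip: 0.3
  rel_one_night: 0.4
  rel_3_4_nights: 0.4
  rel_return_visit: 0.3
  age_30_40: 0.3
  age_40_50: 0.3
  opt_out: 0.8

# Survey covariate marginals (calibration targets for the respondent sample).
covariate_model:
  age: {dist: normal, mean: 39.2, sd: 9.58, min: 18, max: 75, integer: true}
  occupation:
    dist: categorical
    labels:
      - "Tour guide (registered)"
      - "Tourist taxi driver (registered)"
      - "Juice presser"
      - "Bumster / chanter / chancer"
      - "Restaurant / bar worker"
      - "Horse rider"
      - "Fruit seller"
      - "No occupation"
      - "Other"
    probs: [0.20, 0.20, 0.1125, 0.0833, 0.0417, 0.0208, 0.0125, 0.0375, 0.2917]
  registered_labels:
    - "Tour guide (registered)"
    - "Tourist taxi driver (registered)"
  difficulty_350_bill: {dist: bernoulli, p: 0.85}
  income_monthly: {dist: gamma, mean: 3468, sd: 3960, integer: true}
  months_in_industry: {dist: gamma, mean: 110, sd: 97, min: 1, integer: true}
  months_per_year: {dist: normal, mean: 7.4, sd: 2.67, min: 0, max: 12, integer: true}
  who5_total: {dist: normal, mean: 16.2, sd: 4.2, min: 0, max: 25, integer: true}
  hunger: {p_moderate: 0.12, p_high: 0.03}
  hiv_knowledge: {p_very_high: 0.25, p_low: 0.47}
  ever_drugs: {dist: bernoulli, p: 0.537}

# Logistic models linking (centred) covariates to the five risk outcomes.
# Intercepts are on the logit scale at the covariate means, so they set the
# approximate outcome prevalence; slopes echo the direction of the published
# associations (registered occupation protective for STI/alcohol/drugs, hunger
# raising STI risk, HIV knowledge raising condom use).
outcome_model:
  centering:
    age: 39.2
    months_in_industry: 110
    months_per_year: 7.4
    hiv_knowledge: 6.5
  ever_tourist_sex:
    intercept: 0.0       # prevalence ~50%
    age: -0.02
    registered_occupation: -0.3
    difficulty_350_bill: 0.0
    months_in_industry: 0.005
    months_per_year: -0.10
    poor_wellbeing: -0.14
    hunger_flag: -0.04
    hiv_knowledge: -0.03
  condom_last_sex:
    intercept: -0.45     # prevalence ~39%
    age: -0.02
    registered_occupation: -0.29
    difficulty_350_bill: -0.37
    months_in_industry: 0.0
    months_per_year: -0.11
    poor_wellbeing: -0.15
    hunger_flag: 0.09
    hiv_knowledge: 0.14
  sti_12m:
    intercept: -2.7      # prevalence ~9%
    age: -0.05
    registered_occupation: -1.4
    difficulty_350_bill: 0.64
    months_in_industry: 0.0
    months_per_year: 0.0
    poor_wellbeing: -1.1
    hunger_flag: 1.5
    hiv_knowledge: 0.14
  alcohol_30d:
    intercept: -1.65     # prevalence ~17%
    age: 0.02
    registered_occupation: -0.86
    difficulty_350_bill: -0.12
    months_in_industry: -0.003
    months_per_year: 0.12
    poor_wellbeing: -0.07
    hunger_flag: 0.27
    hiv_knowledge: -0.04
  drugs_3m:              # fitted among ever-users only (prevalence ~88% of 130)
    intercept: 2.0
    age: -0.08
    registered_occupation: -0.84
    difficulty_350_bill: 0.9
    months_in_industry: -0.01
    months_per_year: -0.19
    poor_wellbeing: 1.2
    hunger_flag: 0.5
    hiv_knowledge: 0.11
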