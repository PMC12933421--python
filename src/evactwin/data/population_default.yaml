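n_agents: 222
seed: 0
zones:
- zone_id: Z01
  weight: 0.1
  age_marginal:
    18-34: 0.28
    35-54: 0.34
    55-74: 0.27
    75+: 0.11
  income_marginal:
    low: 0.25
    middle: 0.4
    high: 0.35
  education_marginal:
    no_hs: 0.1
    hs: 0.35
    some_college: 0.25
    bachelor_plus: 0.3
  ethnicity_marginal:
    hispanic: 0.55
    white_nh: 0.15
    black_nh: 0.2
    other: 0.1
  p_flood_zone: 0.05
  p_prior_hurricane: 0.35
  shelter_distance_km:
    mean: 3.0
    sd: 2.5
  constraint_prevalences:
    mobility_limited: 0.08
    no_vehicle: 0.06
    financial_barrier: 0.1
    pets: 0.35
    caregiving: 0.12
- zone_id: Z02
  weight: 0.1
  age_marginal:
    18-34: 0.28
    35-54: 0.34
    55-74: 0.27
    75+: 0.11
  income_marginal:
    low: 0.28
    middle: 0.4
    high: 0.32
  education_marginal:
    no_hs: 0.12
    hs: 0.35
    some_college: 0.25
    bachelor_plus: 0.28
  ethnicity_marginal:
    hispanic: 0.55
    white_nh: 0.15
    black_nh: 0.2
    other: 0.1
  p_flood_zone: 0.133
  p_prior_hurricane: 0.378
  shelter_distance_km:
    mean: 4.3
    sd: 2.5
  constraint_prevalences:
    mobility_limited: 0.087
    no_vehicle: 0.08
    financial_barrier: 0.124
    pets: 0.35
    caregiving: 0.127
- zone_id: Z03
  weight: 0.1
  age_marginal:
    18-34: 0.28
    35-54: 0.34
    55-74: 0.27
    75+: 0.11
  income_marginal:
    low: 0.32
    middle: 0.39
    high: 0.29
  education_marginal:
    no_hs: 0.13
    hs: 0.35
    some_college: 0.25
    bachelor_plus: 0.27
  ethnicity_marginal:
    hispanic: 0.55
    white_nh: 0.15
    black_nh: 0.2
    other: 0.1
  p_flood_zone: 0.217
  p_prior_hurricane: 0.406
  shelter_distance_km:
    mean: 5.7
    sd: 2.5
  constraint_prevalences:
    mobility_limited: 0.093
    no_vehicle: 0.1
    financial_barrier: 0.149
    pets: 0.35
    caregiving: 0.133
- zone_id: Z04
  weight: 0.1
  age_marginal:
    18-34: 0.28
    35-54: 0.34
    55-74: 0.27
    75+: 0.11
  income_marginal:
    low: 0.35
    middle: 0.38
    high: 0.27
  education_marginal:
    no_hs: 0.15
    hs: 0.35
    some_college: 0.25
    bachelor_plus: 0.25
  ethnicity_marginal:
    hispanic: 0.55
    white_nh: 0.15
    black_nh: 0.2
    other: 0.1
  p_flood_zone: 0.3
  p_prior_hurricane: 0.433
  shelter_distance_km:
    mean: 7.0
    sd: 2.5
  constraint_prevalences:
    mobility_limited: 0.1
    no_vehicle: 0.12
    financial_barrier: 0.173
    pets: 0.35
    caregiving: 0.14
- zone_id: Z05
  weight: 0.1
  age_marginal:
    18-34: 0.28
    35-54: 0.34
    55-74: 0.27
    75+: 0.11
  income_marginal:
    low: 0.38
    middle: 0.38
    high: 0.24
  education_marginal:
    no_hs: 0.17
    hs: 0.35
    some_college: 0.25
    bachelor_plus: 0.23
  ethnicity_marginal:
    hispanic: 0.55
    white_nh: 0.15
    black_nh: 0.2
    other: 0.1
  p_flood_zone: 0.383
  p_prior_hurricane: 0.461
  shelter_distance_km:
    mean: 8.3
    sd: 2.5
  constraint_prevalences:
    mobility_limited: 0.107
    no_vehicle: 0.14
    financial_barrier: 0.198
    pets: 0.35
    caregiving: 0.147
- zone_id: Z06
  weight: 0.1
  age_marginal:
    18-34: 0.28
    35-54: 0.34
    55-74: 0.27
    75+: 0.11
  income_marginal:
    low: 0.42
    middle: 0.37
    high: 0.21
  education_marginal:
    no_hs: 0.18
    hs: 0.35
    some_college: 0.25
    bachelor_plus: 0.22
  ethnicity_marginal:
    hispanic: 0.55
    white_nh: 0.15
    black_nh: 0.2
    other: 0.1
  p_flood_zone: 0.467
  p_prior_hurricane: 0.489
  shelter_distance_km:
    mean: 9.7
    sd: 2.5
  constraint_prevalences:
    mobility_limited: 0.113
    no_vehicle: 0.16
    financial_barrier: 0.222
    pets: 0.35
    caregiving: 0.153
- zone_id: Z07
  weight: 0.1
  age_marginal:
    18-34: 0.28
    35-54: 0.34
    55-74: 0.27
    75+: 0.11
  income_marginal:
    low: 0.45
    middle: 0.37
    high: 0.18
  education_marginal:
    no_hs: 0.2
    hs: 0.35
    some_college: 0.25
    bachelor_plus: 0.2
  ethnicity_marginal:
    hispanic: 0.55
    white_nh: 0.15
    black_nh: 0.2
    other: 0.1
  p_flood_zone: 0.55
  p_prior_hurricane: 0.517
  shelter_distance_km:
    mean: 11.0
    sd: 2.5
  constraint_prevalences:
    mobility_limited: 0.12
    no_vehicle: 0.18
    financial_barrier: 0.247
    pets: 0.35
    caregiving: 0.16
- zone_id: Z08
  weight: 0.1
  age_marginal:
    18-34: 0.28
    35-54: 0.34
    55-74: 0.27
    75+: 0.11
  income_marginal:
    low: 0.48
    middle: 0.36
    high: 0.16
  education_marginal:
    no_hs: 0.22
    hs: 0.35
    some_college: 0.25
    bachelor_plus: 0.18
  ethnicity_marginal:
    hispanic: 0.55
    white_nh: 0.15
    black_nh: 0.2
    other: 0.1
  p_flood_zone: 0.633
  p_prior_hurricane: 0.544
  shelter_distance_km:
    mean: 12.3
    sd: 2.5
  constraint_prevalences:
    mobility_limited: 0.127
    no_vehicle: 0.2
    financial_barrier: 0.271
    pets: 0.35
    caregiving: 0.167
- zone_id: Z09
  weight: 0.1
  age_marginal:
    18-34: 0.28
    35-54: 0.34
    55-74: 0.27
    75+: 0.11
  income_marginal:
    low: 0.52
    middle: 0.35
    high: 0.13
  education_marginal:
    no_hs: 0.23
    hs: 0.35
    some_college: 0.25
    bachelor_plus: 0.17
  ethnicity_marginal:
    hispanic: 0.55
    white_nh: 0.15
    black_nh: 0.2
    other: 0.1
  p_flood_zone: 0.717
  p_prior_hurricane: 0.572
  shelter_distance_km:
    mean: 13.7
    sd: 2.5
  constraint_prevalences:
    mobility_limited: 0.133
    no_vehicle: 0.22
    financial_barrier: 0.296
    pets: 0.35
    caregiving: 0.173
- zone_id: Z10
  weight: 0.1
  age_marginal:
    18-34: 0.28
    35-54: 0.34
    55-74: 0.27
    75+: 0.11
  income_marginal:
    low: 0.55
    middle: 0.35
    high: 0.1
  education_marginal:
    no_hs: 0.25
    hs: 0.35
    some_college: 0.25
    bachelor_plus: 0.15
  ethnicity_marginal:
    hispanic: 0.55
    white_nh: 0.15
    black_nh: 0.2
    other: 0.1
  p_flood_zone: 0.8
  p_prior_hurricane: 0.6
  shelter_distance_km:
    mean: 15.0
    sd: 2.5
  constraint_prevalences:
    mobility_limited: 0.14
    no_vehicle: 0.24
    financial_barrier: 0.32
    pets: 0.35
    caregiving: 0.18
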