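prevalence:
  family: beta
  base: 0.17
  low: 0.147
  high: 0.194
start_split_abused:
  U:
    family: fixed
    base: 0.964
    low: 0.964
    high: 0.964
  A:
    family: uniform
    base: 0.003
    low: 0.0
    high: 0.0066
  I:
    family: uniform
    base: 0.033
    low: 0.0
    high: 0.066
exits:
  control:
    N:
      U:
        family: dirichlet_row_member
        base: 0.0037
        low: 0.0004
        high: 0.0106
      D:
        family: dirichlet_row_member
        base: 0.00551
        low: 0.001
        high: 0.0136
    U:
      N:
        family: dirichlet_row_member
        base: 0.05
        low: 0.045
        high: 0.0553
      A:
        family: dirichlet_row_member
        base: 9.374999999996908e-06
        low: 1.8749999999993815e-06
        high: 2.0624999999993197e-05
      I:
        family: dirichlet_row_member
        base: 5.06249999999833e-05
        low: 2.9999999999990104e-05
        high: 7.499999999997526e-05
      D:
        family: dirichlet_row_member
        base: 0.00554
        low: 0.0039
        high: 0.0074
    A:
      N:
        family: dirichlet_row_member
        base: 0.1408
        low: 0.0707
        high: 0.2301
      D:
        family: dirichlet_row_member
        base: 0.00554
        low: 0.0
        high: 0.0309
    I:
      N:
        family: dirichlet_row_member
        base: 0.0781
        low: 0.0136
        high: 0.1912
      D:
        family: dirichlet_row_member
        base: 0.00554
        low: 0.0
        high: 0.0438
  intervention:
    N:
      U:
        family: dirichlet_row_member
        base: 0.0037
        low: 0.0004
        high: 0.0106
      D:
        family: dirichlet_row_member
        base: 0.00551
        low: 0.001
        high: 0.0136
    U:
      N:
        family: dirichlet_row_member
        base: 0.05
        low: 0.045
        high: 0.0553
      A:
        family: dirichlet_row_member
        base: 0.0008688484848484977
        low: 0.0006206060606060699
        high: 0.0011791515151515326
      I:
        family: dirichlet_row_member
        base: 0.0016911515151515402
        low: 0.00133430303030305
        high: 0.0020945454545454856
      D:
        family: dirichlet_row_member
        base: 0.00554
        low: 0.0039
        high: 0.0074
    A:
      N:
        family: dirichlet_row_member
        base: 0.1408
        low: 0.0707
        high: 0.2301
      D:
        family: dirichlet_row_member
        base: 0.00554
        low: 0.0
        high: 0.0309
    I:
      N:
        family: dirichlet_row_member
        base: 0.0781
        low: 0.0136
        high: 0.1912
      D:
        family: dirichlet_row_member
        base: 0.00554
        low: 0.0
        high: 0.0438
utilities:
  N:
    family: beta
    base: 0.85
    low: 0.84
    high: 0.86
  U:
    family: beta
    base: 0.63
    low: 0.503
    high: 0.749
  A:
    family: beta
    base: 0.65
    low: 0.518
    high: 0.771
  I:
    family: beta
    base: 0.63
    low: 0.503
    high: 0.749
cost_abuse_per_cycle:
  family: gamma
  base: 2043.0
  low: 52.0
  high: 7536.0
cost_weight_seeing:
  family: gamma
  base: 1.0
  low: 0.75
  high: 1.25
cost_weight_not_seeing:
  family: gamma
  base: 1.0
  low: 0.9
  high: 1.1
cost_intervention_per_woman_cycle:
  family: gamma
  base: 0.46
  low: 0.01
  high: 1.69
cost_referral_once:
  family: gamma
  base: 312.0
  low: 8.0
  high: 1127.0
nhs_cost_share: 0.27807
discount_rate_annual: 0.035
cycle_length_years: 0.5
n_cycles: 20
wtp: 20000.0
cohort_size: 10000
n_psa: 1000
rng_seed: 20180829
stay_mode: printed_stay
accrual: cycle_start
charge_initial_advocates: false
dirichlet_mode: independent_beta
psa_independent_arms: false
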