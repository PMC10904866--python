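# Canonical default configuration. Screening parameters reproduce the
# published programme description; population parameters are synthetic
# stand-ins for the confidential registry (see docs/methods.md).
seed: 0
output_dir: runs
log_level: INFO

population:
  total_size: 10000
  male_fraction: 0.52
  history:
    never_called_fraction: 0.30
    times_called_poisson_mean: 2.0
    adherence_per_call: 0.66
    result_probs: [0.04, 0.93, 0.03]

screening:
  interval_weeks: 52
  sensitivity: 0.96
  specificity: 0.94
  outcome_mode: marginal
  p_positive: 0.04
  p_negative: 0.93
  p_inconclusive: 0.03
  reminder_score: 10.0
  waiting_time_minutes: 10.0
  notice_weeks: 4
  location_score: 20.0
  n_cycles: 10
  n_replicates: 5

decision:
  mode: logistic
  weight_logistic: 0.5
  weight_fuzzy: 0.5
  variability: 0.1
  decision_policy: bernoulli

logistic_model:
  intercept: -0.7
  coefficients:
    pct_prior_adherence: 0.012
    times_called: 0.06
    last_result_negative: 0.15
    last_result_positive: -0.40
    last_result_inconclusive: -0.10

scenarios: []
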