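# Published 4-variable kidney failure risk equation (KFRE), 2-year horizon.
#   risk = 1 - S0 ^ exp( sum_j beta_j * (t_j(x_j) - center_j) )
# with t: age/10, male indicator, eGFR/5, ln(ACR mg/g); centers are the
# development-cohort means.
kfre:
  horizon: 2
  baseline_survival: 0.9832
  terms:
    - {name: age_per_10yr, beta: -0.2201, center: 7.036}
    - {name: male, beta: 0.2467, center: 0.5642}
    - {name: egfr_per_5, beta: -0.5567, center: 7.222}
    - {name: log_acr, beta: 0.4510, center: 5.137}
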