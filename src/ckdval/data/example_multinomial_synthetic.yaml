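# SYNTHETIC example coefficient set for the multinomial absolute-risk engine.
#
# This file demonstrates the ModelSpec format (declarative predictor
# transforms, one intercept and coefficient row per non-reference outcome
# sequence). The coefficients are invented for demonstration and testing:
# they are qualitatively plausible (KRT risk falls with eGFR and rises with
# albuminuria; death risk rises with age) but are NOT the published model.
# Users validating the published risk calculator must supply its coefficient
# file transcribed from the original source.
#
# Linear predictor per category k:
#   LP_k = intercept_k + sum_j beta_kj * (f_j(x_j) - offset_j) / scale_j
# with f = identity or natural log. Reference category: no_event.
horizon: 2
categories:
  - krt_only
  - krt_after_cvd
  - cvd_only
  - cvd_after_krt
  - death_only
  - death_after_krt
  - death_after_cvd
  - death_after_krt_and_cvd
predictors:
  - {name: age, transform: identity, offset: 76.0, scale: 10.0}
  - {name: male, transform: identity, offset: 0.0, scale: 1.0}
  - {name: race_black, transform: identity, offset: 0.0, scale: 1.0}
  - {name: cvd_history, transform: identity, offset: 0.0, scale: 1.0}
  - {name: diabetes, transform: identity, offset: 0.0, scale: 1.0}
  - {name: smoker, transform: identity, offset: 0.0, scale: 1.0}
  - {name: sbp, transform: identity, offset: 143.0, scale: 20.0}
  - {name: egfr, transform: identity, offset: 18.0, scale: 5.0}
  - {name: acr, transform: log, offset: 5.97, scale: 1.0}
intercepts: [-1.27, -3.2, -1.27, -3.2, -1.43, -2.8, -2.5, -3.9]
# rows: categories (order above); columns: predictors (order above)
coefficients:
  - [-0.25, 0.10, 0.05, 0.05, 0.10, 0.05, 0.05, -0.90, 0.45]
  - [-0.10, 0.10, 0.05, 0.40, 0.20, 0.10, 0.15, -0.70, 0.35]
  - [ 0.30, 0.15, 0.00, 0.45, 0.25, 0.15, 0.20, -0.10, 0.10]
  - [ 0.05, 0.15, 0.05, 0.45, 0.25, 0.15, 0.15, -0.60, 0.30]
  - [ 0.55, 0.10, 0.00, 0.30, 0.15, 0.20, 0.00, -0.05, 0.10]
  - [ 0.20, 0.10, 0.05, 0.30, 0.20, 0.20, 0.05, -0.60, 0.30]
  - [ 0.55, 0.15, 0.00, 0.50, 0.25, 0.25, 0.10, -0.10, 0.10]
  - [ 0.30, 0.15, 0.05, 0.50, 0.25, 0.25, 0.10, -0.50, 0.25]
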