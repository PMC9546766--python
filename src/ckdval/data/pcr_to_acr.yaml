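# Urine protein-to-creatinine ratio (PCR, mg/g) -> albumin-to-creatinine
# ratio (ACR, mg/g) crosswalk: piecewise-linear spline in ln(PCR) with knots
# at 50 and 500 mg/g plus sex / diabetes / hypertension indicator terms, as
# published for CKD screening and prognosis use.
#
#   ln(ACR) = intercept
#           + spline_low  * ln(min(PCR/50, 1))
#           + spline_mid  * ln(max(min(PCR/500, 1), 0.1))
#           + spline_high * ln(max(PCR/500, 1))
#           + female * [female] + diabetes * [diabetes]
#           + hypertension * [hypertensive]
pcr_to_acr:
  intercept: 5.3920
  spline_low: 0.3072
  spline_mid: 1.5793
  spline_high: 1.1266
  female: -0.0773
  diabetes: 0.0797
  hypertension: 0.1265
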