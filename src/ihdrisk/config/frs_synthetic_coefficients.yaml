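# SYNTHETIC stand-in for the Framingham coronary heart disease risk score.
# The coefficient values below are NOT the published Framingham estimates;
# they are synthetic placeholders with conventional signs, provided so the
# baseline-score machinery can be exercised end-to-end with a second score.
# Replace this file with a vetted coefficient table before any real use.
name: FRS
covariates: [age, total_chol, hdl, sbp, smoker, diabetes, sex_male]
groups:
  all:
    select: {}
    baseline_survival: 0.90
    mean_linear_predictor: 23.0
    terms:
      - {coef: 3.5, vars: [ln_age]}
      - {coef: 1.1, vars: [ln_total_chol]}
      - {coef: -0.9, vars: [ln_hdl]}
      - {coef: 0.6, vars: [ln_sbp]}
      - {coef: 0.5, vars: [smoker]}
      - {coef: 0.4, vars: [diabetes]}
      - {coef: 0.4, vars: [sex_male]}
worked_examples: []
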