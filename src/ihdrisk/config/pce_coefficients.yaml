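# Pooled Cohort Equations, 10-year first hard ASCVD event risk
# (Goff et al. 2013 ACC/AHA guideline, white male / white female groups).
# Risk = 1 - baseline_survival ^ exp(sum(terms) - mean_linear_predictor).
# Term variables: age (years), total_chol (mg/dL), hdl (mg/dL),
# sbp (mmHg), bp_treated (0/1), smoker (0/1), diabetes (0/1).
name: PCE
covariates: [age, total_chol, hdl, sbp, bp_treated, smoker, diabetes, sex_male]
groups:
  male:
    select: {sex_male: 1}
    baseline_survival: 0.9144
    mean_linear_predictor: 61.18
    terms:
      - {coef: 12.344, vars: [ln_age]}
      - {coef: 11.853, vars: [ln_total_chol]}
      - {coef: -2.664, vars: [ln_age, ln_total_chol]}
      - {coef: -7.990, vars: [ln_hdl]}
      - {coef: 1.769, vars: [ln_age, ln_hdl]}
      - {coef: 1.797, vars: [ln_sbp], if: {bp_treated: 1}}
      - {coef: 1.764, vars: [ln_sbp], if: {bp_treated: 0}}
      - {coef: 7.837, vars: [smoker]}
      - {coef: -1.795, vars: [ln_age, smoker]}
      - {coef: 0.658, vars: [diabetes]}
  female:
    select: {sex_male: 0}
    baseline_survival: 0.9665
    mean_linear_predictor: -29.18
    terms:
      - {coef: -29.799, vars: [ln_age]}
      - {coef: 4.884, vars: [ln_age, ln_age]}
      - {coef: 13.540, vars: [ln_total_chol]}
      - {coef: -3.114, vars: [ln_age, ln_total_chol]}
      - {coef: -13.578, vars: [ln_hdl]}
      - {coef: 3.149, vars: [ln_age, ln_hdl]}
      - {coef: 2.019, vars: [ln_sbp], if: {bp_treated: 1}}
      - {coef: 1.957, vars: [ln_sbp], if: {bp_treated: 0}}
      - {coef: 7.574, vars: [smoker]}
      - {coef: -1.665, vars: [ln_age, smoker]}
      - {coef: 0.661, vars: [diabetes]}
# Worked examples from the source guideline's appendix (55-year-old,
# total cholesterol 213, HDL 50, SBP 120 untreated, non-smoker,
# non-diabetic): used as the config's own oracle.
worked_examples:
  - inputs: {age: 55, total_chol: 213, hdl: 50, sbp: 120, bp_treated: 0, smoker: 0, diabetes: 0, sex_male: 1}
    risk: 0.0538
  - inputs: {age: 55, total_chol: 213, hdl: 50, sbp: 120, bp_treated: 0, smoker: 0, diabetes: 0, sex_male: 0}
    risk: 0.0205
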