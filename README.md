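# ihdrisk

Opportunistic assessment of ischemic heart disease (IHD) risk from
abdominopelvic CT and electronic medical records.

Abdominopelvic CT scans are acquired millions of times a year for
unrelated indications (most often abdominal pain), and a single axial
slice at the third lumbar vertebra (L3) carries body-composition
biomarkers — muscle radiodensity, visceral and subcutaneous fat areas —
that correlate with cardiovascular risk. This package implements a
desk-scale, fully testable version of a multimodal risk-assessment
pipeline built on that idea, for researchers working on opportunistic
imaging and clinical risk modelling:

* **CT preprocessing** — Hounsfield-unit clipping, window/level
  normalization (soft 400/50, bone 1800/400, custom 500/50), 3-channel
  stacking, bilinear resizing with an exact adjoint, and body-mask
  extraction that removes background and the scanner bed.
* **Body composition** — Dice and RMS coefficient-of-variation
  segmentation metrics, tissue areas in cm², mean radiodensity, the
  VAT/SAT ratio, and a reference attenuation-threshold segmenter so the
  pipeline runs without a trained network (any `slice → mask` segmenter
  can be plugged in).
* **Tissue saliency** — the interpretability statistic at the core of
  the package. Given a differentiable scorer with pixel gradient
  `w_ij = ∂S/∂I_ij`, the *observed* saliency of tissue class *t* is its
  share of total gradient magnitude, `S^O_t = Σ_{ij∈t}|w_ij| / Σ|w_ij|`,
  contrasted with the *expected* saliency `S^E_t`, the class's pixel
  share. Cohort-level attention is summarised per class by the ratio of
  means O̅/E̅ with paired t-tests; O̅/E̅ > 1 marks tissue the model
  attends to beyond its area.
* **EMR feature engineering** — outcome labelling from ICD10 I20–I25,
  cohort inclusion filters with a per-rule audit, exponentially
  time-weighted vitals/labs with measurement counts, ontology rollups
  (ICD10 blocks, CPT H2 groups, ATC level 2), the Charlson comorbidity
  index, correlation pruning (|r| > 0.5) and targeted median imputation.
* **Risk models and statistics** — L2-logistic fits with tenfold CV,
  a gradient-boosted clinical model with native missing-value handling,
  feature-concatenation and risk-stacking fusion, config-driven
  published baseline scores (Pooled Cohort Equations), AUROC/AUCPR with
  stratified-bootstrap CIs, the DeLong test, Youden operating points,
  subgroup evaluation and SHAP feature attributions.
* **Synthetic data** — L3-like phantoms (concentric body/SAT/muscle/VAT
  ellipses with tissue-specific HU distributions, air background and a
  scanner-bed strip) and EMR cohorts with a planted logistic outcome
  model, so every stage is exercised end-to-end with recoverable signal
  and no data download.

## Worked example

`examples/02_tissue_saliency.py` plants a scorer whose gradient mass
sits on visceral fat across 25 phantoms and aggregates:

```
       class       O       E    O/E         p
         VAT   0.421   0.068   6.21         0
       OTHER   0.077   0.125   0.62         0
      MUSCLE   0.033   0.053   0.62         0
  BACKGROUND   0.412   0.664   0.62         0
         SAT   0.056   0.091   0.62         0
```

VAT holds 6.8% of the pixels but draws 42% of the gradient magnitude —
an observed/expected ratio of 6.2, ranked first, while every other
class falls below its pixel share; the paired t-tests reject equality
of O and E for all classes. `examples/04_models_and_evaluation.py`
fits the clinical gradient-boosted model on a planted 1200-patient EMR
cohort and prints test AUROC 0.788 (95% CI 0.705–0.851) against an
oracle AUROC of 0.834 from the true coefficients, with the five planted
risk factors (age, male sex, glucose, Charlson index, blood pressure)
occupying the top five SHAP ranks.

The other examples cover phantom generation plus body-composition
extraction (01) and the EMR feature pipeline with its inclusion audit
(03). Each runs in seconds:

```bash
python examples/01_phantom_and_body_composition.py
```

## Scope

The package deliberately does not train the deep segmentation or
imaging networks of a production system: segmenters and scorers are
interfaces, with a threshold segmenter and analytic-gradient scorers
provided as reference implementations. DICOM ingestion, 3-D
volumetrics and survival modelling are out of scope. See
`docs/methods.md` for the model descriptions, parameter choices and
known limitations.
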