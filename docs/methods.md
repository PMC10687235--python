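# Methods

This note documents the models and procedures implemented in `ihdrisk`,
the parameter choices that matter, what the synthetic generators do and
do not emulate, and the numerical conventions.

## Problem setting

The package targets opportunistic IHD risk assessment: a patient
receives an abdominopelvic CT for an unrelated indication, and the
axial slice at L3 plus the patient's medical history are used to
estimate the probability of a new ischemic-heart-disease diagnosis
(ICD10 I20–I25) within a 1- or 5-year horizon. Patients with any IHD
diagnosis at or before the scan are excluded — the goal is detecting
*new* disease.

## CT preprocessing

* **Windowing.** `apply_window` maps HU through the inclusive linear
  ramp `v ↦ clamp((v − (level − width/2)) / width, 0, 1)` — the
  standard radiology display convention; only W/L pairs are specified
  by presets (soft 400/50, bone 1800/400, custom 500/50 HU).
* **Scorer input.** `prepare_scorer_input` clips to [−1000, 1000] HU,
  replicates to three channels and resizes bilinearly. The resize is
  implemented as a separable linear operator (`out = R·img·Cᵀ`) with
  corner-aligned sampling, so constants are reproduced exactly and the
  *adjoint* (`Rᵀ·g·C`) — not an approximate inverse — maps gradients
  from the resized grid back to native pixels. Interpolation is
  bilinear for images and nearest for masks: mask labels must stay
  categorical. The choice of bilinear over spline is a convention; the
  exact adjoint is what saliency correctness rests on.
* **Body mask.** Pixels above −200 HU are candidate tissue; connected
  components that touch the bottom image edge and cover less than 20%
  of the largest component are discarded as the scanner bed; the
  largest surviving component is kept and its internal holes filled.
  The −200 HU threshold sits comfortably between air/bed plastic and
  soft tissue; the bed rule is a heuristic standing in for the
  "traditional image processing" such pipelines use. On phantoms the
  mask matches the analytic body ellipse at Dice ≥ 0.98 and is
  invariant (≤ 0.5% of body pixels) to adding the bed.

## Body composition

Dice is `2|A∩B| / (|A|+|B|)` per class; a class empty in both masks
scores 1.0 (perfect agreement on absence), avoiding NaNs in per-class
sweeps. The RMS coefficient of variation uses the duplicate-measurement
convention — the s.d. of a (manual, automated) pair is `|d|/√2`, its CV
is that over the pair mean, and pairs combine root-mean-square, in
percent. Tissue areas are pixel counts × pixel area (cm²); the VAT/SAT
ratio is spacing-free by construction.

The reference `threshold_segmenter` uses the common body-composition
attenuation ranges — adipose [−190, −30] HU, muscle [−29, 150] HU,
both configurable — with anatomical rules in place of a trained
network: adipose components adjacent to the body surface are SAT,
interior adipose is VAT, and muscle-range components adjacent to SAT
form the abdominal-wall annulus; interior soft tissue in the same HU
range stays "other". On default phantoms every class reaches Dice
≥ 0.90 against ground truth (muscle and SAT ≈ 1.0; VAT ≈ 0.94, the
shortfall being other-tissue pixels whose sampled HU falls in the
adipose range). A trained segmenter can replace it behind the same
`(slice, body) → mask` surface.

## Tissue saliency

For a scorer S with pixel gradient `w_ij`, per image:

* observed: `S^O_t = Σ_{ij∈t} |w_ij| / Σ_{ij} |w_ij|`
* expected: `S^E_t = |{ij ∈ t}| / total pixels`

over the five classes background/muscle/VAT/SAT/other. Conventions:

* `|·|` is the L1 norm over the class's pixels; the signed map is
  stored, magnitudes are taken at aggregation.
* Replicated-channel gradients are summed before the magnitude: the
  channels are copies of one image, so the derivative w.r.t. the
  underlying pixel is the channel sum.
* Saliency is aggregated on the *native* grid: gradients computed on a
  resized grid are pulled back through the resize adjoint first.
* Magnitudes are normalized by their maximum before summation. This is
  scale-free (S^O is invariant to `w → c·w`) and makes the
  constant-|w| identity `S^O ≡ S^E` hold exactly in floating point,
  since all addends become exact integers.
* Class assignment resolves conflicts in favour of the body mask: a
  pixel labelled muscle outside the body is background; BONE labels
  collapse to "other"; anything inside the body not muscle/VAT/SAT is
  "other".
* An image with identically zero gradient has no attribution signal;
  it raises an explicit error per image and is excluded (and counted)
  at cohort level, never imputed.

Cohort aggregation averages S^O and S^E per class across images and
reports the **ratio of means** O̅/E̅ (not the mean of per-image
ratios; both views are derivable from the stored per-image results),
with two-tailed paired t-tests on the per-image (S^O, S^E) pairs.
Zero-variance differences are handled explicitly (p = 1 when all
differences are zero). Fewer than two images yields ratios with NaN
p-values and a warning.

Scorers are anything exposing `score(image) → float` and
`gradient(image) → array`; the bundled linear, quadratic and
class-weighted scorers have closed-form gradients verified against
central finite differences (≤ 1e-6 relative on probes), which makes
them exact oracles for the saliency pipeline.

## EMR features

All history windows are half-open: `(scan − 365 d, scan]` for
features, `(scan, scan + horizon]` for the outcome.

* **Temporal aggregation.** Repeated vitals/labs combine with weights
  `u_i = exp(−λ·Δt_i)`, default half-life 30 days (λ = ln 2/30 per
  day). The phrase "exponential weighting inversely proportional to the
  time difference" admits a second reading, `u_i = 1/(1 + Δt_i)`,
  available behind the `scheme="inverse_time"` switch rather than
  hidden. Weights are computed relative to the most recent measurement
  so extreme decay rates cannot underflow; the λ→∞ limit is the most
  recent value. Empty series yield NaN (missing), not an error.
* **Counts.** The number of measurements of each vital/lab in the
  window is itself a feature (healthcare-utilisation signal).
* **Code rollups.** ICD10/CPT/drug codes map to groups by longest
  prefix (toy block/H2/ATC-2 tables ship as editable TSVs);
  feature values are occurrence counts, which subsume indicators.
  Unmapped codes are reported, never fatal.
* **Charlson index.** Sum of condition weights over *distinct*
  conditions matched by ICD10 prefix, codes at or before the scan; the
  prefix→condition map and weights are an editable TSV following the
  standard ICD-10 coding of the index.
* **Pruning.** Pairs with |Pearson r| > 0.5 (pairwise-complete) are
  broken by dropping the later column in table order, greedily from
  the worst pair, until the recomputed maximum is ≤ 0.5. Strictly
  greater-than: a pair at exactly the threshold survives.
* **Imputation.** Only explicitly targeted features (the lipid
  covariates required by baseline scores) are median-imputed, with
  medians from the training split only; all other missing values pass
  through to the learner. Demographics are age at scan and a male-sex
  indicator; race/ethnicity is deliberately not a feature.

The audit of inclusion filtering is conservative by construction:
input count = included + Σ per-rule drops, with rules applied in a
fixed order (age ≥ 18, prior-year encounter, no prior IHD, adequate
follow-up, then chronological-greedy 6-month deduplication per
patient). Patients whose outcome occurs inside the horizon are not
dropped for short follow-up.

## Models

* `fit_l2_logistic_cv`: standardized features, L2 penalty chosen from a
  logarithmic grid by mean validation AUROC over stratified tenfold CV,
  ties toward the smaller penalty, refit on the full training split.
  Folds shrink with a warning when the minority class is scarce.
* `clinical_gbm`: XGBoost classifier with native NaN routing.
  The default search space is three configurations chosen for the
  shape of EMR designs (wide, many weakly informative code counts,
  few events): L1-regularized depth-1 stumps (1000 trees, η 0.05,
  α 10) for sparse additive surfaces, unregularized stumps, and
  depth-3 trees for interactions; tenfold CV picks per dataset.
* Fusion: `concat_fusion` boosts on baseline-score covariates plus the
  two body-composition features; `stack_models` fits L2 logistic
  regression on component models' predicted risks (2 or 3 columns).
* `BaselineScoreSpec` evaluates published Cox-form scores
  (risk = 1 − S₀^exp(lp − l̄p)) from YAML coefficient configs. The
  bundled PCE config carries the published white male/female
  coefficient groups and reproduces its source's worked examples
  (5.4% / 2.1% ten-year risk) as a self-check; the bundled FRS file is
  a clearly labelled synthetic placeholder exercising the machinery.
* `shap_summary` delegates to the TreeSHAP implementation inside
  XGBoost (`pred_contribs`) and verifies additivity (contributions +
  base = margin) on sampled rows.

## Evaluation statistics

AUROC is the Mann–Whitney rank form with ties at ½; AUCPR is
non-interpolated average precision (its chance level equals
prevalence). Confidence intervals are percentile stratified bootstrap
(cases and controls resampled separately — essential at the ~4%
prevalence typical of 1-year IHD cohorts). AUROC comparisons use the
paired DeLong test via structural components with a two-tailed normal
p (degenerate zero-variance pairs report Δ=0, p=1); AUCPR comparisons
use a paired stratified bootstrap (same resample evaluated under both
models), two-tailed. The Youden operating point maximizes
sens + spec − 1 over observed-score thresholds with ties resolved to
the lowest threshold (maximal sensitivity at equal J). Subgroup tables
flag small or single-class groups instead of dropping them. α = 0.05,
all tests two-tailed.

## Synthetic generators

The phantom is concentric ellipses — SAT ring under the skin, muscle
wall, inner cavity of VAT around a central "other tissue" block — with
an air background and an optional ~0 HU bed strip. Chosen for
closed-form areas: expected pixel fractions are analytic, so
discretisation is the only error term in geometry tests. Default HU
distributions (background −1000±5, SAT −100±15, VAT −90±15, muscle
45±12, other 30±40) follow published attenuation conventions; the
geometry (body semi-axes 150×105 mm, SAT 18 mm, muscle wall 12 mm, VAT
fraction 0.35 at 1.5 mm spacing) is a realistic adult abdomen. What it
does not emulate: organ texture, bone, partial-volume effects,
contrast phases, scanner physics, 3-D continuity — so passing tests
demonstrate correctness of the *measurement and attribution
machinery*, not clinical segmentation performance.

Imaging cohorts jitter per-patient geometry and muscle HU, compute the
two body-composition features from ground truth, and draw labels from
a logistic model on z-scored features with an intercept solved (by
root-finding) to hit the target prevalence. EMR cohorts generate
latent physiology (age, sex, blood pressure, lipids, glucose/HbA1c
with a diabetic subgroup, renal disease), chart it as dated
observations with measurement noise and per-lab missingness (default:
a lab series is entirely absent for 10% of patients), emit consistent
codes (hypertension, diabetes, renal, statins, diuretics, encounters),
and guarantee inclusion-filter compliance. Labels come from a logistic
model on z-scored *latent* features; the retained oracle predictor is
β·z (label noise is applied only to the sampling step, so the oracle
is a fair upper reference, not an unbeatable one). Geometry/chart and
label RNG streams are separate throughout.

## Numerical and scale choices

* Phantom studies run at 128 px (3 mm pixels) for cohort-level
  analyses; the default single-phantom size is 256 px. Chosen so the
  full suite and the acceptance script complete in about a minute
  each.
* Recovery studies use 2000-patient EMR cohorts (15% prevalence,
  label-noise s.d. 0.3) and 800-patient imaging cohorts. At a test
  split of 400 patients the GBM-vs-oracle AUROC gap has appreciable
  sampling spread (roughly ±0.02 across data seeds around a mean near
  0.02); single-seed gaps up to ~0.05 are consistent with a correct
  implementation.
* Bootstrap coverage uses 200 binormal datasets (n = 200, true AUROC
  Φ(μ/√2)) at 500 resamples.
* Determinism: every stochastic routine takes an explicit seed; child
  streams are spawned via `np.random.default_rng([seed, k])`.

## Known limitations

* The threshold segmenter's anatomical rules assume a closed
  SAT/muscle topology; pathologies breaking it (hernias, open muscle
  walls) would need a learned segmenter.
* DeLong p-values are asymptotic; at very small n or extreme AUROCs
  the permutation comparison is the safer reference.
* The Charlson and ontology tables are deliberately small, editable
  stand-ins covering the code families the generators emit — not full
  terminology releases.
* The FRS config is synthetic (see its header); only the PCE config
  carries published coefficients.
* Feature vectors are built record-by-record in Python; for cohorts
  far beyond 10⁴ patients a vectorised path would be warranted.
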