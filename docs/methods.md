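# Methods

## Diagnostic model

The core classifier is single-response OPLS-DA. A two-group contrast
(RA vs healthy controls, or RA vs PsoA — always modelled separately)
is encoded as y = +1 for RA and −1 for the reference group; RA is
positive purely for display consistency, the assignment does not
affect the fit. With a single response every NIPALS step is
closed-form, so fitting is a finite sequence of matrix products
(norm tolerance 1e-12, no convergence loop). The model extracts
`n_orth` orthogonal components (weight `w_orth`, loading `p_orth`,
scores `t_orth`) by deflating `X ← X − t_orth p_orth'`, then one
predictive component on the filtered matrix.

Structural identities that hold to machine precision, and are asserted
by the test suite on every fit: `w ⊥ w_orth,j`; `t ⊥ t_orth,j`;
`corr(t_orth,j, y) = 0`; and the total sum of squares of the scaled
matrix decomposes exactly into predictive + orthogonal + residual
parts. Prediction deflates a new sample with the stored
`(w_orth, p_orth)` pairs and maps the predictive score through the
response loading; consequently a test sample moved along any fitted
orthogonal loading direction `p_orth,j` — the form orthogonal
variation takes in data space — receives an identical prediction.
(Invariance along the *weight* `w_orth` is not a property of this
predictor: the prediction change is `−α (p_orth'w) c`, and
`p_orth'w = 0` cannot hold when the orthogonal weight is extracted
from the loading residual. The loading-direction statement is the
meaningful one: a sample carrying extra orthogonal variation differs
from its twin by `Δt_orth · p_orth`.)

Decision rule: classify as RA when the predicted response is at or
above the training mean of y (ties go to the positive class; on
balanced training sets this is the sign rule on the centered
response). Q² is computed as 1 − Σ(y − ŷ_oof)² / Σ(y − ȳ)² over
out-of-fold predictions.

Default `n_orth` is 1. The generator plants a rank-1 nuisance
structure, and on real tables a single orthogonal component is the
conservative default; `select_n_orth` optionally picks the count in
`0..max_orth` maximizing cross-validated Q², breaking ties toward
fewer components.

## Preprocessing

Metabolite intensities are positive and right-skewed, so the default
pipeline takes natural logs, then mean-centers and unit-variance (UV)
scales each metabolite; Pareto (divide by √SD) and centering-only are
provided because the scaling used by the original commercial software
is not recorded. SDs use the n−1 denominator; constant metabolites get
scale 1 with a warning. Missing values (carried explicitly as NaN,
never zero) are imputed with the half-minimum rule — half the observed
training minimum of that metabolite.

Scalers are fitted on training rows only and applied frozen to
held-out data; inside cross-validation they are refit in every
training fold. This is stricter than scaling once on the full matrix
(which the original workflow most likely did); a `leaky_scaling`
flag reproduces the looser convention for comparison.

## Cross-validation and external validation

Diagnosis is evaluated with sevenfold cross-validation: one-seventh of
the samples are held out, the scaler and OPLS-DA model are fitted on
the rest, and the held-out samples are predicted; repeated so every
sample is left out once. Folds are stratified by class — with 9
controls against 21 RA samples an unstratified partition can leave a
fold with one class only — by dealing each class round-robin through a
common random fold order, so per-class and overall fold sizes differ
by at most one. A `stratify=False` option restores the plain random
partition. Sensitivity = TP/(TP+FN) over RA samples,
specificity = TN/(TN+FP) over the reference group; fractions are kept
at full precision and rendered as whole percentages only in reports.

External validation mimics a two-study design: both feature tables are
restricted to the metabolites identified in both (exact name match
after trimming and case-folding; no synonym table), the discovery
study is optionally subsampled to a balanced 9 observations per group
(deterministic given the seed), one model is fitted, and every sample
of the second study is predicted.

## Metabolite-level reporting

Univariate screening uses two-sided pooled-variance Student's t-tests
per metabolite, deliberately uncorrected for multiple testing: the
diagnosis rests on the multivariate model, and the P values only
illustrate each metabolite's individual impact. Only identified
metabolites are reported by default. Heat maps show standard scores
against a reference group — z = (x − mean_ref)/sd_ref on the raw
intensity scale (display is about relative concentration, independent
of model scaling), reference SD with the n−1 denominator — truncated
to ±2 for legibility, with samples grouped by class and metabolites
ordered by p(corr) from the largest negative to the largest positive
correlation to RA.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes:

* log-normal intensities, `log x_ik = μ_k + shift_ik + λ_k z_i + ε_ik`,
  with metabolite baselines `μ_k ~ N(10, 1)` (log scale, arbitrary
  semiquantitative units) and noise `ε ~ N(0, 0.3²)`;
* a planted marker panel mirroring the reported differential
  metabolites: 9 RA-vs-control markers (glyceric acid, D-ribofuranose,
  hypoxanthine increased; histidine, threonic acid, methionine,
  cholesterol, asparagine, threonine decreased) and 19 RA-vs-PsoA
  markers, shifted by 0.8 log-units. Only directions, not effect
  sizes, are published; 0.8 was chosen once so the default 21/9 cohort
  separates strongly but imperfectly, qualitatively matching the
  reported 81–94% operating points. RA-vs-control effects shift the
  RA group; RA-vs-PsoA effects shift the PsoA group with the opposite
  sign, so each contrast sees its own marker panel (metabolites listed
  for both contrasts, e.g. histidine, are shifted in both groups);
* a rank-1 nuisance: one latent `z_i` per sample with loadings
  `λ_k ~ N(0, 0.5²)`, standing in for sex/age/sampling/batch
  variation. The latent is centered within each clinical group by
  default: nuisance is *defined* as variation uncorrelated with the
  diagnosis, and at n = 30 an i.i.d. latent would correlate with the
  group label by chance (sd ≈ 0.19), making high-loading nuisance
  metabolites genuinely disease-associated in-sample — a confounded
  cohort rather than orthogonal variation. `nuisance_group_centered
  = False` restores the i.i.d. latent. The exact-orthogonality
  constraint couples folds weakly (the training-fold covariance of z
  with y is the negative of the held-out fold's), giving
  cross-validation at the null a small conservative bias — measured
  mean sensitivity/specificity ≈ 0.47/0.43 instead of 0.5 over 50
  null cohorts, within three binomial standard errors of chance;
* study pairs: the validation cohort (14 RA / 20 controls, 240
  metabolites) shares exactly 52 identified metabolite names with the
  discovery cohort; shared metabolites keep their baselines and
  nuisance loadings across studies (semiquantitative scales are
  treated as comparable between cohorts, a favourable assumption),
  while all sample-level draws are independent. Planted markers are
  always placed in the shared set, mirroring that the real validation
  subset retained the discriminating metabolites;
* missingness is off by default; a missing-at-random rate is available
  for exercising the imputation path.

What the generator does **not** emulate: metabolite–metabolite
covariance networks, platform drift and batch alignment artifacts,
heteroscedastic (intensity-dependent) noise, cohort-specific baseline
shifts, and age/sex structure beyond a single shared latent. Passing
tests therefore demonstrate that the pipeline recovers the structure
it assumes — they are not a claim about diagnostic accuracy on real
serum profiles, and the synthetic operating points (which exceed the
published ones) should not be compared to them numerically.

## Problem sizes and numerical choices

Simulation-backed checks use 20 cohorts per condition (50 for null
calibration, 10 study pairs for validation metrics) at the default
cohort sizes; these suffice to estimate means of binomial rates to a
few percent. All randomness flows from explicit integer seeds through
`numpy`'s `default_rng`; reruns are bit-identical. Norm and division
guards use 1e-12; orthogonality assertions use 1e-8; oracle
equivalences (one-component PLS1, textbook t-test) are checked at
1e-10–1e-12. Zero-variance metabolites yield p(corr) = 0, z = 0 and
t = 0 / p = 1 respectively, each with a warning rather than an error,
since constant columns are common in thresholded semiquantitative
data.

## Known limitations

* Single predictive component only (binary response); multi-class or
  multi-response OPLS is out of scope.
* The number of orthogonal components in the original models is
  unreported; the default of 1 is a modelling choice.
* Exact reproduction of the published P values and operating points is
  impossible without the undeposited cohort data; all quantitative
  outputs here are properties of the synthetic conditions.
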