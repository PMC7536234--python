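# Methods

This note documents the models, conventions and numerical choices behind
`ovarad`, in the order the pipeline runs them.

## Synthetic phantom cohorts

The generator emulates the study design the pipeline targets: single-frame
greyscale transvaginal ultrasound images of healthy ovaries with manually
delineated ROI masks, 1–4 images per patient (one per ovary-side × scan
plane slot), four scanner profiles, and roughly one carrier patient in
three.

**Image model.** One phantom is a smooth echogenicity map — a constant
ovary parenchyma level (default 95 grey) on a dimmer background, plus a
Gaussian-filtered large-scale shading field (SD 8 grey, correlation length
image_size/10) — multiplied by spatially correlated Rayleigh speckle
(scale √(2/π) so the speckle has unit mean, then a σ = 0.7 px Gaussian
filter to give the grain a finite correlation length), clipped to [0, 255]
and quantized to 8 bits. The ovary is an ellipse with semi-axes sampled in
millimetres (10–15 × 6–10 mm), random orientation and a jittered centre;
0–3 dark circular follicles (radius 1–2.5 mm, echogenicity × 0.35) act as
class-independent nuisance structure and are excluded from the ROI mask,
with placements that would fragment the 4-connected mask rejected. This is
deliberately the simplest texture-bearing surrogate of B-mode speckle:
there is no beamforming, attenuation, point-spread anisotropy or shadowing,
so passing tests demonstrate that the pipeline recovers a planted texture
contrast under speckle-like noise — not that it would perform equally on
clinical images.

**Planted class effect.** Carriers receive extra small bright spots:
Poisson-many with rate `spot_rate·(1+effect_size)` per 100 ROI pixels
(default rate 0.8) and additive increment `spot_boost·(1+effect_size)`
(default 200 grey) over discs of 1–2 px diameter. The boost is added
*after* the speckle multiplication: added before it, the spots smear across
grey levels and run lengths and barely register in run-length statistics;
added after it they saturate towards 255 and read as crisp short runs /
small clusters of high grey level — which is precisely the phenotype the
effect is meant to plant. A corollary is that once spots saturate, the
`(1+effect_size)` scaling of the boost is nearly inert and the effect is
carried by the spot count. The effect enters *only* through the spot
parameters, so at `effect_size = 0` the carrier and wild-type laws are
identical draw for draw and the cohort is exactly exchangeable — the basis
of the null-calibration checks. At `effect_size = 2` the carrier − wild-type
median gap in short-run high-grey-level emphasis is about two within-class
standard deviations, and the gap is monotone in the effect size (checked at
0.5 / 1 / 2 with 100 images per class).

**Scanners.** Each of the four machine profiles applies a monotone
intensity response `clip(gain · 255 · (v/255)^γ + floor)` and sets the
pixel spacing. Magnitudes are deliberately mild (γ 0.96–1.04, gain
0.98–1.03, floor 0–2 grey, spacing 0.24–0.26 mm): images of one patient
share a machine, so strong systematic machine shifts would correlate
same-patient feature values and visibly inflate the size of the per-image
univariate screen. With the default profiles the empirical screen size on
a null cohort is statistically indistinguishable from the nominal level
(measured by `scripts/acceptance.py`); spacing-driven ROI-pixel-count
differences were the dominant inflation channel at stronger settings.

**Determinism.** All randomness flows from a single `numpy` Generator
seeded by `CohortSpec.seed`; DICOM UIDs are content-derived hashes, so an
identical spec reproduces byte-identical files.

## ROI normalization and discretization

Feature computation sees only masked pixels. They are rescaled linearly so
the ROI histogram spans [0, 255] (`v' = 255(v−min)/(max−min)`); a constant
ROI maps to all zeros rather than dividing by zero, keeping "dark"
semantics. All families — including the first-order statistics — are
computed on these normalized values; this makes the whole feature vector
(except the intensity-weighted centre-of-mass shift) invariant to strictly
increasing affine transforms of the raw intensities, which is tested end
to end. Texture matrices use equal-width binning into N<sub>g</sub> = 32
levels over [0, 256) (`level = min(N_g, ⌊v'·N_g/256⌋+1)`); 32 is the
common radiomics default and keeps 2D matrices dense. Masks are binarized
at > 0; ROI masks must be single 4-connected components of ≥ 16 pixels.

## Feature catalog (232)

The composition — 20 first-order, 14 morphology, 183 texture
(100 co-occurrence + 64 run-length + 16 size-zone + 3 distance-zone),
15 fractal — is a reconstruction that reproduces the published family
totals of the analysis this package re-implements; the exact upstream
composition is not printed anywhere, so the catalog is an ordered,
name-unique registry that alternative compositions can replace. Feature
definitions follow the IBSI-style standard formulary where one exists.
Choices worth noting:

* **GLCM**: symmetric matrices, distances 1 and 2, the four in-plane
  directions; "avg" computes features per direction and averages, "merged"
  pools the directional matrices first. For single-frame input the 2.5D
  merged variant coincides with 2D merging, hence the `2.5Dmerged` name
  tags. No-pair degenerate matrices fall back to energy 1 / others 0.
* **GLRLM**: maximal constant-level runs per direction, background breaks
  runs; the 0° features carry the bare `F_rlm.` names and the other
  directions are suffix-tagged, so rotating an image by 90° permutes the
  0↔90 and 45↔135 blocks exactly.
* **GLSZM / distance zones**: 4-connected zones; zone distance is the
  city-block distance to the ROI border (border pixels at distance 1, the
  image edge counts as border), minimized over the zone.
* **Degenerate fallbacks** are fixed values, never missing entries, so
  feature tables stay rectangular: a constant ROI has histogram entropy 0,
  uniformity 1, co-occurrence energy 1, zero grey-level variances, zero
  skewness/kurtosis/CoV. Run and zone *entropies* are geometry-sensitive
  and legitimately nonzero on a constant ROI (run lengths still vary
  across scan lines).
* **Fractal**: the masked normalized image is thresholded at
  t·255 for t = 0.05…0.75; occupied boxes are counted at dyadic sizes on a
  grid anchored at the mask bounding-box origin and FD is minus the slope
  of an unweighted least-squares fit of log N(s) on log s. An empty set
  gives FD 0; fits with one usable scale are flagged degenerate.
* **Morphology**: areas scale with the per-axis spacing exactly; length
  descriptors use the mean row/col spacing and therefore assume
  near-isotropic pixels (the synthetic scanners are isotropic).

## Univariate screening

Zero-variance columns are dropped, then pruning iteratively finds the pair
with the largest |Pearson r| above the threshold (default 0.9) and drops
the member with the larger mean absolute correlation against all remaining
features — the classic R `caret::findCorrelation` behaviour, adopted
because the analysis being re-implemented was R-based; ties drop the
later catalog name, making the result deterministic and idempotent.
Survivors get two-sided Wilcoxon–Mann–Whitney p-values: exact enumeration
when both groups have ≤ 25 observations and no ties, otherwise the normal
approximation with tie and continuity corrections. No multiplicity
correction is applied by default; the report contrasts the observed
significant count with the expected type-I count m·α (a Benjamini–Hochberg
option exists, off by default).

Tests are per image while the outcome is per patient, so multiple images
of one patient are treated as independent observations — an optimistic
convention inherited from the study design. The generator draws each
image's phantom independently given the machine, which keeps the default
null calibration honest; real repeated scans of one ovary would be more
strongly dependent, and the screen should then be read as a ranking
device rather than calibrated inference.

## Classification strategies

The outer split is per patient (default 75% train, stratified by patient
label, fraction applied per stratum and rounded to nearest). Inside
cross-validation, folds are also grouped by patient — stricter than the
outer-split guarantee alone, adopted for the same leakage rationale. The
positive class is `carrier`; classification is `score ≥ cutoff ⇒ carrier`.

* **ROC/Youden**: candidate cutoffs are the sorted unique scores plus +∞;
  the optimum maximizes J = Se + Sp − 1, ties resolved to the lowest
  threshold. κ = (p_o − p_e)/(1 − p_e) with κ ≡ 0 when p_e = 1.
* **Forward selection (A, B)**: starting from n = 1, each remaining
  feature is fitted together with the held set, scored by the training κ
  at that model's Youden cutoff, and the best is kept (ties → earlier
  pool order); iteration stops when no candidate strictly increases κ, so
  the selection trace is strictly increasing and finite. Logistic
  regression is an unpenalized maximum-likelihood fit; the SVM uses C = 1
  with the `scale` bandwidth 1/(p·Var) and its decision-function values as
  ROC scores; both standardize features on training statistics.
* **Strategy C**: exhaustive grid over depth {2,3,4} × learning rate
  {0.05,0.1,0.3} × trees {50,100,200} × subsample {0.7,1.0}, scored by
  patient-grouped 5-fold CV misclassification error, first-in-grid-order
  tie-break, refit on the full training split; per-feature importance is
  the booster's total split gain.
* **Strategy D**: a compact genetic pipeline search (population 24,
  8 generations, tournament size 3, crossover 0.7, mutation 0.25, elitism)
  over genomes of {no-op, variance filter} × {logistic, RBF-SVM, boosted
  trees, random forest} × bounded hyperparameter ranges, fitness = the
  same grouped CV error with per-genome caching. It preserves the defined
  computation of an automated-ML search (a GA minimizing grouped 5-fold CV
  error) at a size that runs in minutes on one CPU; it is not a
  reimplementation of any particular auto-ML system's operator set.

On null cohorts the Youden-cutoff strategies are *expected* to sit at or
below the majority-class accuracy while κ ≈ 0: a Youden operating point
balances sensitivity and specificity, and on an imbalanced null its
expected accuracy is (1−π) + Se(2π−1) ≤ 1−π for π < ½. The no-signal
sanity test therefore asserts κ ≈ 0 (two-sided) and no accuracy excess
over the majority rate (one-sided), rather than accuracy equality.

## Problem sizes used in the checks

The shipped experiments are sized for a single CPU: the screening-size
check simulates 100 patients (~240 images) and pools 50 label
permutations; effect-recovery runs use 60-patient cohorts at effect size
2 and 25 replicate feature-level cohorts for the selection-order check;
the monotonicity check uses 100 images per class at three effect levels.
These sizes give Monte-Carlo errors comfortably inside the asserted
tolerances while keeping the full suite around two minutes.

## Known limitations

* The phantom is a statistical texture surrogate, not an acoustic
  simulation; machine heterogeneity is a monotone intensity map plus a
  spacing change, with no resolution or point-spread differences.
* The 232-name catalog preserves family counts and all externally
  documented feature names, but individual values are not claimed to match
  any specific legacy implementation bit for bit.
* Per-image testing of a per-patient outcome understates dependence for
  real repeated imaging (see Screening above).
* Length-type morphology features assume near-isotropic pixel spacing.
* The genetic search is deterministic given a seed but, like any small GA,
  only explores a modest genome space; it is a search procedure, not a
  guarantee of the CV-optimal pipeline.
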