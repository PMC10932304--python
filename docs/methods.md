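# Methods

## The clinical rules

The R score is (ALT/ULN_ALT)/(ALP/ULN_ALP) with ULN_ALT = 56 U/L and
ULN_ALP = 147 U/L; bilirubin ULN is 1.2 mg/dL. Labels are assigned in a
fixed order — recovered (both enzymes below ULN), hepatocellular (ALT ≥ ULN
and R ≥ 5), cholestatic (ALP ≥ ULN and R < 2), mixed (2 ≤ R < 5 with both
enzymes elevated) — and anything outside these rules is reported as
`unclassifiable` rather than coerced into a class: the rule set is not
exhaustive (e.g. R in [2, 5) with a single elevated enzyme), and surfacing
the gap is more honest than guessing. Two boundary conventions are
explicit and configurable: the hepatocellular boundary is R ≥ 5 (the strict
R > 5 reading is a flag), and R = 2 falls to mixed because the cholestatic
rule demands R < 2. Whether "recovered" should additionally require normal
bilirubin is genuinely ambiguous in clinical practice, so both variants are
computed (`label` and `label_bil` in `classify_cohort`).

## QC-SVRC drift correction

Within a batch, each feature's pooled-QC intensities are regressed on
injection order with ε-SVR (RBF kernel); corrected intensity = raw ×
(median QC)/(trend at that injection). The correction is multiplicative and
strictly positive where applied, so zeros, signs and missingness are
preserved, and batches are processed independently.

Hyperparameters (per feature × batch, all overridable via `svr_params`):

* ε = 5% of the median QC intensity. The ε-insensitive tube sets a floor on
  the residual QC spread — drift inside the tube is invisible to the loss —
  so ε should match pooled-QC technical repeatability (typically ~5% CV for
  LC-MS), not be an order larger.
* C chosen from {1, 10, 10², 10³, 10⁴} × median QC intensity by
  leave-one-out RMSE over the batch's QC points (C has intensity units, so
  the grid is scaled per feature).
* RBF γ = 1 / median pairwise squared injection-order distance among the
  QCs (median heuristic) — a lengthscale of the order of the QC spacing.

Features with fewer than `min_qc` = 5 QC points in a batch pass through
flagged `skipped_insufficient_qc` (leave-one-out selection is meaningless
below that), as do features whose fitted trend is not strictly positive
wherever it would be applied (`skipped_degenerate`).

## Imputation, transformation, scaling

Missing (and non-positive) cells are imputed at half the per-feature
minimum observed in the *training* matrix, then log10, then autoscaling
with train-derived mean/SD. Half-minimum rather than zero because the log
requires positivity and missingness in LC-MS is concentrated at the low
end. Zero-variance or all-missing training features are excluded and
recorded in the scaler state. The scaler is always fitted inside a
training partition and applied unchanged to held-out samples.

## Univariate screen

Welch's two-sample t (unequal variances) per feature, Benjamini–Hochberg
adjustment across features, selection at q < 0.05. The screen is computed
and reported as a per-feature table; the PLS feature path is driven by VIP
selection, not by the screen — callers who want the intersection can
restrict the intensity matrix to `ScreenResult.selected` before training.

## PLS1-DA, VIP, and the encoding choice

PLS is fitted by NIPALS with X- and y-deflation; for a single response each
component is closed-form (w ∝ X'y), so fitting is deterministic with no
random initialisation, scores are mutually orthogonal, and the first *a*
components of a larger fit equal a fit with `n_lv = a` — the whole
complexity path comes from one fit, which the CV loops exploit. y is
centred, never scaled. At full rank the fit reproduces ordinary least
squares, which the tests use as an independent oracle.

Class encoding is {target: 1, rest: 0} with decision threshold 0.5. The
symmetric ±1 encoding is available and affinely equivalent for
classification, but 0/1 is the default because the ternary readout treats
the three raw predicted values as 0–100% axes: with 0/1 encoding a sample
that is a convex mixture of the class poles predicts, to first order, its
mixture weight on each axis, so the clipped-and-renormalised triple
estimates the latent mixture directly. With ±1 encoding the same triple
collapses mixtures toward vertices.

VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with
SSY_a = q_a²·t_a't_a, the standard formulation, pinned by the identity
mean(VIP²) = 1 (asserted to 1e-9 in the tests).

## Subject-wise double cross-validation

Folds partition *patients* (shuffled with the seed, dealt round-robin), and
samples inherit their patient's fold, so longitudinal replicates never
straddle a train/test split. The outer loop (k = 5 by default) holds out
patients for the error estimate; the inner loop (k = 5) runs inside each
outer-training partition and selects the LV count by CV classification
accuracy with the one-standard-error rule (smallest count within one SE of
the best; plain argmax behind a flag) — accuracy curves plateau and the
1-SE rule resists overfitting the inner folds. Mixed-type patients (any
sample labelled mixed) are excluded from all folds; their samples are
decomposed by the final ensemble, which makes them genuinely held out.

Per training partition: scaler → LV selection → stage-1 PLS on all
features → VIP ≥ 1 selection → recomputed scaler and stage-2 refit on the
selection. Nothing (scaler, LV count, VIP set) is computed outside a
training partition; the test suite enforces this with a leakage canary — a
feature that encodes the class only on held-out patients must not move
outer accuracy.

The LV counts and VIP set sizes are re-derived on every dataset; per-fold
choices and the final refit choice are both reported. No class reweighting
is applied; balanced accuracy is reported alongside raw accuracy.

## Ternary mapping and monitoring

Raw triples are clipped below zero and renormalised; an all-nonpositive
triple maps to the barycentre and is flagged degenerate (softmax is
available behind a flag for comparison). Clip-normalise is the default
because it preserves the percentage reading of well-behaved triples
exactly. Residual-DILI thresholds are 0.20 (minor) and 0.40 (major) on the
larger injury coordinate of a clinically recovered sample — chosen so that
the "moderate phenotype" range (≥ ~40%) is a major flag and the "still
noticeable contribution" range (~20–30%) a minor one; both configurable.
Transition labelling uses delta = 0.15 per consecutive-timepoint move,
above the coordinate-recovery error observed on synthetic cohorts (MAE
≈ 0.07), so annotated shifts exceed estimation noise.

## The synthetic-cohort generator

What it emulates: longitudinal samples nested in patients; three latent
poles with per-sample mixture weights w = (w_C, w_H, w_R) on the simplex;
a bile-acid-like block responding to w_C and a second block responding to
w_H (60 features each of 828 by default; 30% of each block shifted down,
glycerophospholipid-like, the rest up); log2 effect magnitudes uniform in
[0.5, 1.5] × effect_size (mean = effect_size, default 1.5); residual log2
noise 0.5; lognormal baselines; two batches with mild multiplicative drift
over injection order; pooled-QC injections every 10 samples (technical
noise 0.05 log2) plus blanks; 5% missingness at random. Liver chemistry is
tied to the mixture (ALT/ULN = 0.5 + 4·w_H + ε, ALP/ULN = 0.5 + 4·w_C + ε,
ε ~ N(0, 0.15); bilirubin rises with both injury weights), calibrated so
pure poles exceed their clinical thresholds with probability ≥ 0.95.

Disease course: patients start at their pole (mixed patients at a
Dirichlet(4, 4, 2) draw) and resolve abruptly at a uniformly drawn visit,
after which w_R ≥ 0.9 — modelling clinical resolution between scheduled
visits. This keeps samples near poles or near the recovered vertex rather
than smeared across the ambiguous mid-simplex, which is also what makes a
discrete per-sample label well defined. The per-sample clinician-style
label is recovered when w_R ≥ 0.75, else the patient's latent type —
emulating expert classification, which sees more than the two enzymes; the
rule-based R-score classifier is computed independently and agrees with
the generating pole on ≥ 95% of pure-pole samples.

What it does not emulate: real m/z–RT structure, adducts/isotopes,
correlated metabolite modules, drug-specific signatures, non-random
(intensity-dependent) missingness, or gradual biochemical recovery.
Passing tests therefore demonstrate that the machinery recovers the
structure it assumes at realistic sizes and noise — not that the original
cohort's biology is reproduced.

## Problem sizes and numerical choices

Tests and the acceptance script simulate at the reference conditions
(60 patients, ~220 samples × 828 features for recovery/accuracy checks;
12 patients × 40 features for drift-correction checks; 24 patients × 120
features for most unit tests) — large enough for stable statistics, small
enough that the whole suite runs in well under a minute of simulation plus
a few seconds of model fitting per cohort. Degenerate inputs are errors,
not silent repairs: constant y, LV counts beyond the effective rank
(detected by covariance exhaustion during deflation, tolerance 1e-12),
ALP = 0 in the R score, empty VIP selections, fold plans with more folds
than patients. Ties in the one-SE rule resolve to the smallest LV count.

## Known limitations

* The deposited study cohort is not bundled; the dataset-integrity checks
  (278 × 828 table; clinical class counts 34/79/54/111) run only when the
  deposit is placed under `data/zenodo/`, and the corresponding acceptance
  test fails until then. All other checks run on synthetic data.
* Between-batch level alignment is not applied (within-batch correction
  only); an optional median-centering step would be needed for strongly
  offset batches.
* The ensemble gives no calibrated probabilities; the ternary coordinate is
  a normalised projection, not a posterior.
* Model serialization stores matrices as JSON lists — fine at these sizes,
  inefficient for very wide models.
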