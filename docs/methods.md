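# Methods

## The problem

Whether a rectal cancer has metastasized to regional lymph nodes (LNM)
changes treatment; preoperative assessment from diffusion MRI of the
*primary tumor* is an attractive non-invasive proxy. Three signal models of
the same multi-b-value acquisition are compared as markers of nodal status:

* **DWI / ADC** — mono-exponential Gaussian diffusion,
  `S_b / S_0 = exp(-b * ADC)`;
* **DKI** — non-Gaussian diffusion,
  `S_b = S_0 * exp(-b * D_app + b^2 * D_app^2 * K_app / 6)`, where `K_app`
  measures the deviation from Gaussianity and `D_app` is the corrected
  diffusivity;
* **three-compartment RSI** —
  `S(b) = S_0 * (f1 * e^(-b*D1) + f2 * e^(-b*D2) + f3 * e^(-b*D3))` with
  fixed diffusivities `D1 < D2 < D3` for the restricted, hindered and
  free-water compartments; the volume fractions `f1, f2, f3` are the
  markers.

The acquisition is an 11-shell protocol, b = 0, 50, 100, 150, 200, 400,
600, 800, 1000, 1500, 2000 s/mm² with per-shell NEX 1,1,1,1,1,2,2,2,4,4,4.
The compartment diffusivities are fixed at 0.5, 1.3 and 3.0 ×10⁻³ mm²/s,
which linearizes the RSI fit and keeps fractions comparable across
patients.

Because no patient data are available, a synthetic generator produces every
input with known ground truth, and all validation is against that ground
truth or against closed-form/independent oracles.

## Fitting

**ADC** is inverted in closed form from exactly the b = 0 and b = 800 s/mm²
shells (`ADC = ln(S_0/S_800)/800`), the pair conventionally used
clinically; a log-linear fit over all shells is available as a non-default
option. Noise can push `S_800` above `S_0`; the estimate is then clipped to
0 and flagged.

**DKI** is a linear least-squares fit of
`ln S = ln S_0 − b·c1 + b²·c2` with `c1 = D_app` and
`c2 = D_app²·K_app/6`, over all 11 shells. If the unconstrained solution
violates `D_app > 0` or `0 ≤ K_app ≤ k_max` (default `k_max = 3`, standard
practice for body DKI), a bounded trust-region refit of the same objective
enforces the constraints. An optional NEX weighting assumes signal-domain
variance ∝ 1/NEX and propagates it to the log domain (weight ∝ S·√NEX);
unweighted is the default since nothing in the study design requires it.

**RSI** normalizes by S(0) and solves non-negative least squares against
the fixed design `[e^(-b·D1), e^(-b·D2), e^(-b·D3)]`. Reported fractions
are the weights renormalized onto the simplex, so `f1+f2+f3 = 1` always
holds downstream; the raw weights are preserved for diagnostics. A
root-mean-square residual above 0.05 (in S(0)-normalized units) flags a
voxel whose signal the compartment basis cannot represent (`poor_fit`).

Per-volume fitting visits every in-mask voxel; failures carry NaN (a
sentinel that cannot be confused with a valid 0) and are excluded from the
fitted-voxel mask and from all ROI aggregates.

A deliberate property of the model family: on a voxel that truly contains a
single compartment the kurtosis model degenerates to mono-exponential and
`K_app = 0`. Fitted `K_app` therefore rises with the restricted fraction
only over the mixed-tissue range (it peaks near f1 ≈ 0.7 and returns to 0
at f1 = 1); tests assert monotonicity on f1 ∈ [0, 0.6], which brackets both
group medians.

## Synthetic data

The generator emulates the study conditions, not anatomy:

* **Screening roster** — 100 consecutive patients by default, with exactly
  5/4/3/6/5 records in the five mutually exclusive exclusion categories
  (non-rectal pathology, inconclusive pathology, >2-week scan-to-biopsy
  interval, incomplete/poor MRI, prior treatment), leaving 77 eligible,
  31 of them LNM-positive.
* **Clinical covariates** — age and maximum diameter normal per group, sex
  Bernoulli, CEA log-normal matched to the reported group medians and
  IQRs (4.08 (1.84, 13.35) vs 2.68 (1.21, 6.02) ng/mL).
* **Compartment fractions** — patient-level triples from a per-group
  Dirichlet law. The concentration vector is calibrated by least-squares
  quantile matching to the reported group quartiles of f1/f2/f3, with the
  median residuals up-weighted ×4: three Dirichlet parameters cannot match
  nine quantiles exactly (reported medians sum to 0.82 and 0.70, while
  simplex-valued marginals constrain the achievable combinations), and the
  medians are the contract the generator's tests enforce (calibrated
  marginal medians land within 0.03 of the targets). Voxels jitter around
  the patient triple with logistic-normal noise (τ = 0.10) renormalized
  onto the simplex, so every voxel satisfies the constraint the RSI fitter
  assumes.
* **Diffusivity parameters** for the imaging-free cohort table — normal
  per group (truncated at 0): ADC 1.09 ± 0.29 vs 1.57 ± 0.62, D_app
  1.04 ± 0.44 vs 1.85 ± 0.07, K_app 0.77 ± 0.27 vs 0.49 ± 0.18 (×10⁻³
  mm²/s for the diffusivities).
* **Lesion geometry** — a random ellipsoid (≥ 50 voxels) on a 16×16×8 grid
  by default, with b=0 signal 1000 (arbitrary units) against a dimmer
  background; a small necrotic core (< 20% of the ROI, elevated free-water
  fraction) is embedded and flagged so aggregation can avoid it, as readers
  avoid obviously necrotic regions.
* **Noise** — Rician: independent complex Gaussian noise per excitation
  with per-channel σ = S0_ref/SNR, magnitudes averaged over NEX, mirroring
  scanner magnitude averaging. Default SNR at b=0 is 50, a typical clinical
  DWI figure; nothing in the study reports the true SNR, so it is
  configurable.
* **Second observer** — a seeded morphological perturbation toggling at
  most 10% of the first observer's boundary voxels. This produces agreement
  in the "excellent" regime (ICC > 0.75) without modelling human raters.

What the generator does **not** emulate: anatomically realistic rectal
geometry, perfusion (no IVIM compartment), susceptibility/eddy-current
distortion, T2 effects, partial volume with non-tumor tissue classes, or
between-scanner variability. Passing tests therefore demonstrate that the
pipeline recovers what this generative model encodes — not that the
clinical effect sizes would replicate on real patients.

## ROI stage

Parameter maps live on the acquisition grid the ROI was drawn on, so ROI
transfer is the identity. The per-patient summary is the mean over
(ROI ∖ necrosis ∖ fit failures); median is available as an option.
Observer agreement is ICC(2,1) — two-way random effects, absolute
agreement, single measurement — computed from the two-way ANOVA mean
squares with negative variance components truncated at 0. The
absolute-agreement single-measure form is the conservative choice when the
two raters are a sample from a population of possible radiologists; the
choice matters near the 0.75 threshold. Both observers' readings are then
averaged for the cohort table.

## Statistics

* **Group comparisons** — Shapiro–Wilk per group at α = 0.05 gates between
  the independent-samples t-test (both groups normal) and the two-sided
  Mann–Whitney U (exact when sample sizes permit and ties allow, otherwise
  tie-corrected normal approximation). Categorical variables use the
  chi-square test without continuity correction, falling back to Fisher's
  exact test when any expected count is below 5. The test actually used is
  recorded per variable.
* **Logistic regression** — continuous predictors are standardized by the
  whole-sample SD so odds ratios are per 1 SD; binary predictors are
  encoded 0/1 unscaled. Variables with univariate p < 0.1 enter one joint
  multivariate model, with no stepwise elimination. Complete separation is
  detected (fit failure or |coef| > 15 on the standardized scale) and
  flagged with no OR reported; collinear designs are rejected by a
  condition-number guard (κ > 10⁸).
* **ROC** — empirical AUC by pairwise counting with half credit for ties,
  which is exactly the Mann–Whitney U statistic divided by n₁n₂. The CI is
  the DeLong normal interval. The cutoff maximizes Youden's J with ties
  broken toward the lower cutoff; marker orientation is chosen per marker
  so AUC ≥ 0.5 and recorded. Composite diffusion-model scores (DWI = ADC;
  RSI = f1 + f3; DKI = D_app + K_app) are the in-sample predicted
  probabilities of a logistic model over the listed variables, and their
  cutoffs are reported on the probability scale and marked as such. Under
  complete separation the composite score falls back to a lightly
  ridge-penalized fit (λ = 10⁻³) — the penalty pins the coefficient scale
  but cannot change the ranking, hence not the ROC.
* **DeLong test** — structural components per case and control, paired
  variance `var_A + var_B − 2·cov`, two-sided normal p. Degenerate paired
  variance (identical markers) is flagged.
* **No multiplicity correction** is applied, matching the single-cohort
  reporting style the pipeline reproduces.

## Problem sizes and numerical choices

Default experiment sizes are chosen so the whole suite exercises every
claim at desk scale: 30 phantoms on a 16×16×8 grid for the agreement study,
2000 patients for distribution-level checks of the cohort generator, 100
replicates of the 31/46 cohort for the f2 null behavior, 1000 replicates of
n = 50-per-group nulls for the test-gate calibration, and a 10⁴-replicate
stratified bootstrap (n = 80) as the independent check of the DeLong paired
variance. Seeds are explicit everywhere; per-patient streams are spawned
from a single root generator, so any phantom is bit-reproducible from
(group, seed).

Tolerances: noiseless inversion is exact to 10⁻⁶ relative (diffusivities,
kurtosis) and 10⁻⁸ absolute (fractions); the NNLS solution is verified
against a 0.01-step exhaustive simplex search both coordinate-wise (within
grid resolution; the objective is nearly flat along one simplex direction,
so the grid argmin may sit a step off) and by squared-error dominance;
logistic coefficients are verified against an independently coded BFGS
optimizer of the same likelihood to 10⁻⁶.

## Known limitations

* The eligibility filter operates on labels the generator itself assigns;
  it validates bookkeeping, not clinical triage.
* ROC/AUC of the composite models is in-sample, as in the study design this
  mirrors; no cross-validation is attempted, so composite AUCs are
  optimistic.
* The D_app distribution of the LNM-negative group (1.85 ± 0.07) is taken
  at face value from the reported table; its unusually small SD makes
  D_app a near-perfect synthetic discriminator, stronger than a real cohort
  would show.
* ICC values on the default synthetic cohort are higher (~0.99) than a
  human inter-observer study would produce, because the only disagreement
  source is the bounded ROI perturbation.
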