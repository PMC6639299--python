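# Methods

This note documents the models and procedures implemented in
`npcradiomics`, the defaults they use, and the design choices made where
the analysis admitted more than one reasonable construction.

## Feature extraction

### Gray-level quantization

All texture matrices operate on intensities quantized to `n_levels = 32`
equal-width bins over the ROI min–max range, recomputed independently for
each wavelet sub-band. A constant ROI maps every voxel to level 1. The
min–max policy makes the texture features invariant to affine intensity
rescaling, which is the desirable behaviour for arbitrary-unit MRI; its
flip side is that histogram entropy is insensitive to pure amplitude
scaling (see the phantom design below).

### Roster composition

The 208-name roster is fixed as 10 HIST + 22 GLCM + 9 GLRLM on the native
image, the same 41 recomputed per wavelet sub-band (164), and 3 FRAC. The
GLCM roster is Haralick's fourteen — angular second moment, contrast,
correlation, sum-of-squares variance, inverse difference moment, sum
average, sum variance, sum entropy, entropy, difference variance,
difference entropy, information measures of correlation I and II, maximal
correlation coefficient — plus eight standard additions: autocorrelation,
cluster shade, cluster prominence, dissimilarity, homogeneity2, maximum
probability, inverse difference normalized, and inverse difference moment
normalized. Conventions: 0·log 0 ≡ 0 throughout; correlation and the
information measures fall back to 0 for degenerate marginals; the maximal
correlation coefficient is the square root of the second-largest
eigenvalue of Haralick's Q matrix restricted to occupied gray levels, 0
when fewer than two levels are occupied. `sum_variance` is dispersion of
p_{x+y} about its own mean (the sum average), not about the sum entropy
as in Haralick's original typo-laden formula.

Texture matrices pool the four in-plane unit-distance directions (0°,
45°, 90°, 135°) across all slices, both orderings counted, and are
normalized to probability form. Through-plane offsets are excluded
because transversal MRI slice spacing (3 mm here vs 1 mm in-plane) makes
through-plane co-occurrence incommensurate with in-plane co-occurrence.
Run-length matrices use the same four directions; a voxel outside the
mask terminates a run.

### Wavelet sub-bands

A single-level 2-D discrete wavelet transform (Coiflet-1, periodized
boundary) is applied slice-wise to the full image. Two-letter sub-band
names (LL/LH/HL/HH) imply a 2-D transform; the periodized orthonormal
filter bank conserves per-slice energy exactly for even slice dimensions,
which the test suite asserts at 1e-6 relative tolerance. The ROI mask is
downsampled to the sub-band grid by the any-parent rule: a sub-band voxel
is foreground iff any voxel in its 2×2 parent block is foreground. A
consequence of the dyadic grid is that features are exactly invariant to
even in-plane translations only; odd shifts change the coefficient
alignment (the native-image families remain invariant to any whole-voxel
shift).

### Fractal features

* `box_counting_dimension`: 3-D box counting of the binary mask over
  dyadic scales within the ROI bounding box; least-squares slope of
  log N(s) against log(1/s). Requires at least two scales (mask extent
  ≥ 4 voxels).
* `intensity_fractal_dimension`: Sarkar–Chaudhuri differential box
  counting on the quantized intensity surface, slice-wise within the
  bounding box, box height h = s·G/M (G = 32 gray levels, M = max
  in-plane extent). For ROIs too small for two dyadic scales the scale
  set degrades to {2,3} and then {1,2}; below 4 voxels extent the feature
  raises an error.
* `lacunarity`: gliding-box statistic var/mean² + 1 of the box mass (sum
  of intensities) over 3×3×3 boxes fully inside the mask (falling back to
  any-coverage boxes for very thin ROIs). A constant field has
  lacunarity exactly 1.

## Synthetic cohorts

### Phantom model

Each patient's volume is a 16×32×32 grid (3×1×1 mm spacing) containing an
ellipsoidal tumor with per-axis radii drawn uniformly (default ≈ 5–7.5
voxels, auto-scaled to the grid), jittered center, and intensity

    I(x) = 100 + 100·exp(−16·d²(x)) + a·G_σ(x),

where d is the normalized ellipsoidal distance, a the noise amplitude and
G_σ a unit-variance Gaussian random field with correlation length σ
(white noise convolved with an isotropic Gaussian kernel and
re-standardized). The sharp bright core pins the ROI intensity range at
~100 units while the bulk of the tumor sits near the baseline; the noise
amplitude then controls how much of that fixed range the bulk histogram
occupies. This is what makes histogram entropy and GLCM contrast respond
*monotonically* to the amplitude under min–max quantization (a flat or
broadly graded base profile would not: the quantizer is scale-invariant,
so amplitude-dominated ranges saturate the features). The test suite
verifies Spearman > 0.9 for both features across a paired amplitude sweep
at fixed correlation length.

Two latent phenotypes set the texture defaults: smooth (σ = 3.0,
a = 6) and heterogeneous (σ = 0.7, a = 25); the heterogeneous phenotype
has strictly higher ROI entropy at matched geometry. Each patient also
receives a smaller "lymph-node" lesion in an image corner whose texture is
drawn from a fixed, phenotype-independent model — node-region features
therefore carry no survival signal, giving the pipeline a built-in
negative control. A second-rater mask is produced for the first 19
patients (the dual-contoured subset) by random binary dilation or erosion
of up to `rater2_perturbation` voxels (default 1).

### Clinical covariates and survival

T and N stage are drawn from phenotype-conditional categorical
distributions (heterogeneous skews higher), overall stage is derived from
(T, N), age ~ N(48.8, 12.7²) truncated to 18–85, sex male with
probability 0.746, and the diagnosis date is emulated by generation
order, so the chronological train/validation split is deterministic.

Event times are exponential with hazard λ_i = λ₀·exp(Σ β_f·z_{if}),
λ₀ = 0.01/month, where z are cohort-standardized values of the planted
true features. The default planted pair is `LL_HIST.kurtosis` (+1) and
`LH_GLCM.correlation` (−1): both reproduce well under the rater-2
perturbation (ICC ≈ 0.97 in phantom cohorts), and they are nearly
uncorrelated with each other. The latter matters: a strongly correlated
pair with opposite signs has nearly zero *marginal* association with the
hazard, which the L1 path cannot pick up — a real failure mode of LASSO,
not of the generator. Per-endpoint signal scales are DFS 1.0, OS 0.8,
DMFS 0.3 and LRFS 0.0, so a correctly behaving pipeline finds DFS/OS
signatures, a marginal DMFS one, and reports the LRFS radiomics model as
unavailable. Censoring is an independent exponential whose rate is solved
numerically (Brent) so that the expected censored fraction equals
`censoring_rate` (default 0.3) given the realized hazards.

What the phantoms do **not** emulate: MRI physics (bias fields, coil
profiles, partial-volume mixing), inter-scanner intensity shifts,
non-proportional hazards, informative censoring, and anatomically
realistic lesion shapes. Passing tests therefore demonstrate the
correctness and statistical calibration of the pipeline machinery, not
clinical performance on real images.

## Selection

ICC(2,1) follows the two-way random-effects, absolute-agreement,
single-measurement form, (MS_R − MS_E)/(MS_R + (k−1)MS_E +
(k/n)(MS_C − MS_E)), computed from the ANOVA mean squares on the
dual-contoured training patients; all-identical ratings define ICC = 1.
The screen keeps features with ICC strictly greater than the threshold
(default 0.8). Redundancy elimination replicates the caret
`findCorrelation` greedy rule on the Pearson correlation matrix of the
survivors (training cohort only): repeatedly take the remaining pair with
the largest |r| above the cutoff (default 0.5) and drop the member with
the larger mean absolute correlation to everything else; exact ties drop
the lower index (the reference routine's tie behaviour is
version-dependent, so the tie-break is pinned here). Pearson rather than
rank correlation is used because it is the referenced routine's default.

## Clustering

NMF uses multiplicative Frobenius updates with ε-guarded denominators,
20 random restarts, 500 max iterations and a 1e-6 relative-improvement
stopping rule; the objective is non-increasing by construction and the
implementation records the per-iteration error so tests can assert it.
Input is the per-feature min–max-scaled matrix (features such as skewness
are negative; min–max preserves ordering and guarantees nonnegativity).
Patients are hard-assigned to the basis column with the largest loading
after fixing the usual W/H scale indeterminacy by row-normalizing H.
Cluster labels are arbitrary; group sizes are reported as unordered sets.
Stage association uses Pearson's χ² without continuity correction;
survival comparisons use the product-limit estimator and the two-sample
log-rank test (events before censoring at tied times).

## Survival modelling

The L1-penalized Cox path is solved by the glmnet-style coordinate
descent in scikit-survival (Breslow tie handling, tolerance 1e-9);
covariates are standardized to training mean 0 / SD 1 before entering the
penalty, and those standardization parameters are frozen into the
signature, so validation data never contribute scale information.
Cross-validated deviance follows Verweij & Van Houwelingen: the
contribution of fold k at penalty λ is −2[pl(all) − pl(without k)]
evaluated at the coefficients fitted without fold k. `lambda.1se` is the
largest λ whose mean CV deviance is within one standard error (over
folds) of the minimum. LOOCV is the default (and is cheap here because
the deviance is evaluated vectorized across the whole path); k-fold is
available and used for the n=300 simulation studies where LOOCV would
dominate runtime. A separate 10-fold cross-validation report
(out-of-sample C per fold, stratified by event status) is produced for
stability assessment and plays no role in choosing λ.

The risk score is the penalized linear predictor on standardized
covariates — no unpenalized refit is performed on the selected support
(the alternative is noted; it changes the score scale, not the ranking
logic). Risk-score thresholds are therefore comparable only within a
fitted signature, not to scores from other implementations of the same
design. Harrell's C counts comparable pairs under the usual censoring
rules with ties in score credited 0.5; its 95% CI is a percentile
bootstrap over patients (2000 resamples by default, seeded; smaller
counts are used inside the test suite for speed). Clinical covariates
enter as ordinal integers (T 1–4, N 0–3), age in years, sex as a binary
indicator, and are penalized on the same footing as radiomics features
(nothing in the design suggested differential penalties; exempting the
clinical block is a one-line change via the solver's penalty factors).
When `lambda.1se` shrinks every coefficient to zero the model cell is
reported as unavailable rather than backing off to a denser λ — an empty
sparse model is a result, not an error; the same policy makes the
pipeline report stratification as unavailable when no endpoint signature
exists.

Stratification thresholds are the training-median risk score with a
strict `score > threshold → high risk` rule; subgroup analyses split the
validation cohort by overall stage (I/II vs III/IV), sex, and the age
median. The nomogram points table maps the covariate with the widest
linear-predictor span over its observed training range to 0–100 points
and every other covariate proportionally; total points recover the risk
score through a recorded affine map.

## Pipeline and problem sizes

`run_full_analysis` executes generate → extract → cluster (full cohort)
→ split → primary selection (training) → models → validation scoring →
stratification, writing every intermediate artifact as CSV/JSON plus
convenience plots (heatmap, KM curves); the numeric files are the tested
surface, and identical configurations reproduce them byte-for-byte.

Simulation sizes used by the test and acceptance suites were chosen to
keep each statistical check well-powered while the whole suite stays
fast: 1000 random 6×6 images for the texture-matrix oracles, n = 500 for
null concordance and unpenalized-coefficient recovery (100 seeds),
n = 100 with LOOCV for the null-model-selection rate (10 seeds), n = 300
split 200/103-style for planted-signal recovery (10 seeds, 10-fold CV for
λ), and a 60-patient image-level cohort (40/20 split, 19 dual-contoured)
for the end-to-end run. Statistical studies of the survival machinery use
directly simulated Gaussian feature matrices with roster column names;
rendering image phantoms there would exercise no additional code path at
two orders of magnitude more cost, while image-level behaviour is covered
by the end-to-end cohort.

## Known limitations

* The roster is a documented reconstruction constrained by the printed
  family counts and named features; other 31-texture decompositions
  exist.
* No intensity normalization is applied before extraction; required
  before multi-scanner use.
* Lymph-node masks are pooled per patient (all foreground voxels form one
  ROI); per-node extraction is not implemented.
* Wavelet features are exactly translation-invariant only to even
  in-plane shifts (dyadic grid).
* The bootstrap CI for C is percentile-based; it can be narrow at very
  small validation sizes.
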