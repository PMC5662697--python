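# Methods

This note records the models, conventions and numerical choices behind
`mpradiomics`, and what the synthetic experiments do and do not demonstrate.

## Image standardization

Volumes are resampled to isotropic grids of 1, 2 and 3 mm.  Output size is
`floor(extent / voxel_size)` per axis with the origin preserved, so the
physical extent is kept to within one voxel; intensities are interpolated
linearly and label maps with nearest-neighbour (labels must stay
categorical).  Resampling uses `scipy.ndimage.map_coordinates` on
voxel-center coordinates; a grid smaller than 2 voxels on any axis is an
error.

Quantization to L ∈ {32, 64, 128, 256} levels is computed **per extraction
subregion** from that subregion's own intensity sample (not per volume):
texture matrices are region-local and region-wise quantization maximizes
gray-level utilization.  Three schemes are implemented, all monotone, all
with right-closed bins:

* **uniform** — L equal-width bins on [min, max];
* **equal-probability** — bin edges at the empirical k/L quantiles, giving
  level histograms that are flat up to ties;
* **Lloyd-Max** — the MSE-optimal scalar quantizer, iterated from the
  uniform boundaries (representatives = conditional cell means, boundaries =
  midpoints of adjacent representatives) until the relative MSE decrease is
  below 1e−7 or 500 iterations; deterministic, and never worse than the
  uniform quantizer it starts from.

A constant sample maps everything to level 1 with a logged warning.  Because
all three schemes are range- or quantile-based, adding a constant to the
intensities leaves every quantized level — and hence every high-order
feature — unchanged.

## Feature catalog

The catalog (`catalog.json`, versioned) fixes 12 first-order titles and 52
high-order titles: GLCM 22, GLRLM 13, GLSZM 12, NGTDM 5, drawn from the
classic radiomics feature set so that the per-patient counts come out to
864 first-order + 44 928 high-order = 45 792 measures, and so that the
signature-relevant titles (GLCM IDMN and IMC2, GLRLM HGRE, GLSZM GLN) are
present.  First-order statistics are computed on raw, unquantized
intensities; only entropy and uniformity discretize, on a fixed 64-bin
histogram.  Kurtosis is non-excess (normal ≈ 3); zero-variance samples
report 0 for the dispersion and shape moments with a warning.

Texture conventions:

* **Directions** — the 13 unique 3D offsets at Chebyshev distance 1.
  Co-occurrences and runs are *pooled* across directions into one matrix
  before statistics are computed (per-direction averaging is the noted
  alternative); pooling is more robust for small subregions and makes the
  features exactly invariant under axis-aligned 90° rotations.
* **GLCM** — distance 1, symmetric (both pair orientations counted),
  normalized to sum 1; pairs leaving the mask are ignored.  IDMN/IDN
  normalize the level difference by L; IMC2 is clamped to 0 when rounding
  makes the exponent argument slightly negative; correlation of a
  single-occupied-level matrix is defined as 1.
* **GLRLM** — maximal collinear same-level runs, counted per direction via
  a vectorized chain-propagation scheme and verified against a brute-force
  scanner.
* **GLSZM** — zones are 26-connected components of equal level
  (`skimage.measure.label` on the quantized array).
* **NGTDM** — 26-neighbourhood mean differences; voxels with at least one
  in-mask neighbour participate (partial neighbourhoods at the border are
  averaged over the neighbours present).  Coarseness of a perfectly
  homogeneous region is capped at 1e6; busyness and strength return 0 when
  their denominators vanish.

Measures from empty or sub-minimal subregions are missing values; only an
empty whole tumor aborts extraction.  Downstream, columns missing in more
than 20% of patients are dropped and the remainder median-imputed.

## Reproducibility screening

OCCC uses the 1/n (biased) variance convention, matching Lin's original
estimator, and reduces exactly to Lin's CCC at J = 2.  It is computed on
the training cohort only, to keep validation untouched.  The battery per
high-order feature varies one parameter with the others fixed: 12 voxel-size
tests (3 measures), 12 quantization tests (3) and 9 gray-level tests (4) =
33.  Selection is deliberately literal: first-order OCCC **≥** 0.85;
high-order count of OCCCs **strictly >** 0.85 must reach 10.  Undefined
OCCCs (all columns constant) never count.  A feature whose setting grid did
not survive missing-value cleaning cannot be assessed and is excluded.

## Prognostic screening

Harrell's C-index (scikit-survival implementation; ties in the predictor
count 1/2, tied event times yield no usable pair) with higher value =
higher risk.  Measures with C ≥ 0.60 or C ≤ 0.40 are kept.  Redundancy
pruning is greedy over Spearman |ρ| ≥ 0.90 pairs in descending |ρ|;
"more prognostic" means larger |C − 0.5| so negatively associated features
compete fairly; ties keep the earlier column.  Greedy (not exhaustive)
pruning is order-dependent in principle; the descending-|ρ| order fixes the
result deterministically.

## Signature model

Features are z-standardized on training statistics; the standardization
constants travel with the model, so the risk score of any cohort is computed
on the training scale and rescaling an input column is absorbed exactly.
The L1 path is fitted with `CoxnetSurvivalAnalysis` (glmnet-style,
l1_ratio = 1, tol 1e−9); λ is chosen by 10-fold cross-validated
Verweij–van Houwelingen partial-likelihood deviance,
−2·[pl_full(β₋k) − pl_−k(β₋k)] summed over folds, minimum criterion.  Fold
assignment is seeded and stratified by event status so every fold holds
events.  The package's own Breslow partial likelihood is used for the
deviance; with continuous (tie-free) phantom times Breslow and Efron
coincide, which is how the λ→0 fit can be checked against an independent
Newton-type Cox fit to 1e−4.

The optimal cutpoint replaces the X-tile GUI with its core computation: a
deterministic scan of all unique training scores, each group required to
hold ≥ 10% of patients, maximizing the standard (ρ = 0) log-rank chi-square;
ties go to the smallest cutpoint.  Group comparison at validation uses the
G-rho family with weights Ŝ(t−)^ρ from the pooled left-continuous
Kaplan-Meier curve; ρ = 0 reduces to the standard log-rank (verified against
lifelines) and ρ = 1 (the default) upweights early differences.  The
C-index CI uses a normal approximation with the binomial-style standard
error over usable pairs — adequate for ranking models at these cohort
sizes, but approximate (it ignores pair correlation).  The hazard ratio is
a univariate Cox fit on the binary risk-group indicator.

Fixed-setting comparator signatures repeat the chain per setting on its
1 536 columns, skipping the reproducibility screen (nothing varies within
one setting); settings where screening or the LASSO keep nothing are marked
degenerate.  A degenerate signature scores every patient 0 and its C-index
is 0.5 by construction.

## Phantom generator

Each phantom is a nested-ellipsoid tumor (necrosis ⊂ enhancing ⊂
non-enhancing ⊂ edema envelope; default radii 5/9/12/16 mm, ±8% per-patient
jitter) in a 48³ volume at 1 mm spacing.  Modality intensities are
Gaussian random fields: white noise smoothed with a Gaussian of
σ = correlation length / spacing and renormalized to unit variance, scaled
by a per-compartment (mean, sd, correlation length) table chosen for
qualitative MR realism (necrosis dark on T1/T1C, enhancing rim bright on
T1C, edema bright on FLAIR/T2).  Correlation length 0 degenerates to
i.i.d. voxel noise.

The hazard-linked generative parameter z ~ N(0, 1), drawn per patient,
multiplies the within-tumor noise sd by exp(0.35·z), so dispersion-sensitive
features carry the survival signal.  Event times are exponential with
h(t|z) = h₀·exp(β·z̃), z̃ the standardized z, and h₀ = ln 2 / 427 days —
a median survival typical of GBM training cohorts.  Censoring is
independent and uniform on (0, T_max), with T_max calibrated by root-finding
so the expected censoring fraction matches the requested rate; rate 0 means
every event is observed.  All randomness derives from
`default_rng([seed, patient_index])`, so cohorts are bit-reproducible and
the per-patient z is recorded for oracle use.

What the phantoms do *not* emulate: anatomy, MR physics, bias fields,
registration error, scanner-to-scanner intensity shifts, or inter-feature
correlation structure of real tumors.  Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline — not clinical
performance on real cohorts.

`synthetic_feature_table` emulates the *post-extraction* state directly
(noisy copies of z plus independent noise columns, survival from the same
hazard model) so the statistical stages can be exercised at cohort sizes
(n = 200; 60/32 splits) where full-grid image extraction would be wasteful.
The image route is exercised end to end at smaller n by the pipeline smoke
test and the feature-count checks.

## Problem sizes and defaults

The pipeline's default configuration simulates 12 training and 8 validation
phantoms at 28–48³ voxels and uses 5-fold CV (keeping n ≥ 2·folds at these
cohort sizes); the signature-fitting API defaults to the method's 10-fold
CV.  The acceptance script runs one default-size patient plus a 3-patient
cohort through the full 36-setting grid, 5 hazard-linked seeds (n = 200 for
active-set recovery, 60/32 for validation concordance) and 20 null seeds.

## Known limitations

* The exact feature-title membership of published GBM catalogs varies; the
  catalog here is fixed data, chosen to satisfy the count arithmetic and
  include the named signature features.
* OCCC batteries require the full 36-setting grid; partially extracted
  tables are screened only for the features whose grid is complete.
* The C-index CI and the cutpoint scan are the simple, deterministic
  variants; no bootstrap or maximally-selected-statistic p-value correction
  is provided.
* 2D slice-wise texture matrices are not implemented; all matrices are 3D.
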