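# Methods

This note documents the statistical procedures the package implements, the
synthetic data model used to validate them, the defaults and the numerical
choices, and what a green test suite does and does not establish.

## 1. Data model

All analyses consume a `CohortStack`: an `n_subjects x n_voxels` matrix of
modulated, smoothed grey-matter (GM) partial-volume density restricted to
a binary analysis mask, with rows aligned to a subject table (id, group,
age, sex, scan date, clinical scores). Volumes must share one grid and
affine; the package never resamples. Statistic volumes carry NaN outside
the mask. Cluster peaks are reported in template (MNI) mm via the NIfTI
affine, with 0-based voxel indices internally; peak ties break to the
smallest linear (C-order) index so outputs are deterministic.

The analysis mask is a required input: published VBM studies rarely state
whether inference ran over the whole template or a study-specific GM mask,
so the package takes no position and applies whatever mask it is given.

## 2. Group comparison (VBM)

Per voxel, OLS of GM density on `[1, group, age, sex]` (group 0 = control,
1 = patient; sex 0 = F, 1 = M). The group-contrast t statistic has
df = n − rank(X). Voxels with zero residual variance get t = 0 and are
flagged. Rank-deficient designs (e.g. a single-sex sample with sex
requested) are hard errors naming the collinear columns.

**Cluster-extent FWE.** The map is thresholded at a predefined
cluster-forming height (default t > 4, one-sided in the patient < control
direction; two-sided available). The null distribution of the maximal
suprathreshold cluster size is built by permuting group labels while
keeping the covariate rows fixed — adequate under the null of no group
effect with exchangeable errors; Freedman–Lane residual permutation is not
implemented. Corrected p for an observed cluster of size s is
`(1 + #{null >= s}) / (n_perm + 1)`; when fewer distinct relabellings than
`n_perm` exist the test enumerates all of them and reports the exact
proportion (observed labelling included). Default `n_perm = 5000`
(corrected-p resolution 2e-4); simulation studies in the test suite use
999 (resolution 1e-3), which matters for calibration: at small n_perm the
achievable p-grid is coarse and rejection at alpha = 0.05 effectively
requires a stricter empirical proportion (11/256 vs 49/999), measurably
deflating the realized family-wise error.

The permutation loop is implemented by Frisch–Waugh partialling: GM and
each permuted group column are residualised against the fixed covariates
once, after which every permutation's t-map is a single matrix product.
This is algebraically identical to refitting the full GLM and is verified
in the tests against brute-force enumeration. Component labelling inside
the loop crops to the bounding box of suprathreshold voxels (cropping can
neither merge nor split components).

**Uncorrected validation map.** A liberal two-sample map (default
|t| > 2.8, p < 0.005, two-tailed, equal variances; covariates optional) is
provided as the conventional sensitivity check, always flagged
"uncorrected".

**Severity subgrouping.** Patients are split at a clinical motor score
threshold (default MDS-UPDRS III = 21; the threshold value itself goes to
the upper, "moderate", group), with missing-score exclusions logged.

## 3. Group-interaction regression

The central model, fitted voxel-wise or on ROI summaries:

    Y = a + b*X + c*G + d*G*X + e,  df = n - 4.

Before fitting, Y and X are z-scored within each group (sample SD,
ddof = 1). Consequences used throughout the package and its tests:

* the within-group slope equals that group's Pearson correlation
  (b = r_control, b + d = r_pd), so d is exactly the correlation
  difference — this holds algebraically, not just asymptotically;
* t_d is invariant to affine rescaling of the raw data within either
  group.

The per-voxel fit is vectorised through the 4x4 normal equations assembled
from column-sum sufficient statistics; singular systems (zero within-group
variance) are flagged, excluded from inference, and reported with t_d = 0,
p = NaN.

**Known conservativeness.** Because both variables are standardised by
their sample SDs, the fitted slope is the sample correlation, whose true
sampling variance is (1 − r²)²/n — smaller than the model-based
(1 − r²)/n the OLS t statistic assumes. The d-test is therefore exact when
the common correlation is near zero (measured size 0.050 over 1000 null
simulations at n = 172/group) but conservative when both groups share a
strong correlation (measured size 0.010 at common r = 0.6). A Fisher
z-transform of the per-group correlations would equalise the variance, but
the model is deliberately fit exactly as the published procedure states.

**Covariance mode.** Y = seed-region mean GM, X = local GM. Within-group
display maps use plain Pearson r (equal to the reduced-model slope under
z-scoring) with a fixed display threshold p < 6e-8 by default — the value
the source analysis applied — with Benjamini-Hochberg FDR available as the
principled alternative. The larger group can be repeatedly subsampled
without replacement to the smaller group's size (default 100 repeats) and
the r maps averaged, removing the sample-size asymmetry. Whether to
residualise on age/sex first is the caller's choice; the default fits the
model exactly as written.

**Ageing mode.** X = age, Y = local GM. Two parallel fits reconcile
normalised inference with natural-unit reporting:

* the z-scored interaction fit supplies t_d and FDR-corrected
  significance, optionally inside a small-volume mask;
* the reduced per-group natural-unit fit supplies slopes in
  GM-density/year, differenced as (control − pd) so positive values mean
  extra decline in patients, thresholded at |Δ| ≥ 0.002/year with
  components < 20 voxels (26-connectivity) removed, signs preserved.

Cross-sectional age slopes are predicted rates of age-related change, not
longitudinal atrophy rates; the package reports them as such.

## 4. Clinical association

Scores are resolved per subject and instrument to the visit nearest the
scan date; equidistant ties go to the *earlier* visit (pre-scan data
cannot be contaminated by post-scan progression), and a missing value at
the chosen visit is filled from the most recent earlier non-missing visit
only — never from the future. Every resolution records its provenance
(`nearest_visit`, `filled_most_recent`, `missing`). Association uses
Pearson r with a parametric two-sided p, and an age/sex-adjusted OLS of
the ROI mean on score + age + sex (complete cases; collinearity is a hard
error). Pooling patients and controls versus patients-only is an explicit
parameter; the default analyses patients only.

## 5. Synthetic cohorts

The generator emulates the statistical structure of smoothed, modulated GM
maps at desk scale; per-subject volumes are

    baseline
    - atrophy * baseline * [pd] * 1_atrophy_region
    + slope_group * (age - age_ref) * 1_age_region
    + A * z_i * 1_seed  +  A * (lam_g * z_i + sqrt(1-lam_g^2) * w_i) * 1_network
    + N(0, noise_sd) iid per voxel,

then Gaussian-smoothed and clipped at 0. Defaults and why:

| parameter | default | rationale |
|---|---|---|
| grid / voxel | 32³ at 2 mm | minute-scale tests; regions stay distinct after smoothing |
| smoothing sigma | 3 mm | the standard VBM kernel the emulated maps carry |
| baseline GM | 0.5 | mid-range partial-volume density |
| noise_sd (pre-smoothing) | 0.35 | gives ~0.03 post-smoothing across-subject SD, the order seen in smoothed modulated GM |
| n_control / n_pd | 50 / 100 | desk-scale 1:2 case-control imbalance |
| ages | uniform(45, 80) | matches the emulated cohort's mean ± SD |
| atrophy | 8 % of baseline | focal patient deficit, amygdala-like sphere (r = 4 vox) |
| age slopes | −0.001234 / −0.004434 /yr | the published control/patient rates for the right hippocampus |
| covariance loading | 0.6 control / 0.0 pd | strong network in controls, absent in patients |
| clinical correlations | e.g. SCOPA-AUT −0.3, HVLT +0.3 | desk-scale recoverable versions of the reported associations |

**Covariance construction.** Seed-region GM carries a latent standard
normal factor z_i at amplitude A (default 0.02 GM-units); network-region
GM carries `lam * z_i + sqrt(1-lam^2) * w_i` at the same amplitude. The
planted *signal* correlation between seed and network is therefore exactly
the loading `lam` — chosen over the alternative factor-weight reading
(corr = lam²) because it makes d read directly as a correlation
difference, the quantity the interaction test targets.

**Smoothing order and attenuation.** Effects are added before smoothing,
mirroring the segment → modulate → smooth order of real pipelines. A
consequence used by the validation suite: region-mean effects are
attenuated by the mean of the smoothed region indicator (≈ 0.49 for the
default spheres), and measured region means carry correlated voxel noise
(≈ 0.01 SD per region mean). Recovery tests therefore compare estimates
against the *analytic post-smoothing expectation* computable from the
truth record, not against the raw planted parameter — and the spatial
recovery of the thresholded slope-difference map is scored against the
analytically expected suprathreshold region (the planted difference
exceeds the 0.002/yr cutoff only on an eroded core of the sphere).
Smoothing uses wrap-around boundaries so the image sum is conserved
exactly, which keeps the noiseless expectations closed-form.

**Clinical scores** are linear in the seed *signal* with a requested
marginal correlation (score = mean + sd(r z_seed + sqrt(1-r²) eps) + age
term); the correlation against *measured* seed GM is attenuated by the
region-mean noise (≈ −0.26 observed for a planted −0.3 at n = 300, within
the validation tolerance). Visit tables plant ~8 % missingness at the
nearest visit so the backward-fill path is exercised.

**What the generator does not emulate:** registration error, scanner/site
effects, anatomically realistic templates, lesions, non-Gaussian noise,
spatially varying baseline. A green suite establishes correctness and
calibration of the estimators on this stated world, not performance on
real MRI.

## 6. Pipeline and reproducibility

One YAML-serialisable config drives data generation/loading and all four
analysis stages. A single master seed is expanded per stage via numpy's
`SeedSequence` (all derived seeds < 2³¹ and logged in the report). Outputs
are uncompressed `.nii`, CSV and sorted-key JSON with no timestamps, so a
fixed-seed run is byte-identical when repeated — asserted by the test
suite. Any stage failure aborts with the stage name attached.

## 7. Known limitations

* Permutation FWE supports the group contrast only; covariates are held
  fixed under relabelling (no Freedman–Lane).
* TFCE and variance smoothing are out of scope.
* The interaction d-test inherits the conservativeness described in §3
  when both groups share a strong correlation.
* The balanced-subsample average map has no closed-form p-value; it is a
  display/stability device, with inference carried by the interaction
  test.
* Cluster-extent inference at small n_perm is conservative by p-grid
  coarseness; use n_perm ≥ 1000 for calibrated alpha = 0.05 decisions.
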