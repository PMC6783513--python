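# Methods

`rsmvpa` implements a complete resting-state fMRI case-control analysis —
connectivity feature extraction, multivariate pattern classification, and
mass-univariate group statistics — together with a synthetic-cohort
generator that provides ground truth for every stage. This note documents
the models, the defaults and why they were chosen, the numerical decisions,
and what the synthetic validation does and does not establish.

## Synthetic cohorts

Each subject is a 4D grid (default 24³ voxels at 3 mm, 240 volumes at
TR = 2.5 s, matching a common 1.5 T protocol) organised into disjoint
cuboid regions inside a gray-matter mask. Region *r* carries a latent AR(1)
series u_r(t) with unit marginal variance and autocorrelation φ (default
0.4, in the range of band-limited BOLD); voxel series are
u_r(t) + ε with iid noise of sd σ (default 1), giving within-region voxel
correlations of 1/(1+σ²) = 0.5 and ≈0 between regions.

The group effect is a set of extra latents v_p, one per (effect-region,
partner-region) pair: in patients the effect region receives Σ_p c·v_p and
partner p receives c·v_p, so the effect region — and only it — is coupled
to several other regions at once and acquires a strictly higher expected
voxel-wise connectivity strength. A single latent shared by all coupled
regions would make effect and partner regions statistically symmetric and
the discriminative map could not single out the effect region; the
per-pair construction is what makes the recovery analyses well-posed. The
coupling amplitude c solves c²/(1+c²+σ²) = `effect_strength`, so
`effect_strength` is read as the target voxel-level correlation of one
coupled pair; it is monotone and 0 at 0. Per-subject amplitudes are
jittered (sd 0.15) and clinical scores (ISI, PSQI, SAS, SDS, with
case-control intercepts at typical published questionnaire means) are
linear in the realised amplitude, so score correlations have a recoverable
ground truth. At `effect_strength = 0` the patient and control branches
consume identical random streams and are bit-identical draws — the
exchangeability guarantee used by all null-calibration studies.

Voxels outside every region are zeros (background air): the gray-matter
probability map exceeds the 0.2 masking threshold exactly on the union of
regions, so no analysis stage ever reads them. Motion files are six small
smoothed random walks; they carry no injected artifact and exist to
exercise the Friston-24 plumbing. Not modelled: hemodynamics, physiological
noise, susceptibility artifacts, anatomical variability.

## Temporal preprocessing

Order: discard initial volumes (default 10) → per-voxel linear detrend →
ideal (boxcar) DFT band-pass, 0.01–0.1 Hz → OLS nuisance regression
(Friston-24 motion expansion, CSF, white matter, global signal; 27 columns
plus intercept). The ideal filter zeroes bins strictly outside the band
(DC always), which makes the Parseval energy check exact.

Two decisions deserve justification:

* **Regressors are band-passed with the same band before regression**
  (switchable), and the linear ramp is kept in the regression design. The
  full chain is then one orthogonal projection — onto in-band directions
  orthogonal to the filtered regressors — so re-applying it is exactly a
  no-op, and regression can never reintroduce frequencies the filter
  removed. With raw regressors (the switch off) neither property holds.
* **Short-series rank handling.** Band-passing a design whose column count
  exceeds the dimension of the in-band subspace (possible for short test
  series) makes it rank-deficient; the pipeline projects onto an
  orthonormal basis of the design span, which is the identical projection.
  Note that ~230 retained volumes at TR 2.5 s give a ~104-dimensional
  in-band space: the standard 27-column model is safe at protocol length,
  but a 60-volume toy series is annihilated by it.

Synthetic cohorts have no CSF/WM anatomy; tissue masks default to
designated block regions and the global signal to the whole gray mask.
Subject exclusion by motion (the usual 2 mm rule) is a manifest-level
concern, not realignment, and out of scope.

## Connectivity features

**FCS** (functional connectivity strength): for each gray-matter voxel the
sum of Pearson correlations with all other gray voxels exceeding r > 0.25
(strict; self-correlation excluded), computed in row chunks so the V×V
matrix is never materialised (pinned exactly against an O(V²) double loop).
The subsequent "z conversion" of an FCS map is ambiguous in the field's
usage because a sum of correlations exceeds 1 and cannot be
arctanh-transformed; both readings are implemented — in-mask map
standardization (default) or arctanh of each suprathreshold r before
summation (`fcs_standardize="fisher_sum"`).

**Large-scale FC**: node-mean series over an integer parcellation, pairwise
Pearson r, Fisher z, packed in row-major strict-upper-triangle order with
an explicit pair index map (268 nodes → 35,778 features).
|r| ≥ 1 (possible with duplicated synthetic series) is clamped to 1−10⁻⁷
with a warning.

**ReHo**: Kendall's W of each voxel's series with its in-mask
26-neighborhood (center included; 7/19/27 selectable), computed from
midranks with no tie-correction term, W = 12·Σ_t(R_t−R̄)²/(K²(n³−n)).
Edge voxels use the neighbors that exist (K passed per voxel); isolated
voxels get 0 and a warning. Maps are normalised to in-mask mean 1, then
smoothed.

Voxel-wise maps are smoothed with an isotropic Gaussian (default 6 mm
FWHM, σ = FWHM/√(8 ln 2)) on the zero-filled grid and re-masked. By
default the result is divided by the smoothed mask: synthetic masks have a
high surface-to-volume ratio and the renormalization removes edge
attenuation (a constant in-mask image stays constant).

Feature tables flatten in-mask voxels in C-order (sorted by (x,y,z) index),
with the voxel/pair index map stored so weight back-projection is exact.

## Classification

Stratified k-fold CV (default 5; each class shuffled by seed and dealt into
test blocks differing by ≤1, so 38/44 subjects give per-class test blocks
{8,8,8,7,7}/{9,9,9,9,8} — the "80/20" split up to divisibility). Per fold:
per-feature standardization by train mean/sd (sample sd; zero-variance
features zeroed), PCA retaining **all** components, linear SVM (C = 1,
exposed; patient = positive class). The all-component PCA is a pure
rotation and the linear SVM's dual solution lives in the span of the
training rows, so decision values with and without the PCA stage agree to
<10⁻⁶ — the pinned correctness oracle for the transform chain. Weights are
back-projected as w = R·w_pc and reported in the standardized feature
space (that is what the classifier saw); duplicated features split weight
evenly. Per-fold accuracy/sensitivity/specificity/AUC (AUC from decision
values within the fold) are averaged across folds; pooled test predictions
form one confusion matrix.

Permutation test: each iteration permutes all labels once, then the entire
CV (including re-stratification) is re-run; p = (N_exceed+1)/(N_perm+1)
with ties counted as exceeding. With 1000 permutations the attainable
floor is 1/1001 < 0.001. Two calibration facts from the null studies:
with ~20 subjects the fold-mean metrics are heavily tied across
permutations (they live on a 1/20 grid), so their p values are valid but
conservative; the pooled-decision-value AUC (`auc_pooled` in the CV
result) is nearly continuous, gives approximately uniform null p values,
and is what the uniformity study uses.

Confound removal (`residualize_confound`) regresses each feature on
[1, covariate] over the full sample, replicating the common published
procedure; this leaks the covariate distribution across folds, and a
train-only variant is provided. Severity filtering retains patients with
duration > 6 months, total sleep time ≤ 390 min, and SOL > 45 or WASO > 45
or SOL+WASO > 60 min; controls pass through.

## Weight maps and clusters

Back-projected weight vectors are thresholded to the top 1% of in-mask
voxels by absolute value (⌈pct·V/100⌉ voxels, ties at the cutoff all
retained and logged; signs preserved). Connected components use
26-connectivity by default (6/18 selectable) with positive and negative
voxels labeled separately, so a peak's sign is unambiguous; components
below the minimum size are dropped. Peaks are reported in world mm via the
image affine (0-based voxel indices internally). Anatomical labeling is
out of scope (the region column of cluster tables is blank).

## Group statistics

Per-voxel OLS of subject maps on [intercept, group, age, sex, education]
(group coded patient = 1; no interactions), t for the group column, df =
n − p. With no covariates this reduces to the classical pooled-variance
two-sample t (agreement to 10⁻⁹, the pinned oracle). Voxels with zero
residual variance: t = 0 where the group estimate also vanishes
(bit-identical maps), otherwise missing and flagged.

Residual smoothness per axis uses the classical Gaussian-random-field
first-differences estimator, FWHM_a = d·√(−2 ln 2 / ln(1 − s²_a/(2 s²)))
with s²_a the variance of first spatial differences over in-mask pairs and
s² the point variance, averaged over subjects; ratios ≥ 1 (rougher than
white noise) are skipped and all-skipped axes raise. For noise convolved
with a Gaussian kernel the formula returns the kernel width exactly in the
continuum limit; the estimator recovers an 8 mm kernel on a 24³ grid at
3 mm voxels within 15%.

Cluster-extent correction is AlphaSim-style Monte Carlo: Gaussian white
noise on the mask's padded bounding grid, smoothed to the estimated
per-axis FWHM with periodic (wrap) boundaries — making the field
stationary so one in-mask variance renormalization renders the voxel
threshold exact — then two-sided thresholding at |z| > z_{1−p/2} (voxel
p = 0.01) and recording the largest sign-split component. The critical
size is the smallest k with empirical P(max ≥ k) ≤ α (α = 0.05; 1000
simulations at full scale). Data maps are thresholded at the matching t
quantile and components ≥ the critical size survive.

A geometry caveat discovered in calibration: the correction's family-wise
error is honest (within the binomial band of 0.05 over 200 null cohorts)
when the null map's spatial covariance is kernel-induced, i.e. on compact
single-region masks. Layouts of many small latent-sharing blocks put
block-wise equicorrelation into the maps at all distances; the smoothness
estimator then reports a large FWHM (correctly, in the sense of fitted
Gaussian width) but the Gaussian-field null is a poor model of such
fields. This mirrors the real-data situation, where AlphaSim's Gaussian
assumption is itself an approximation.

Edgewise (large-scale FC) comparisons use Benjamini–Hochberg FDR at
q = 0.05. Cluster–score correlations are Pearson r of per-subject
cluster-mean values against a questionnaire score, two-sided p from the t
transform, with an optional subject subset (the patient group, in the
standard design). One synthetic-specific caveat: within-mask map
standardization makes FCS maps relative, which preserves the group
difference but dilutes the within-patient amplitude link; the recovery
study therefore evaluates the score correlation over the whole cohort.

## Validation studies and their scales

The acceptance suite and `scripts/acceptance.py` run, per fresh seed:
structural dimensionality (268 nodes → 35,778), the permutation-p floor,
oracle equivalences (chunked FCS vs O(V²); Kendall's W vs hand-expanded
ranks; FDR vs independent step-up; components vs flood fill),
PCA-rotation invariance, null calibration (100-seed CV accuracy within the
binomial band of 0.5; 200×99-permutation p uniformity by KS; family-wise
error within the band of 0.05 over 200 replicates at 200 simulations),
signal recovery at coupling 0.8 with 20+20 subjects (mean accuracy > 0.9;
top-1% weight cluster Dice > 0.5 with peak inside the region in ≥ 80% of
10 seeds; cohort-level score correlation), and 8 mm smoothness recovery
over 50 replicates. The script reports smaller replicate counts (30/60/3/20)
than the test suite; both complete on one CPU in minutes. Passing these
shows the machinery is correct and calibrated on data satisfying the
generator's assumptions; it does not certify performance on real BOLD data
with hemodynamics, physiological noise, or realistic anatomy.
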