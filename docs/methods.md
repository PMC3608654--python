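# Methods

## Problem and model

A single patient's scalar brain map — in the motivating application a DTI
fractional-anisotropy (FA) volume, registered to a template and restricted
to a white-matter mask — is compared voxel by voxel to a small normative
("reference") cohort.  At voxel *i*, with reference mean `m_i` and SD
`s_i` (n−1 denominator) from *n* controls, the classical scores are

    Z_i = (x_i − m_i) / s_i                     (standard Z, N(0,1) null)
    t_i = Z_i / sqrt(1 + 1/n)                   (one-vs-many t, t(n−1) null)

The one-vs-many (Crawford–Howell) t is exact when the control values are
iid Gaussian.  With a small reference cohort, however, `m_i` and `s_i`
are themselves noisy: the held-out-control Z-score is distributed as
`sqrt(1 + 1/n) · t(n−1)`, whose SD for n = 20 is ≈ 1.083, so thresholding
Z against N(0,1) over-calls abnormality; and any departure from
Gaussianity (e.g. variance heterogeneity across subjects) invalidates the
t's nominal coverage altogether.

The enhanced Z-score (EZ) addresses both nonparametrically.  A bootstrap
estimates the sample-to-sample SD of the Z-score at each voxel: each of
*B* replicates draws n+1 subjects with replacement from the *N* available
controls, uses the first *n* as a reference group, scores the (n+1)-th
against them, and `sd*_i` is the SD (n−1 denominator) of the *B*
replicate Z-scores.  Then

    EZ_i = Z_i / sd*_i

is referred to a standard Gaussian.  Where the data really are Gaussian,
`sd*` reproduces the theoretical factor (≈ 1.06 · sqrt(1 + 1/n) for
n = 20) and EZ behaves like a correctly calibrated Z; where dispersion is
locally inflated or deflated, `sd*` adapts per voxel.  The mean of the
replicate Z-scores (`mean_z`) is retained as a bias diagnostic; it should
be tightly centered on zero.

## Covariate adjustment

Before scoring, systematic effects of age, sex (F=0/M=1) and education
(years) are removed by a voxelwise OLS regression fitted on the reference
cohort (overall F test with 3 numerator and n−4 denominator df).  The
fitted effects are subtracted — for any subject, patient or control —
only at voxels where the F test passes at `alpha` (default 0.05) *and*
the passing voxels form a connected cluster of strictly more than
`cluster_gate` voxels (default 100, 26-connectivity).  Adjusting
everywhere would inject regression noise into the smooth residual field
and cost detection sensitivity; the gate restricts the correction to
regions with spatially coherent demographic effects.  Covariates are
centered at the reference-cohort means (the fit is equivariant to the
centering choice; mean-centering keeps adjusted maps comparable to the
reference mean).  All three covariate terms are removed at significant
voxels, not only the individually significant ones.

## Dual thresholding and GRF cluster inference

Abnormality is decided in two stages.  Stage one: a two-sided voxel
threshold `alpha1` on the score's null distribution (Gaussian for Z/EZ,
t(n−1) for the one-vs-many t); the score's sign labels abnormally high
vs abnormally low values, and the two signs are treated as separate
families throughout.  Stage two: contiguous suprathreshold clusters
(26-connectivity by default) are kept only if their spatial extent is
improbable under a stationary Gaussian random field, at level `alpha2`.

Cluster p-values use the classic cluster-size exceedance formulation.
With resel count `R = S / (FWHM_x · FWHM_y · FWHM_z)` (S = mask voxels)
and Gaussian-scale threshold `u`:

    E[m]      = R · (4 ln 2)^{3/2} (2π)^{−2} (u² − 1) e^{−u²/2}
    E[N]      = S · (1 − Φ(u))
    P(n ≥ k)  = exp(−β k^{2/3}),   β = (Γ(5/2) / (E[N]/E[m]))^{2/3}
    p_corr    = 1 − exp(−E[m] · P(n ≥ k))

"Corrected" retains clusters with `p_corr ≤ alpha2` (familywise over the
search volume, per sign); "uncorrected" uses `P(n ≥ k)` directly.
Smoothness is estimated from the reference residuals: standardized
residual fields are differenced along each axis, and
`FWHM_a = sqrt(4 ln 2 / λ_a)` with `λ_a` the lag-1 difference variance
relative to the residual variance.  White noise gives the resolution
floor `sqrt(2 ln 2) ≈ 1.18` voxels.  Score maps are never spatially
smoothed — smoothing would blur lesion margins — so the estimated FWHM
reflects the data's intrinsic correlation.

A Monte-Carlo check (500 null fields, FWHM 3 voxels, 32³ lattice with an
ellipsoidal mask) puts the realized familywise rate of the corrected
test at `alpha2 = 0.05` close to nominal (≈ 0.05–0.08 across seeds,
both signs combined).  Note one non-obvious consequence of the size
formulas: corrected cluster *counts* are not monotone in `alpha1` — a
tighter voxel threshold shrinks clusters but also makes any given size
rarer under the null, so a cluster can survive at `alpha1 = 0.01` yet
fail at 0.05.

## FWER pseudo-t comparator

The comparator method replaces the voxelwise SD with a spatially smoothed
SD (Gaussian kernel, default FWHM 8 mm) to form a pseudo-t map, and
controls the familywise error empirically: per-tail thresholds are the
(1 − alpha) quantiles of the maximum (and minimum) pseudo-t over
leave-one-out reference subjects, with no cluster-extent stage.  This is
a deliberate simplification of the published comparator (which calibrates
pseudo-t degrees of freedom by cross-validation); the max-statistic
quantile achieves the same familywise control and is far simpler.  It is
markedly conservative, which is the point of the comparison.

## Evaluation machinery

Per-subject global metrics are the abnormal-voxel counts (all / low /
high; all = low + high).  Discrimination of patients from held-out test
controls uses AUC = Mann–Whitney U / (n_p · n_c) with midrank ties, a
one-tailed Wilcoxon–Mann–Whitney p (patients > controls; exact
enumeration for tie-free samples with n_p·n_c ≤ 400, otherwise the
tie-corrected normal approximation), ROC curves as step functions over
observed counts, and the operating point closest to (FPR 0, TPR 1) with
ties broken toward higher sensitivity.  The grid search crosses
`alpha1 ∈ {0.05, 0.01}` with `alpha2 ∈ {0.05, 0.01} × {corrected,
uncorrected}` for each scoring method; the reference cohort must be
disjoint from the test controls.  Group-difference tests on the counts
are the unequal-variance t, the two-sided WMW, and the paired t for
within-patient comparisons across reference groups.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
each subject is `baseline + σ_i · G_j + covariate terms (+ lesions)`,
with `G_j` a stationary unit-variance Gaussian field (white noise
convolved with a Gaussian kernel on a torus, renormalized by the kernel's
L2 norm).  Defaults: 32×32×32 voxels of 1 mm with an ellipsoidal mask,
baseline 0.45 and between-subject SD 0.05 (typical white-matter FA
levels), field FWHM 3 mm (a plausible intrinsic correlation scale for
unsmoothed 1 mm FA maps), cohort sizes 21 reference / 21 test controls /
34 patients (the validation design's sizes), and one spherical lesion of
radius 3.6 voxels (≈ 200 voxels) at −3σ in each patient.

Variance heterogeneity follows the two-Gaussian scale mixture
`π₁ N(μ, σ₁²) + (1−π₁) N(μ, σ₂²)` in either of two readings of the
sampling unit: per-voxel (each voxel assigned σ₁ or σ₂ once, fixed
across subjects — subpopulations of voxels) or per-subject (every
subject–voxel draw independently from the mixture — subpopulations of
people).  The per-voxel mode is the default.  The distinction matters:
the one-vs-many t is scale-invariant, so per-voxel heterogeneity leaves
its coverage exactly nominal; only the per-subject mode produces the
across-subject mixture under which the t interval's empirical coverage
fails (≈ 0.93 instead of 0.95 at π₁ = 0.5, σ = 0.5σ/1.5σ), and the
coverage-failure experiments therefore use that mode.

What the generator does *not* model: real white-matter anatomy and tract
geometry, nonstationary smoothness, registration error, FA's bounded
support and skewness, and the right-tail asymmetry seen in real EZ
densities.  Passing tests therefore demonstrate internal statistical
correctness of the machinery under its own assumptions, not clinical
performance; the published patient-level numbers (AUC ≈ 0.72,
sensitivity/specificity ≈ 0.71) depend on a private clinical cohort and
are out of scope.

## Numerical choices and defaults

- `B = 1000` bootstrap replicates by default (2000 in the consistency
  experiments): the Monte-Carlo SE of `sd*` is then well below the width
  of the dispersion band.  Resampling is with replacement over all N
  controls for every slot (the held-out subject may coincide with a
  reference member); a leave-one-out scheme (`scheme="holdout"`) is
  available.  Replicates with zero reference SD at a voxel are dropped at
  that voxel only, with a logged count.
- `sd_floor = 1e-6` (FA units): voxels with reference SD below it are
  flagged and excluded from scoring (reported, never silently zeroed).
- Dispersion classes compare `sd*/sqrt(1+1/n)` to the SD of the t
  distribution with df offset ±10 (`ψ_L = SD t(df+10)`,
  `ψ_U = SD t(df−10)`); the offset shrinks to `df−4` for small cohorts
  so the band exists.
- Connectivity 26 by default (6/18 configurable); the cluster gate uses
  strict inequality ("more than" `cluster_gate` voxels).
- Tail probabilities are two-sided, `2(1 − Φ(|EZ|))`; sidedness of the
  decision is carried by the score's sign.
- Missing values propagate as missing; no imputation anywhere.
- Volumes are float32 on disk, float64 in memory; masks intersect (never
  union) across subjects so every retained voxel has n observations.

## Problem sizes in the shipped experiments

The test suite and the reproduction script run on reduced lattices
(16³–32³ with ellipsoidal masks, a few thousand in-mask voxels) with the
cohort sizes above; at these sizes every experiment is seconds to tens of
seconds and all Monte-Carlo bounds stated in the tests were chosen with
the corresponding sampling error in mind.  The conservativeness-ordering
experiment pools three independent reference cohorts of 40 subjects,
because the expected EZ-vs-t count margin under homogeneous Gaussian
variation is only 1–2% and a single small cohort can flip it; the
lesion-recovery rate sits near its 0.90 bound (a spatially correlated
noise field cancels a 3σ lesion below the cluster threshold in roughly
one subject in ten), so seed-to-seed values of 0.85–0.95 are expected.

## Known limitations

- GRF formulas assume stationarity and a unit-variance Gaussian field;
  nonstationary (local-smoothness) correction and permutation-based
  cluster inference are documented alternatives, not implemented.
- The EZ null is taken as standard Gaussian; the observed right-tail
  asymmetry of real EZ densities (and mixture-model density estimation
  of it) is out of scope.
- The pseudo-t comparator approximates the published method's
  cross-validated df calibration by a leave-one-out max-statistic.
- No registration, resampling, reorientation or preprocessing: inputs
  are assumed pre-aligned on a common grid.
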