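# Methods

`rehomvpa` implements a classification workflow for three-group resting-state
fMRI cohorts — depressed essential-tremor patients (DET), non-depressed
essential-tremor patients (ET), and healthy controls (HC) — built on
voxel-level regional homogeneity and whole-brain multivariate pattern
analysis, plus a synthetic cohort generator that makes every stage testable
without clinical data.

## Regional homogeneity (ReHo)

ReHo quantifies local functional connectivity as Kendall's coefficient of
concordance W between a voxel's time series and those of its 26 nearest
(face/edge/corner) neighbours.  For K series of n time points, with R_i the
across-series sum of within-series temporal ranks at time point i and
R̄ = (n+1)K/2,

W = (Σ_i R_i² − n R̄²) / ((1/12) K² (n³ − n)),  W ∈ [0, 1].

Numerical choices:

- **Ties** take average ranks and no tie-correction term is added to the
  denominator; BOLD-like floating-point series make exact ties measure-zero.
- **Mask edges.** The canonical neighbourhood is K = 27, but voxels at mask
  boundaries lack neighbours.  By default the in-mask neighbour subset is
  used with the actual K (discarding edge voxels would shrink the
  discriminative surface); `edge_policy="full"` zeroes voxels without the
  complete neighbourhood instead.  Voxels with K < 2 are set to 0.
- **All-constant sets** have undefined rank agreement; W is reported as 0
  with a warning.
- Under null concordance E[W] = 1/K (the Friedman-statistic relation), so
  white-noise volumes sit near 1/27 at interior voxels — a useful sanity
  anchor that does not depend on series length.
- The vectorized map computation (rank once per voxel, then sum rank
  volumes over the 27 neighbourhood shifts) is exactly equal — bit-for-bit —
  to the per-voxel loop, because every intermediate quantity is an exact
  multiple of 0.25 well below 2⁵³.

Each raw W map is divided by its within-mask global mean (in-mask mean
becomes exactly 1), then smoothed with a Gaussian kernel, default 4 mm
full-width at half-maximum converted per axis through the voxel size
(σ_vox = FWHM / (√(8 ln 2) · voxel_mm)).  Smoothing comes *after* the W
computation, so it cannot manufacture neighbourhood concordance; it uses
reflective boundaries (constants are preserved) and the output is re-masked
by default.

## Temporal preprocessing

The pipeline assumes spatially normalized series (slice timing, realignment
and normalization are out of scope) and applies, in order:

1. **Nuisance regression** — voxelwise OLS on an intercept plus the
   Friston-24 motion expansion {p, p², p(t−1), p(t−1)²} and white-matter,
   CSF and global-mean signals.  Collinear or zero columns are dropped with
   a warning; residuals are orthogonal to every retained regressor.
2. **Linear detrend** — removal of the per-voxel best-fit line.
3. **Band-pass 0.01–0.08 Hz** — an ideal (frequency-domain) zero-phase
   filter: Fourier components outside the band are zeroed.  This is the
   filter family of the classic resting-state toolboxes; it is exactly
   idempotent and introduces no phase shift, which matters here because any
   temporal shift would distort rank order and bias W.  Re-running the
   composed detrend+filter operator changes the signal by ~1–2 % RMS at
   T ≈ 230 — the line subspace of the detrend step is not orthogonal to the
   pass band on a finite window — while the filter alone is an exact
   projection.

Head motion is summarized as mean framewise displacement (Power variant):
the sum of absolute backward differences of the six rigid-body parameters,
rotations converted to arc length at a 50 mm radius.  Subjects with mean FD
strictly above 0.2 mm are excluded before any analysis.

## Classification

Features are the smoothed, normalized ReHo values at in-mask voxels
(subjects × voxels; columns in lexicographic grid order).  Evaluation is
leave-one-subject-out cross-validation: each fold mean-centers the features
with training-fold statistics only (no test leakage; a global-centering
variant exists behind a flag for comparison with toolboxes that center
once), trains, and predicts the held-out subject.  All classifiers are
linear, f(x) = w0 + wᵀx:

- **Linear SVM** (C-SVC, default C = 1; the soft-margin parameter is not
  dictated by the method and is exposed as a flag).
- **Gaussian-process classification** with Laplace-approximate posterior
  and kernel k(x, x′) = σ₀² + x·x′ (linear plus a constant bias component;
  σ₀² = 10 by default).  Binary uses the logistic likelihood with the
  standard stable Newton iteration; multiclass uses the softmax likelihood
  in the inverse-free parameterization (per-class Cholesky of
  I + D^{1/2} K D^{1/2}), which remains stable when the kernel is
  rank-deficient — e.g. constant features, where predictions collapse to
  the training class frequencies as they should.  Predictions plug the
  latent posterior mean into the link (MAP plug-in, no predictive-variance
  correction): deterministic, and exact for the class-frequency collapse.
  Newton iterations are bounded (default 100) and non-convergence raises
  with diagnostics.  Expectation propagation is not implemented.

Metrics from the held-out confusion matrix (true × predicted): sensitivity
TP/(TP+FN), specificity TN/(TN+FP), PPV, NPV, balanced accuracy, total
accuracy, and AUC via the Mann–Whitney rank statistic (ties count ½).  The
"positive" class is the patient-like class — by default the alphabetically
first label, which makes DET positive in every contrast here; it is
configurable and recorded in every result.  Zero-denominator metrics are
reported as NaN with a warning, never silently as 0.  Three-class AUC is
reported pairwise (one-vs-one) from the class-probability matrix.

Because LOSOCV with these linear fits has no stochastic step, repeated runs
are bit-identical.

## Permutation inference and the discriminative map

Significance is assessed by label permutation: each replicate permutes the
subject labels uniformly at random (class counts preserved by
construction), reruns the complete LOSOCV, and records the performance
metrics; p = #{replicates with metric ≥ observed} / n_perm, ties counting
against the observed value.  A count of zero is reported as
"p < 1/n_perm" rather than 0.  The default replicate count is 1,000;
simulation suites use smaller counts and say so.

Per-voxel contribution uses the *normalized* absolute across-fold mean
weight: each run's |mean weight| vector divided by its L2 norm, i.e. the
voxel's share of the weight map.  Normalization is not cosmetic — for a
maximum-margin classifier the overall weight scale is inversely tied to the
margin, so an easily separated observed problem has *small* raw weights
while permuted labels force *large* ones; comparing raw |w| across
permutations would make true effects look null.  The normalized statistic
compares where the weight sits, which is what a discriminative map is
about; its permutation p compares against the same statistic from the
permuted replicates.  The discriminative map keeps
voxels with p strictly below α (when α is below the resolution 1/n_perm of
a reduced-permutation run, only voxels never reached by any permutation
survive), groups them into connected components — default 26-connectivity,
matching the 27-voxel neighbourhood spirit; 6 and 18 selectable — and
retains components strictly larger than 30 voxels.  Components are signed
by their mean weight (positive = patient group higher).

With only n_perm label permutations the attainable p-values are multiples
of 1/n_perm, and with small cohorts the accuracy metrics are coarse, so
permutation p-values are super-uniform under the null: the measured
type-I-error rate at the 0.05 level sits at or below nominal.  The
calibration suite checks it stays within [0.02, 0.10].

## ROI–symptom correlation

The surviving clusters of the DET-vs-HC contrast become ROIs; each
subject's mean smoothed ReHo per ROI is correlated with the HDRS-17
depression score by partial Pearson correlation among DET subjects,
controlling for age, sex (coded 0/1), education, tremor scores (TRS parts
A&B and C), MMSE, anxiety (HARS-14) and mean FD.  Both variables are
residualized on [intercept | covariates]; r is the Pearson correlation of
the residuals and the two-tailed p uses t = r √(df/(1−r²)) with
df = n − k − 2.  With zero covariates this reduces exactly to plain
Pearson.  Bonferroni control offers two modes — α/m for m ROIs (default)
and the pairwise α/(m(m−1)/2) variant — because published figure captions
in this literature sometimes quote the pairwise form even when m tests are
performed; the default is the test count, and the mode is recorded in the
output.

## Synthetic cohorts

The generator emulates the study conditions: group sizes 41/43/45
(DET/ET/HC), T = 230 retained volumes at TR = 2 s, a 24×24×24 grid of 3 mm
voxels.  Its parts:

- **Baseline noise**: stationary unit-variance AR(1) series per voxel
  (default lag-1 coefficient 0.3, a mid-range value for band-limited BOLD
  noise), burn-in 100 samples.
- **Implanted coherence**: inside each effect region every voxel is
  √c · shared + √(1−c) · private with both components AR(1), so c is the
  shared-variance fraction and in-box Kendall's W increases monotonically
  with c.  Each subject's realized c deviates from the group value by a
  Gaussian perturbation (SD 0.1 by default), clipped to [0, 0.999];
  regions with group coherence 0 stay pure independent noise.
- **Clinical covariates**: independent lower-truncated normals whose
  *truncated* means match the published group means (the location is
  solved for; sampling at the printed mean would overshoot it after
  truncation — by +0.44 HDRS points in the DET group).  HDRS-17 is floored
  at 7 for DET (the diagnostic threshold) and 0 otherwise; rating scales
  at 0; sex is Bernoulli at the published male fraction; HC tremor scores
  are 0.  Covariates are drawn independently — the published table gives
  moments only, so the joint distribution is unknowable; this is a stated
  simplification.
- **Symptom coupling**: HDRS-17 = base + Σ_regions coupling × (c_subject −
  c_group) + floor truncation, which links depression severity to the
  actually implanted signal and makes the ROI-correlation stage a
  parameter-recovery problem.
- **Head motion**: mean FD uniform on [0.05, 0.18] mm so every subject
  passes the 0.2 mm gate by default; a per-group count of injected
  high-motion subjects (FD uniform on [0.21, 0.45]) exercises the
  exclusion stage.

Default effect regions are two 6³ boxes: an anterior-superior box with
DET-elevated coherence and positive symptom coupling (a prefrontal-like
positive discriminative pattern) and a posterior-inferior box with
DET-reduced coherence and negative coupling (cerebellar-like negative
pattern).

What the generator does *not* emulate: anatomy and tissue contrast, spatial
autocorrelation of noise outside the implanted boxes, scanner artifacts,
slice timing, susceptibility distortion, realistic motion time series, and
covariate correlations.  Passing tests therefore demonstrate that the
pipeline recovers implanted local-coherence structure and is calibrated
under its null — not that any specific clinical accuracy would be attained
on real data.

## Reproducibility and problem sizes

Every stochastic step flows from a single seed through spawned per-subject
RNG streams, so streaming and materialized generation are identical and
reruns are bit-exact.  The validation suites use desk-scale problem sizes
chosen once: classification recovery at 15+15 subjects on the full 24³
grid with T = 230; permutation calibration at 100 cohorts × 200
permutations (12 subjects, 6³ grid); discriminative-map localization at
10+10 subjects, 18³ grid, 100 permutations; ROI sign recovery at 100
cohorts of 30 patients, 12³ grid.  Full-scale analyses (129 subjects,
1,000 permutations) run through the same code paths via the CLI.

## Known limitations

- Simple multiple-kernel-learning classifiers are not implemented (reported
  inferior in this workflow's source analyses and toolbox-specific).
- No parametric (Gaussian-random-field) cluster inference and no voxelwise
  FDR: inference is permutation + extent only.
- The GPC omits predictive-variance correction and expectation propagation;
  probabilities are MAP plug-ins.
- Surface-based and 7/19-neighbour ReHo variants and frequency-specific
  ReHo are out of scope.
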