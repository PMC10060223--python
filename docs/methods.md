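# Methods

This note documents the models, numerical choices and limitations of the
package.  Notation: subjects *i*, ROIs *r*, voxels *v*; y is the behavioral
score, d<sub>ir</sub> the disconnection score.

## Behavioral scores

TMT: `score = ln(B − A)` seconds, defined only for B > A > 0; subjects
with B ≤ A are flagged missing and excluded, never imputed.  Stroop:
counts of correct responses in a fixed window (default 45 s) are converted
to seconds per correct response and the interference
`rt_CW − (rt_C + rt_W)/2` is log-transformed; nonpositive interference is
likewise a missing score.  The natural logarithm is used throughout — the
log base only rescales scores linearly and cannot affect correlations,
selection or AIC differences.  Standardization uses the sample SD (n−1)
and is performed within each sample: cross-task prediction compares
z-scores computed in the training sample with z-scores computed in the
test sample.  This is the minimal reading of "standardized to allow
cross-task prediction"; pooling samples before z-scoring would leak test
statistics into training.

## Volumes and grids

All volumes must share one template geometry (shape + affine, hashed into
a `grid_id`); combining mismatched grids is a hard error, and no
resampling is implemented — registration happens upstream of this package.
NaN anywhere in an input volume is a hard error rather than silently
treated as 0.  Cluster operations default to 26-connectivity (the standard
volumetric cluster convention); 6 and 18 are available.

## Disconnection scores

`d_ir = Σ_{v ∈ lesion_i} M_r(v)`, computed exactly (no thresholding,
no normalization by lesion size).  FC maps are signed Fisher-z fields and
the masked sum is taken as-is — negative z under a lesion reduces the
score.  FC voxels with undefined correlation (zero variance) carry 0 and a
count of them is kept for QC.  The edge-density baseline is the same
masked sum against a single whole-brain map; the lesion-volume baseline is
voxel count × voxel volume (mm³).

## FC map construction

Seed-based recipe: linear detrend, ideal FFT band-pass (default
0.009–0.08 Hz), regression of caller-supplied nuisance columns (the module
adds an intercept and band-passes the regressors identically; callers
supply motion/global/ventricle/WM-style regressors and their first
temporal derivatives), correlation of each voxel's residual with the
ROI-mean residual, Fisher z.  |r| is capped at 1 − 1e−12 before `atanh`.
The band-pass is an ideal (brick-wall) frequency-domain filter — simple
and exactly invertible, at the cost of ringing on strongly non-stationary
signals; it is configurable.

## The network AC map

The a priori network's AC maps are combined by PCA: each map is centered
over brain-mask voxels, the stack's first right-singular vector gives the
voxel loadings, oriented so the mean loading is nonnegative, zeros outside
the mask.  Only the first component is used; an optional loading threshold
is exposed but no default is claimed.  Centering each *map* (rather than
each voxel across maps) keeps the component interpretable as the common
above-average connectivity pattern and makes the degenerate identical-maps
case reduce to the (centered) map itself.

## CPM

Feature selection: vectorized per-ROI Pearson r, with
`t = r·√((n−2)/(1−r²))` and two-sided p from the exact t reference
distribution with n−2 df.  Constant columns are never selected.  Sign
policy: `positive_only` for AC and edge-density scores, `two_sided` for FC
(whether the original restriction applied to FC is unknown; two-sided is
the permissive reading).  Selection threshold α = 0.01 uncorrected.

Prediction: per-ROI univariate OLS of behavior on disconnection, averaged
with equal weights across selected ROIs.  A model with zero selected ROIs
is degenerate: it predicts the training mean and is flagged, keeping AIC
comparisons computable.  Cross-validation defaults to leave-one-out
(deterministic); k-fold with a seeded shuffle is available.  Feature
selection is nested inside every training fold — selection on the full
sample before CV would invalidate the out-of-sample claim.

A consequence of the equal-weight averaging worth knowing: averaging many
weakly inter-correlated per-ROI predictions shrinks the prediction SD well
below r·SD(y), so the averaged prediction is underdispersed.  AIC measures
RSS, which penalizes miscalibrated dispersion; two models with different
feature-correlation structure can therefore occasionally swap AIC order
even when one clearly dominates in correlation.  This is a property of the
prediction rule itself, not of its implementation here.

## Model comparison

`AIC = n·ln(RSS/n) + 2k` with k = 1 by default and identical k across
compared models, so differences reduce to `n·ln(RSS₁/RSS₂)`.  The original
AIC variant is unspecified; this Gaussian-residual form is chosen because
it reproduces the internal identity linking the two reported effect
quantities, `|ΔAIC| = 2n·ln R` with R the worse/better ratio of
root-mean-square prediction errors — absolute AIC values are therefore not
comparable to other variants, only differences are meaningful.  The
evidence rule `p = L/(1+L)`, `L = e^(ΔAIC/2)` is one-sided; callers place
the hypothesized better model first.  Extreme ΔAIC is computed through the
logistic form, so p underflows gracefully to 0 or saturates at 1.
Bootstrap CIs are percentile (not BCa), resampling subjects with
replacement, B = 100 by default; resamples with RSS = 0 are redrawn and
capped.  FDR is Benjamini–Hochberg step-up.

## Permutation nulls

Cluster relocation: every cluster is independently rigidly translated
(shape preserved, no rotation/reflection — the minimal reading of
"permuting locations") to a uniform position fully inside the brain mask
via rejection sampling; relocated clusters may overlap each other and
overlapping voxels count once.  Empirical p-values use the add-one
convention `(1 + #{null ≥ obs})/(1 + B)`, so p ∈ [1/(B+1), 1] and never
exactly 0.  Note that count-valued overlap statistics on small grids are
coarsely discrete; ties make the empirical p conservative, and calibration
checks should use the weighted (continuous) overlap mode.

Random-ROI specificity: each iteration samples k ROIs without replacement
and reruns the identical CPM train/test; degenerate iterations predict the
training mean rather than being skipped (skipping would bias the null
toward informative subsets).  Lower AIC is better, so the alternative is
"less".

## Back-projection

Per voxel, a simple regression across ROIs of the selection-stage t-scores
on the voxel's AC value, with intercept; the output is the slope
t-statistic (0 at zero-variance voxels, capped at ±1e8 for numerically
perfect fits).  The null permutes the assignment of t-scores to ROIs —
exchangeable under the hypothesis that connectivity profiles carry no
information about ROI predictiveness — and records the map-wise maximum
statistic per permutation (family-wise error control).  Two-tailed
handling uses |t|; with TFCE, the positive and negative branches are
enhanced separately and combined voxel-wise by max.  TFCE defaults:
E = 0.5, H = 2, 100 integration steps of size max(stat)/steps,
26-connectivity.  For an isolated voxel of height h at these defaults the
transform converges to h³/3 as the step size shrinks.

## Synthetic cohort generator

The generator emulates the *structure* of a three-sample lesion study —
not its anatomy.  Defaults (chosen once, stated here as the package's
conditions):

- grid 40×48×40 at 1.5 mm isotropic; ellipsoid brain mask;
- 60 spherical cortical ROIs, 30 per hemisphere, minimum separation
  enforced;
- a 10-ROI a priori network (~17% of ROIs) balanced across hemispheres;
- AC maps: sums of straight Gaussian-profile tubes (σ = 2.5 mm, peak 50)
  from each ROI to its partners.  Network ROIs connect long-range to other
  network ROIs; all other ROIs connect to their nearest neighbours, so
  tracts are spatially segregated the way association fibres are — without
  this, every tube crosses the phantom's centre and every disconnection
  score degenerates into a lesion-volume proxy;
- FC maps: Gaussian bumps at the seed and an imperfect partner list (one
  true partner dropped, two indirect ROIs added, emulating polysynaptic
  coupling) plus a smooth signed background, scaled to a Fisher-z-like
  range.  FC fields live in grey matter, not along the tract course, which
  is why FC disconnection carries less information than AC about
  tract-transecting lesions;
- edge density: normalized union of all pair tubes;
- lesions: unions of 1–2 ellipsoidal blobs, log-normal radius
  (mean log 1.15, SD 0.3 voxel units), laterality mix 40/40/20 L/R/bilateral,
  clipped to the brain mask;
- behavior: y = β₀ + w·(Σ_r z(d_ir))/SD + ε with the planted set the union
  of shared and task-specific ROIs (3 + 2 by default, all inside the
  network), ε ~ N(0, 0.3²).  Planted columns are standardized within
  cohort before weighting because raw masked sums have arbitrary
  atlas-dependent scale; the composite is normalized so the signal SD
  equals `effect_weight` (0.8) regardless of how many ROIs are planted.
  Effective per-ROI weights are recorded in the ground truth;
- raw task fields are back-computed so the behavior module reproduces the
  latent score exactly: TMT-A ~ U(25, 40) s and TMT-B = A + e^y; Stroop
  counts are searched over (C, W, CW) integer triples to within 0.02 log
  units (rounding recorded).  Stroop latents are clamped to the range a
  45-second window can express (ln-interference in [−4.2, 3.0]) — real
  tests saturate at floor/ceiling — and clamped subjects are counted;
- sample sizes 120/100/80 (train TMT, test TMT, test Stroop), disjoint
  subjects.

What passing tests on this generator do show: the pipeline's statistics
are calibrated (selection rate ≈ α under the null, permutation p uniform,
bootstrap coverage nominal, family-wise error at level), parameters are
recovered under strong signal, and the qualitative orderings the design
plants (AC above FC; the a priori network surviving restriction
cross-task) emerge from the analysis.  What they do not show: performance
on real anatomy — curved tracts, shared deep-WM bottlenecks, vascular
lesion topographies, registration error, and behavioral confounds (age,
education, co-occurring deficits) are all absent.  At these desk-scale
sample sizes the AC-over-FC AIC ordering reproduces in roughly 94% of
cohorts (the AC model has higher held-out correlation in essentially all
of them; the remainder are dispersion-calibration flips of the averaging
rule discussed above, whose rate shrinks as n grows).

## Problem sizes used in the test suite

Integration fixtures run on a 24×28×24 grid with 20 ROIs and groups of
40/30/25.  The selection-calibration check uses n = 200 × 60 ROIs × 500
replicates; parameter recovery uses 100 cohorts at 20 ROIs, n = 60, strong
weights (1.5) and low noise (0.1); the AC-vs-FC and network-restriction
checks use 100 cohorts at the full default conditions with one shared
phantom atlas (the atlases emulate fixed normative data — only patients
vary across cohorts); permutation and coverage calibrations use B = 99
nulls / 200 replicates and B = 2000 bootstrap / 500 replicates
respectively.

## Known limitations

- No spatial resampling/registration; inputs must share a grid.
- Absolute AIC values are tied to the Gaussian-residual form; only
  differences are meaningful.
- The cluster-relocation null ignores spatial autocorrelation of the
  reference map (no variogram/spin-style preservation).
- TFCE is evaluated by a finite Riemann sum; very coarse step counts
  underestimate the transform.
- The Stroop inverse transform is limited by integer counts; scores are
  representable only to ~0.02 log units and within the window's
  floor/ceiling.
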