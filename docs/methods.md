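# Methods

## Problem setting

`petroi` discovers discriminative metabolic patterns in spatially
normalized FDG-PET brain volumes.  Instead of fixing regions of interest
(ROIs) anatomically (atlas regions) or testing voxels one at a time
(mass-univariate t-tests), it derives ROIs from the data itself: voxels of
a normal-control (NC) reference image are clustered into units that are
homogeneous in uptake *and* compact in space, and each subject is then
summarized by per-cluster statistics and classified with a linear
margin classifier.

All volumes are assumed spatially normalized upstream (a shared voxel
grid; the classic template grid is 91×109×91, but any consistent shape
works) and intensity-normalized by one of two schemes implemented in
`volume_io`: grand-mean (divide by the mean over all brain voxels) or a
reference-region scheme dividing by the mean over the primary
sensorimotor cortex (pre/postcentral gyri), a territory relatively spared
in dementia.  Both schemes are scale-equivariant, so global scanner
scaling cancels.

## Mixture model and model selection

`gmm_core` implements the density p(x|θ) = Σ_k π_k N(x|μ_k, Σ_k) with
full covariances, fitted by EM:

* E-step: responsibilities p_nk ∝ π_k N(x_n|μ_k, Σ_k), computed in log
  space and normalized per point.
* M-step: weighted proportions, means and scatter matrices; a ridge
  ε·I with ε = 1e-6 × (mean per-axis data variance) is added to each
  covariance so thin voxel slabs cannot produce singular Σ.

Everything likelihood-shaped goes through a log-sum-exp: the inner sum of
log Σ_k exp(A_nk) factors out the row maximum, so the log-likelihood stays
finite on data scaled by 1e±150 where direct density evaluation
under/overflows.  EM's monotone-likelihood guarantee is asserted in tests
(slack 1e-8) over 100 random instances.

Initialization (not dictated by the underlying theory; a package choice):
farthest-point seeding of K centers from the data with small jitter,
one hard-assignment pass to responsibilities, then EM.  Defaults:
3 restarts, |ΔL| < 1e-6 absolute, 300 iterations max, all randomness
behind one integer seed.

The number of components is chosen by minimizing

    BIC = −2 log L + log(N)·P        AIC = −2 log L + 2·P

with P = K·D·(D+3)/2 + K − 1 free parameters.  Ties break toward smaller
K, and BIC differences are translated into the usual Bayes-factor grades
(0–2 weak, 2–6 positive, 6–10 strong, >10 very strong; boundaries fall in
the lower band).  On 3D mixtures with 8σ separation and N = 2000, BIC
recovers the generating K in ≥90% of seeded replicates while AIC tends to
select at least as many components — the expected asymmetry of the two
penalties.

## Two-phase ROI discovery

`roi_discovery` clusters a reference image in two phases:

1. **Intensity binning.**  Masked voxels are split into `n_bins`
   equal-width intensity bins over [min, max] (half-open; maximum closed
   into the last bin; constant images give a single bin).  Voxels within
   a bin have similar uptake by construction.
2. **Spatial clustering.**  Each non-empty bin is clustered on its
   (x, y, z) voxel indices alone with GMM + model selection.  Candidate K
   come from the rule that a cluster should hold between 30 and 1000
   voxels: K ∈ [⌈n/1000⌉, ⌊n/30⌋] for a bin of n voxels, clamped to
   (1, 1) when empty.  The bounds act only through the search range; no
   post-hoc splitting or merging is applied.  For very wide ranges a
   stride > 1 may thin the scan (logged).

The resulting clusters exactly partition the mask (asserted property),
are intensity-homogeneous within one bin width, and deterministic given
the seed (per-bin seeds derive from the map seed and the bin index).
Clustering uses raw voxel indices rather than mm coordinates — grids are
isotropic after spatial normalization, so the two differ by a constant
factor that the mixture absorbs.

## Features and selection

Each subject volume becomes a vector of per-cluster mean and sample SD
(n−1 denominator; SD = 0 for singleton clusters): 2·C features for C
clusters (1000 clusters → 2000 features; the 116-region atlas baseline →
232 features).  Features are ranked by the absolute two-sample
t-statistic on training rows only (an entropy/information-gain ranking on
supervised single-threshold discretizations is available as an
alternative), and the top-m are kept — m = 150 under BIC, 400 under AIC by
default, clipped to the feature count when the map is smaller.  The
voxel-wise baseline runs an uncorrected two-tailed equal-variance t-test
per masked voxel, keeps voxels with p < 0.001, and uses the raw
intensities of the 150 lowest-p voxels as features.

## Evaluation workflow

`evaluation` runs repeated stratified k-fold CV (default 10×10; per
class, fold sizes differ by ≤1; 30+30 subjects → 3 per class per fold and
54 training subjects).  Within each training split:

* the reference image is the mean of the NC volumes (either an external
  NC pool or the training members of the least-impaired class);
* the bin count is selected from a grid by accuracy on one stratified
  80/20 sub-split of the training subjects, identical across bin sizes
  (ties → fewer bins);
* features are ranked and selected on training rows;
* features are standardized by training mean/SD (a package choice — the
  linear SVM is not scale-invariant and cluster means and SDs live on
  different scales);
* the penalty C of the linear SVM is grid-searched
  ({2⁻⁵, 2⁻³, …, 2⁵}) by stratified CV accuracy on the training rows.

Accuracy, sensitivity (true-positive rate on the more-impaired class) and
specificity are aggregated by instance within each repeat and then
averaged over repeats; the AUC is the Mann–Whitney rank statistic over
the pooled (score, truth) pairs of all repeats and folds, with ties
counting one half.  Probability outputs (Platt-scaled) feed the ROC; when
disabled, signed decision values are used (AUC is rank-invariant).

Two pipelines are compared with the corrected resampled paired t-test,
t = mean(d)/√((1/R + n_test/n_train)·var(d)) on R per-run accuracy
differences with R−1 degrees of freedom; the extra n_test/n_train term
accounts for overlapping training sets across CV runs.

Single-case error analysis uses the weighted-Euclidean dissimilarity
ratio ρ = (D_other − D_target)/D_target, where rows are re-weighted by
the classifier weight vector and D_group is the mean distance from the
test case to a group's training rows; larger ρ reads "more similar to the
target (disease) group".

The informative-regions report assigns, per fold, 10..1 points to the ten
clusters whose best-ranked feature comes first (clusters are re-identified
across folds by their voxel-coordinate set), sums points over all repeats
and folds, and attributes the voxels of the overall top-ten clusters to
atlas regions, ranked by voxel share.

## Synthetic phantom

`phantom` generates the test bed: an ellipsoidal "brain" (92% of each
half-dimension) partitioned into contiguous regions by a seeded Voronoi
tessellation of random interior sites, with a constant baseline per
region drawn uniformly from [0.7, 1.3] — the span of normalized FDG
uptake from white matter to metabolically active cortex.  A subject
volume is baseline × (1 − effect) in the affected regions (defaults:
NC 0%, MCI −7%, AD −15%) plus i.i.d. Gaussian noise with SD = 10% of the
local baseline, optionally blurred (blur induces the spatial correlation
that scanner-resolution smoothing produces in real data; off by default
to keep the noise model transparent).  Everything is deterministic given
the spec seed, with distinct noise streams per subject.

What the phantom does *not* emulate: PET physics (attenuation, partial
volume, scanner PSF), anatomical variability across subjects, spatially
varying uptake within a region, and registration error.  Passing the
end-to-end tests therefore shows that the pipeline recovers planted
regional effects under honest noise and cross-validation — not that it
attains any particular accuracy on clinical data.

## Study problem sizes

The bundled studies (`petroi.studies`) run at phantom scale, chosen so
the full workflow is exercised end to end on a small grid:

* phantom: 16×20×16 grid (~1.8k mask voxels), 12 regions, 2 affected
  at −15%, 20 classified subjects per group plus a disjoint 20-scan NC
  reference pool; bin grid {8, 16}; 10×10 CV.
* the reference pool is kept disjoint from the classified subjects.  On a
  piecewise-constant phantom, within-region variation of a reference
  built from classified training subjects is pure noise, so bin
  membership would select on those subjects' own noise and bias their
  features relative to held-out subjects (regression to the mean).  A
  disjoint pool mirrors the clinical protocol, where the NC scans that
  define the reference are external to, e.g., an MCI-vs-AD comparison.
* pipeline EM settings: 1–2 restarts, |ΔL| < 1e-2, ≤50 iterations,
  K-scan stride 2 — the clusterings are consumed as hard partitions, so
  tight likelihood convergence adds nothing at this scale.
* component-recovery study: 20 replicates, K* cycling over {2,…,6},
  separation 8σ, N = 2000, K grid 1..8, 2 restarts.

## Known limitations

* Two-class tasks only; the three diagnostic groups are evaluated
  pairwise.
* The SVM is consumed as a contract (scikit-learn); its solver internals
  and non-linear kernels are out of scope.
* Cluster identity across CV folds is defined by exact voxel-set
  equality; maps that differ between folds contribute separate entries
  to the region tally, which is conservative.
* Empty intensity bins are retained for index stability but skipped in
  clustering; a bin whose every candidate K fails to fit degenerates to
  a single cluster with a logged warning.
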