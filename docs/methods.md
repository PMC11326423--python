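# Methods

`ihirate` automates the visual rating of incomplete hippocampal inversion
(IHI) from spatially normalized grey-matter probability maps.  This note
documents the models and procedures it implements, the choices made where
the design was open, and what the synthetic test bed can and cannot show.

## The rating protocol and its arithmetic

A hemisphere is rated on four ordinal criteria: verticality/roundness of
the hippocampal body (C1), verticality and depth of the collateral sulcus
(C2), medial position of the hippocampus (C3), and fusiform-gyrus sulci
exceeding the subiculum level (C5).  C1–C3 live on a 0–2 scale in steps of
0.5, C5 in steps of 1.  A fifth protocol criterion (subiculum bulging) is
excluded by design: it is nearly constant in the population, unreliable to
rate, and its omission barely affects the composite.  It is not
representable in the package's types, so it cannot creep back in.

The composite IHI score is the plain sum of the four criteria (0–8);
a hemisphere is classified IHI when the composite is ≥ 4.  Continuous
model predictions are snapped to each criterion's grid before composites
or agreement statistics are computed, because human raters can only emit
on-grid values.  Two conventions are fixed here:

* **Tie-breaking.** Exact grid midpoints round up (toward the higher
  score).  This is deterministic and, at the margin, favours detecting an
  inversion over missing one.
* **Order of operations.** Criteria are rounded first, then summed, so
  the composite is always a sum of legal criterion scores.
* **C5 grid.** The protocol's "2-point scale with a step of 1" is read as
  {0, 1, 2}.  The grid is a single constant, so the alternative binary
  reading is a one-line change; the unweighted kappa used for C5 is valid
  under either.

## Preprocessing

Inputs are grey-matter maps already normalized to a template grid;
segmentation and spatial normalization are out of scope.  The hippocampal
region of interest is the half-open voxel box `[24:96, 54:107, 16:49]`
(72 × 53 × 33 voxels) covering both hippocampi and the surrounding sulci.
The bracket notation is interpreted as slice syntax on the normalized
grid; the box is configuration, not code.  Right-hemisphere crops are
mirrored along the left–right axis into a canonical left frame so a
single model per criterion serves both hemispheres; mirroring is an
involution and is tested as such.  Per-crop min–max intensity
normalization is available (grey-matter maps are already near [0, 1], so
this is close to a no-op on real inputs); constant crops map to zero.
Flattening for the linear baseline uses x-fastest (Fortran) order and is
the exact inverse of the reshape.

## Models

One regressor per criterion and hemisphere frame predicts the continuous
criterion score; the composite is never a direct regression target — it
is reconstructed as the sum of rounded per-criterion predictions, which
keeps the score interpretable criterion by criterion.

Three deep families share a train/predict contract and are interchangeable
under one config key:

* **conv5fc3** — five blocks of [3³ conv → batch norm → ReLU → 2³ max
  pool], then three fully connected layers ending in a scalar.
* **resnet3d** — five residual blocks (conv–BN–ReLU–conv–BN plus identity
  shortcut, 1³ projection when channels change) separated by max pooling,
  head FC → ReLU → dropout(0.5) → FC.
* **secnn** — the residual network with a squeeze-and-excite gate per
  block: global average pool per channel, bottleneck MLP (reduction 16 by
  default), sigmoid gate rescaling the channels of the main path.

Channel widths, fully connected widths and the SE reduction are not part
of the architectural contract and live in `ArchitectureSpec`
(defaults 8–128 channels; a reduced preset `ArchitectureSpec.tiny()` with
4–16 channels is used for CPU-scale experiments and tests).  Pooling uses
size-2 windows with floor semantics; an axis that reaches extent 1 stops
shrinking, so the 72 × 53 × 33 ROI maps to 2 × 1 × 1 after five pools.

The layer stack — 3D convolution (stride-1, zero 'same' padding,
im2col + BLAS matmul), batch normalization, max pooling, dropout,
residual and squeeze-excite blocks, Adam — is implemented in NumPy inside
the package (`ihirate.nn`), with hand-written backward passes.  Every
backward pass is verified against central finite differences in the test
suite; input gradients propagate to the voxels, which is what makes
saliency maps a by-product of ordinary backpropagation.

**Training.** Mean squared error, Adam with learning rate 1e-4 and weight
decay 1e-4, batch size 16, at most 50 epochs; the early-stopping
tolerance of 0 means training runs all epochs and the weights from the
epoch with the lowest validation loss are kept (first epoch wins ties).
Labels are the manual criterion scores as given.  Left–right flip
augmentation and IHI oversampling exist behind config flags but are off
by default: for this task they have not been found to help.  All
randomness (shuffling, dropout, initialization) flows from a single seed;
two runs with the same seed produce bitwise-identical training curves.

**Ridge baseline.** Ridge regression on flattened crops with the penalty
chosen by nested cross-validation: 5 outer folds for honest performance
estimation, 6 inner folds for penalty selection within each outer fold,
penalty grid of 13 log-spaced values 1e-3…1e9 (the grid is
configuration).  The final model refits on all data
with the penalty selected by a last 6-fold pass.  Folds are plain
unshuffled K-folds, matching the default behaviour of the standard
KFold splitter.

**Saliency.** Group saliency maps are mean absolute input gradients over
a set of crops, thresholded to retain exactly the 1000 largest voxels
(ties broken by flat voxel index).  For the linear model the gradient is
analytic: |coefficients| reshaped to the ROI.

## Stratified split search

25% of each cohort is isolated as a test set before any modelling; the
remainder is re-split 80/20 into training and validation.  Fractional
sizes floor at each stage — this rule exactly reproduces the published
train/val/test rows for cohorts of 2008, 993 and 400 subjects.  To make
the test set representative, 200 candidate random splits are drawn and
the one minimizing distributional discrepancy across the stratification
variables (all IHI criteria of both hemispheres, age, weight, height,
sex, handedness, imaging centre) is selected; the inner train/validation
split reuses the same selector.  Splitting operates on subjects, never on
single hemispheres, so the two hemispheres of a subject cannot straddle
the test boundary.

Open points resolved here: numeric variables are compared with the
two-sample Kolmogorov–Smirnov statistic between {train ∪ validation} and
test; categorical variables cannot meaningfully use a KS test, so the
total-variation distance between category proportions (same [0, 1] scale)
is used instead; the aggregate across variables is the maximum (worst
variable), with a mean option in config.  Missing covariates are a hard
error by default.  The published row for the fourth cohort (554/185/246
of 985) does not follow the stated fraction rules and is not reproduced;
the package implements the stated rules.

## Agreement statistics and method comparison

* **ICC.** Composite scores are nearly continuous and are evaluated with
  an intraclass correlation computed from the two-way ANOVA mean-squares
  decomposition.  The default variant is ICC(2,1) — two-way random
  effects, single rater, absolute agreement — because the scientific
  question is whether a single automatic rating can replace a single
  manual one, systematic offsets included.  ICC(3,1) (consistency) is a
  switch, and the variant is echoed in every report.  The implementation
  is vectorized over bootstrap replicates and matches both a brute-force
  variance-components oracle and pingouin's `intraclass_corr` to
  near machine precision in the tests.
* **Kappa.** Individual criteria use Cohen's kappa over the *declared*
  criterion grid (so unobserved categories weight correctly):
  quadratically weighted for the ordinal C1–C3, unweighted for C5, whose
  scale is not treated as ordinal.  Kappas are defined only on the grid;
  passing unrounded predictions is an error, not a silent cast.
* **Bootstrap.** 100 subject-level redraws with replacement give the
  bootstrap mean, standard error (replicate standard deviation) and a
  95% percentile confidence interval (a normal-approximation interval is
  a switch).  Replicate index sets are retained.
* **Method comparison.** Two methods are compared by recomputing the
  metric on bitwise-identical bootstrap replicates and differencing, so
  sampling variation cancels; t = mean(d)/SD(d) with n_boot − 1 degrees
  of freedom, two-sided, Bonferroni-corrected over the hypothesis family
  (family size is explicit in config and echoed in output).  Under a
  simulated null this test's type-I error sits at the nominal 5% — the
  calibration is part of the acceptance suite.

## The phantom test bed

Real IHI cohorts are access-restricted, so the package ships a generator
of synthetic "hippocampus phantoms" with known ground truth.  Each
subject has four latent traits in [0, 1] that drive a simple geometry in
the ROI crop: an ellipsoidal body whose in-plane angle rises from
horizontal to vertical with t1 (and grows rounder), a medial wedge-shaped
dark groove whose depth grows with t2 (collateral sulcus), a medial
translation of the body with t3, and a second lateral groove with t5.
Latent t maps to criterion score round(2t) on the criterion's grid, so
the latent → image → score chain is monotone and learnable by
construction; monotonicity is property-tested through intensity probes.

* **Prevalence control.** Each hemisphere's latents come from a
  two-component mixture: a "typical" Beta(1.2, 5) concentrated near 0 and
  an "inverted" Beta(5, 1.5) concentrated near 1, mirroring the bimodal
  typical-vs-IHI framing.  The induced distribution of the composite is
  computed exactly (Beta CDF differences at rounding boundaries,
  convolved across criteria), and the mixture weight is solved in closed
  form to hit the target prevalence in expectation.  Defaults follow the
  published left/right asymmetry: ≈ 20% IHI on the left, ≈ 8% on the
  right.
* **Anatomical nuisance.** Every subject's geometry is shifted and
  rescaled by random per-subject jitter that carries no information about
  the criteria (position SD 0.05 of the crop, log-size SD 0.12 by
  default).  Without it, a well-tuned linear readout of 9000+ voxels can
  decode even the body angle almost perfectly; with it, angle reading
  becomes a genuinely position-invariant — i.e. nonlinear — problem, as
  it is in real anatomy.
* **Cohort effects.** Cohorts differ in size, age structure, Gaussian
  blur, additive noise, multiplicative contrast, rater identity and
  prevalence.  Four presets echo the IMAGEN / QTIM / QTAB / UKBiobank
  structure at one tenth scale.
* **Rater noise.** Each criterion is independently perturbed one grid
  step (direction uniform; forced inward at the scale ends) with
  probability 0.65.  This value is a calibration constant: it places the
  truth-vs-observed composite ICC over 500 subjects inside 0.70–0.85,
  the band reported for expert inter-rater reliability.  No per-criterion
  reliability figures exist to calibrate against, so the probability is
  uniform across criteria.
* **Determinism.** Generation is a pure function of (spec, seed);
  per-subject generators are derived by counter, never global state.

What passing on phantoms does *not* show: the geometry is an ellipsoid
with carved wedges, not anatomy; there is no scanner physics, no
segmentation artefact, no anatomical covariance between criteria, and the
latent→score map is exact by construction.  Phantom results validate the
pipeline's mechanics (learnability, statistics, orchestration), not
clinical performance.

## Experiment orchestration and problem sizes

`run_experiment` reproduces the study design end to end at phantom scale:
generate cohorts, select stratified splits, train each architecture under
each training strategy (single-cohort; three-cohort; all-cohort), predict
on every cohort's untouched test set, and evaluate pooled and per cohort.
Every stage's seed is SHA-derived from (master seed, stage name) so
stages rerun independently; completed checkpoints are detected on disk
and reused, making partial runs resumable.  A manifest records artifacts,
seeds, timings and the config hash.

The recovery experiments in the test suite and acceptance script run at
deliberately reduced problem sizes chosen for a single CPU: 30 × 22 × 14
crops, 400 subjects per cohort (240/60/100 split), reduced-width
networks (`ArchitectureSpec.tiny()`), 15 epochs at learning rate 1e-3
(the small nets are stable at a higher rate than the full-size default),
low image noise, rater noise off (so recovery is measured against
noiseless truth), and anatomical jitter raised to 0.07/0.15 to keep the
angle task honestly nonlinear.  Under these conditions conv5fc3 reaches
held-out composite ICC(2,1) ≈ 0.82–0.90 across seeds, exceeds the ridge
baseline on the angle criterion, and loses accuracy on a low-prevalence
(8%) cohort relative to a 20% one — the qualitative left/right pattern.

## Numerical notes and limitations

* Conv gradients, batch-norm backward in both modes, pooling argmax
  scatter and the SE gate are all finite-difference checked; the ICC and
  kappa kernels match independent oracles to 1e-10.
* Percentile bootstrap intervals may exclude the point estimate on
  pathological data; `ci_lower ≤ ci_upper` is the only ordering asserted.
* Degenerate inputs fail loudly: constant ratings (undefined ICC/kappa),
  off-grid predictions, missing criteria, unattainable prevalence
  targets, out-of-bounds ROIs, non-finite losses.
* The NumPy networks are CPU-oriented; full-width training on the full
  ROI is supported but slow, and no GPU path exists.
* The bootstrap t-test's degrees of freedom (n_boot − 1) and the
  percentile CI are deliberate package choices; both are recorded in
  every report.
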