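# Methods

This note records the models the package implements, the numerical choices
behind them, what the synthetic phantoms do and do not emulate, and the
known limitations.

## Deformation model

All nonlinear deformations are stationary velocity fields (SVFs)
parameterised by cubic B-spline control lattices.  Displacements are stored
in voxel units of the fixed grid; world (mm) conversion happens only at
I/O through the NIfTI affine.  The exponential is computed by scaling and
squaring with 8 steps by default (6 inside registration loops); against a
256-step Runge–Kutta integration of the same field the error is below
0.05 voxel for fields within the safe amplitude bound.  That bound —
max |velocity| ≤ 0.4 × control spacing — is a conservative sufficient
condition for a positive Jacobian determinant of the exponential, and is
asserted in tests rather than assumed.

Two composition conventions coexist deliberately.  Everywhere except the
reconstruction refinement, transforms compose through their exponentiated
displacement fields (`compose`, exact up to interpolation).  Inside the
Bayesian refinement, SVFs combine by velocity addition — the first-order
truncation of the group operation — because that is what makes transform
synchronisation a *linear* problem.  The approximation error grows with
field amplitude; at the ≤2-voxel distortions the phantoms use it is well
below the registration noise.

Bending energy is the sum of squared second spatial differences (including
mixed terms, counted twice), zero for any affine field and quadratic in
the field.  Inside the optimiser the penalty is evaluated on the control
lattice and averaged per control point, so one `reg_weight` value has the
same meaning in 2D and 3D and across grid sizes; the dense-field
`bending_energy` operation keeps the plain (unaveraged) convention.

## Registration

Similarity (block) registration optimises translation, rotation (Euler
angles in 3D) and log-isotropic-scale per block, maximising global NCC of
the assembled blocks against the reference while a tiling term
`mean((Σ soft masks − 1)²)` over the reference foreground punishes overlap
and gaps.  The optimisation is hierarchical (per block group, then per
block) and each level is solved by coordinate descent over groups with a
bounded Powell subproblem (±4 voxels, ±0.12 rad, ±0.12 log-scale per
sweep).  The bound is a trust region: without it a block can run away to a
spurious NCC optimum when its neighbours are still misplaced.  At the
per-block level the first sweep drops the tiling term so a badly jittered
neighbour cannot drag its peers; later sweeps restore it.  The level
objective is recorded and is non-increasing across levels by construction.

Nonlinear registration maximises squared local NCC (Gaussian windows,
coarse-to-fine σ schedule) minus bending energy, by gradient ascent with
backtracking on the exact objective; the similarity gradient uses the
first-order (one-step) approximation of the SVF exponential, which the
line search then validates against the true objective, so monotone
improvement is guaranteed even where the approximation is poor.  The LNCC
gradient keeps the window means inside the convolutions (the exact
adjoint); the approximate form with means pulled outside is measurably
wrong at window scale.  Warping inside registration losses clamps to edge
values rather than zero-filling — constant fill makes the objective
discontinuous at the field of view boundary and stalls the ascent.

Atlas-stage label registration maximises the label log-likelihood under
the warped atlas with a weak Dirichlet prior α = 1e-5 (configurable).  The
data term is a cross-entropy between the subject's *smoothed* one-hot
encoding and equally smoothed atlas channels (σ = 1 voxel): with the same
smoothing on both sides, perfect alignment is exactly the optimum (Gibbs'
inequality), whereas smoothing only the atlas side creates a small
spurious boundary-shrink force.  The ascent direction damps the 1/p weight
to 1/(p + 0.05): the undamped gradient concentrates on a handful of
mismatched voxels and stalls the line search.  The objective itself keeps
the α = 1e-5 convention.

Default control-point spacings: 10 mm for section refinement (the standard
for this kind of data), 4 voxels for the atlas and segmentation stages,
and 5 voxels (= 2.5 mm) with LNCC σ 2.5 mm and bending weight 0.001 for
the registration-based segmentation baseline.

## Reconstruction graph and L1 refinement

For an S-section stack with a reference slice and two stain images per
section, the measurement set is: three inter-modality registrations per
section (each stain to the reference, stain B to stain A; one direction
each) and, per modality, directed neighbour registrations at offsets ±1
and ±2 (4S−6 each).  Total 15S−18.  The latent spanning tree is the
reference-slice chain plus one edge per stain image: 3S−1 edges.  Under a
Laplace noise model the MAP latents minimise Σ w_k‖y_k − P_k x‖₁, solved
as a linear program (HiGHS) independently per control point and component;
edge weights default to 1 and are configurable per registration type (the
appropriate weighting is genuinely unknown).  Cross-stain image pairs are
histogram-matched (monotone quantile mapping) before registration; this
stands in for contrast transfer between modalities and is described as
exactly that — a monotone intensity remap, matching how the phantoms
generate their stains.

Two baselines are provided for comparison experiments: direct per-section
registration (sensitive to any single failed registration) and
neighbour-only chaining anchored at the middle section (smooth but
straightens curvature — the classic banana effect, reproduced on a curved
tube phantom).

## Segmentation model

Intensities are modelled in the log domain, so the multiplicative bias
field becomes additive and its M-step is a responsibility-weighted linear
least-squares problem in the polynomial coefficients (monomials of total
degree ≤ order in [−1,1]-normalised coordinates, no constant term — the
constant is absorbed by the class means).  Components per class default to
1 (configurable); the variance floor is 1e-6 × data variance, with a flag
when it engages.  The E/M iteration is a generalised EM: GMM updates are
exact, the bias update is an exact maximiser given responsibilities, and
the observed-data log-likelihood is asserted non-decreasing (tolerance
1e-8 relative) on every run.  The outer loop alternates EM with the
deformation update (default 5 alternations, or relative joint-objective
change < 1e-5; the recovery experiments converge in 2).  Ties in the
argmax segmentation break toward the lowest label id.  Masking is an
explicit input: voxels outside the mask (or with non-positive intensity)
are excluded and receive the background label with posterior 1.

The default tissue-clustering configuration lists 15 named classes,
mirroring the granularity used for real whole-brain ontologies; phantom
tests use one class per label via `TissueClustering.identity`.

## Phantoms: what they emulate and what they do not

Every generator is a pure function of its arguments (bit-identical outputs
for identical seeds) and returns its ground truth with the data.

* **Geometry** — non-overlapping random ellipsoids (optionally grouped so
  hierarchy siblings are adjacent).  Volumes and overlaps are trivially
  verifiable; nothing emulates cortical folding or thin laminae.
* **Intensities** — per-class Gaussian mixtures plus an optional smooth
  random texture.  The texture matters: registration is unidentifiable on
  piecewise-constant regions, and real tissue always carries texture.  No
  scanner noise model (Rician etc.).
* **Bias** — exp of a unit-variance random low-order polynomial scaled by
  an amplitude; exactly the family the segmentation model fits.
* **Section stacks** — stains are monotone intensity remaps of the
  reference slice, distorted by a rigid-motion velocity field (exact
  rotations via the flow of a linear field) plus a random B-spline SVF.
  Landmark pairs are planted through the true inverse field, so truth
  transforms reproduce them to machine precision.  No folds, tears, or
  staining artefacts — gross registration failures are emulated by
  corrupting measured edges instead.
* **Blocks** — grid cut with slab-coherent ("cut from the same slice")
  plus per-block pose jitter, the error structure the hierarchical
  alignment exploits.  Pre-jitter, block masks partition the foreground
  exactly.
* **Cohorts** — ages uniform, sexes balanced, ICV lognormal
  (ln ICV ~ N(ln 1.45e6, 0.12²)); ROI volume = ICV × (μ(age) + sex offset
  + Laplace(0, b(age))), with μ, b cubic B-splines on the stated control
  ages.  ICV enters multiplicatively and sex additively after division,
  matching the division-then-regression correction order, and the noise is
  exactly the model the trajectory fit assumes — so parameter recovery
  tests whether the estimator works, not whether the model is right for
  real cohorts.

Passing tests on these phantoms therefore demonstrate correctness of the
estimators under their own assumptions and the robustness claims built
into the experiments (outliers, bias, curvature); they do not demonstrate
performance on real histology or MRI.

## Statistics

* Covariate correction fits ICV-divided volumes against an intercept, sex
  (F/M indicator) and optionally age; held-out subjects are corrected with
  training-fold coefficients.  Which covariates to regress is a parameter:
  the division-by-ICV step is fixed, the regression set is chosen per
  analysis (classification uses sex + age, ageing maps use sex).
* LOO-LDA scales training features to unit variance, uses the pooled
  within-class covariance S, and regularises Σ = S + λI with λ = 1, which
  the unit-variance normalisation makes scale-appropriate.  λ = 0 is
  allowed but raises on a singular Σ.
* AUROC is the rank (Mann–Whitney) estimator with ties counted ½.  The ROC
  "elbow" is defined as the Youden J maximiser (sensitivity + specificity),
  ties broken toward higher sensitivity — an explicit convention, since
  operating points are meaningless without one.
* The DeLong test uses the standard structural-component covariance for
  paired AUROCs; identical inputs give z = 0, p = 1 by convention.
* Spearman maps use average-rank tie handling; constant volumes report
  undefined (NaN) rather than 0.  A Benjamini–Hochberg FDR column is
  provided alongside raw p values.
* The Laplace trajectory fit maximises the exact log-likelihood
  Σ −log(2b(aₙ)) − |vₙ−μ(aₙ)|/b(aₙ) by normalised gradient ascent with
  backtracking; θμ is initialised by a least-absolute-deviations spline
  fit (an LP), θb from the mean absolute residual, and the scale curve is
  parameterised through a softplus with floor 1e-6 so b > 0 everywhere.
  The basis is a clamped cubic B-spline with one coefficient per control
  age (the default four evenly spaced control ages give the Bernstein
  basis on [30, 95]); rows are non-negative and sum to one, so positive
  control values guarantee a positive curve.  The reported 95% band is
  μ ± 3b; the exact central coverage of ±3b is 1 − e⁻³ ≈ 95.0%.

## Problem sizes used in the shipped experiments

Recovery experiments run at 32³–36³ for block alignment and atlas
construction (five subjects, three build iterations — the change log
plateaus there), 36×36 sections with S = 6 for the reconstruction graph
(72 measured edges), ~48k voxels for EM recovery, and 64³ for the
end-to-end segmentation.  These sizes were chosen so the full suite
completes in minutes while every ROI relevant to a Dice threshold exceeds
500 voxels; the algorithms contain nothing size-specific.

## Known limitations

* The similarity search is local: block jitter far beyond the trust
  region per sweep (≈ ±4 voxels, ±7°) needs more sweeps or a coarser
  initialisation level.
* First-order SVF composition inside the refinement biases latents for
  large distortions; the LP could be iterated around exponentiated
  compositions but is not.
* The segmentation assumes the atlas and image grids already match;
  resampling between grids is left to I/O.
* No symmetric/inverse-consistent registration energies, no Riemannian
  statistics on diffeomorphisms, no learned components.
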