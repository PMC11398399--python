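# histoatlas

Building a probabilistic anatomical atlas from serially sectioned,
histologically stained tissue requires solving four coupled computational
problems: (1) putting thousands of distorted 2D sections back into a
coherent 3D volume, (2) averaging many labelled volumes into a voxelwise
categorical prior, (3) using that prior to segment new intensity volumes,
and (4) turning the resulting per-subject ROI volumes into population
statistics.  `histoatlas` implements this full computational core in
Python, together with a phantom module that generates every input class
with known ground truth, so each stage is testable end to end on a laptop
— no proprietary or restricted imaging data needed.

It is aimed at researchers in biological image analysis who want a
transparent, classical (non-learned) reference implementation of these
methods to study, extend, or benchmark against.

## Methods at a glance

**3D reconstruction.** Tissue blocks are first aligned to a reference
volume with similarity transforms `x = sR(x₀−c) + c + t`, optimised
jointly with a tiling regulariser `∫(Σ_b m_b(x) − 1)² dx` that punishes
both overlap (Σ>1) and gaps (Σ<1) between warped block masks, in a
coarse-to-fine hierarchy (shared per block group, then per block).
Sections are then refined with B-spline stationary velocity fields (SVFs)
maximising local NCC minus bending energy.  Finally, all pairwise
registrations — `15S−18` for an `S`-section stack with three images per
section — are treated as Laplace-noise measurements of signed sums of the
`3S−1` latent spanning-tree SVFs.  Under first-order SVF composition
(velocity addition) the maximum-likelihood latents solve

```
min_x  Σ_k w_k ‖y_k − P_k x‖₁
```

a linear program decoupled per control point and component, making the
reconstruction robust to grossly failed registrations.

**Atlas construction.** Alternates (i) registering each subject's labels
to the current atlas by maximising `Σ_v log[(p̃_v(l_v)+α)/(1+αL)]` (weak
Dirichlet prior α, bending-energy regularised, diffeomorphic SVF model)
and (ii) averaging the deformed one-hot segmentations, until the max
voxelwise probability change is negligible.

**Bayesian segmentation.** A generative model: labels drawn from the
deformed atlas, grouped into tissue classes, each with a Gaussian mixture
over log-intensities plus an additive polynomial bias field (multiplicative
on raw intensities).  GMM and bias parameters are estimated by EM (monotone
observed-data likelihood); the atlas deformation by quasi-Newton ascent.
A registration-based baseline (control-point spacing 5 voxels, local NCC
σ = 2.5 mm, bending weight 0.001) and Dice evaluation are included.

**Statistics.** ROI volumes are corrected for intracranial volume (by
division) and nuisance covariates (by regression); AD-style classification
uses leave-one-out regularised LDA with the criterion
`L(x̄) = (μ̄₁−μ̄₀)ᵀΣ⁻¹(x̄ − ½(μ̄₁+μ̄₀))`, `Σ = S + λI` (λ = 1) on
unit-variance features, with rank-based AUROC and the paired DeLong test;
ageing maps use Spearman correlation; ageing trajectories are fitted by an
age-dependent Laplace model whose location μ(a) and scale b(a) are cubic
B-splines (default control ages 30, 51.6, 73.3, 95 years), maximised by
gradient ascent, with the 95% band μ ± 3b (ln 20 ≈ 3).

## Worked example

Reconstruct a distorted synthetic stack and compare the Bayesian solution
with naive alternatives:

```python
import numpy as np
from histoatlas import phantom, recon
from histoatlas.core import Volume, LabelVolume

rng = np.random.default_rng(0)
shape = (12, 36, 36)                      # 12 slices of 36x36
vol, lab = np.zeros(shape), np.zeros(shape, np.int32)
y, x = np.mgrid[0:36, 0:36]
for z in range(12):                       # a curved bright tube
    t = z / 11
    cy, cx = 14 + 8 * (2 * t - 1) ** 2, 10 + 16 * t
    m = ((y - cy) / 5) ** 2 + ((x - cx) / 4) ** 2 < 1
    vol[z][m], lab[z][m] = 150, 1
vol += 30 + 12 * rng.standard_normal(shape)

stack = phantom.make_section_stack(Volume(vol), LabelVolume(lab), 6,
                                   {"rigid": 1.0, "bspline": 0.8}, seed=3)
graph = recon.build_registration_graph(stack)     # 72 edges for S=6
recon.run_pairwise_registrations(stack, graph)
latents = recon.refine_bayesian(graph)            # 17 latent tree SVFs
bayes = recon.stain_transforms_from_latents(graph, latents)
m = recon.evaluate_reconstruction(stack, bayes)
print(f"landmark error {m.mean_error_voxels:.2f} ± {m.sd_error_voxels:.2f} vox")
```

On this phantom the run prints

```
landmark error 0.35 ± 0.17 vox
```

i.e. the refined transforms land the planted landmark pairs about a third
of a voxel from their true counterparts, while neighbour-only chaining on
the same registrations leaves roughly a 2-voxel error (the curvature of
the tube is straightened away — the "banana effect") and a single
corrupted direct registration would dominate any per-section solution.

A command-line interface mirrors the library:

```
histoatlas phantom --shape 32 --rois 5 --seed 1 --out work/
histoatlas atlas --subjects subjects.csv --reference ref.nii.gz --out atlas.nii.gz
histoatlas segment --image img.nii.gz --atlas atlas.nii.gz \
    --clustering tissue.yaml --out seg/
histoatlas stats trajectory --cohort cohort.csv --out stats/
```

## Layout

| module | contents |
|---|---|
| `histoatlas.phantom` | seeded generators of labels, intensities, bias, SVFs, section stacks, blocks, cohorts (ground truth retained) |
| `histoatlas.deform` | SVF exponential (scaling & squaring), composition, warping, B-spline fields, bending energy |
| `histoatlas.recon` | block alignment, section registration, registration graph, L1/LP refinement, landmark evaluation |
| `histoatlas.atlas` | probabilistic atlas construction |
| `histoatlas.segment` | EM (GMM + bias), deformation updates, Bayesian segmentation, registration baseline, Dice |
| `histoatlas.stats` | covariate correction, LOO-LDA, ROC/DeLong, Spearman maps, Laplace B-spline trajectories |
| `histoatlas.io` / `histoatlas.cli` | NIfTI/LUT/CSV/YAML I/O and the `histoatlas` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
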