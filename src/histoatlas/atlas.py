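"""Probabilistic atlas construction from labelled volumes.

The atlas is built by alternating two steps until the voxelwise
probabilities stop changing:

1. each subject's label volume is registered to the current atlas with a
   diffeomorphic B-spline SVF model, maximising the log-likelihood of the
   labels under the deformed atlas (a weak Dirichlet prior keeps the logs
   finite) minus a bending-energy penalty;
2. the atlas is re-estimated as the voxelwise average of the subjects'
   one-hot label encodings mapped into atlas space.

Initialisation registers each subject's *intensity* volume to a reference
scan by local NCC and averages the deformed segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import deform, _optim
from .core import LabelVolume, ProbAtlas, Volume

DIRICHLET_ALPHA = 1e-5  # "weak" prior strength on atlas probabilities
ONEHOT_SMOOTH_SIGMA = 1.0  # voxels; makes the label data term differentiable


def onehot(labels: np.ndarray, label_list, smooth_sigma: float = 0.0) -> np.ndarray:
    """One-hot encoding ``grid + (n_labels,)``, optionally smoothed and
    renormalised so voxels still sum to one."""
    labels = np.asarray(labels)
    out = np.stack([(labels == l).astype(float) for l in label_list], axis=-1)
    if smooth_sigma > 0:
        for i in range(out.shape[-1]):
            out[..., i] = ndimage.gaussian_filter(out[..., i], smooth_sigma)
        out /= np.maximum(out.sum(axis=-1, keepdims=True), 1e-12)
    return out


def warp_onehot(oh: np.ndarray, displacement, label_list) -> np.ndarray:
    """Warp one-hot channels linearly; out-of-field voxels become the
    lowest (background) label rather than probability-zero everywhere."""
    labels = list(label_list)
    bg = int(np.argmin(labels))
    return np.stack(
        [
            deform.warp(
                oh[..., i], displacement, mode="linear",
                fill=1.0 if i == bg else 0.0,
            )
            for i in range(oh.shape[-1])
        ],
        axis=-1,
    )


def update_atlas(deformed_onehot_labels, label_list=None, affine=None) -> ProbAtlas:
    """Voxelwise mean of one-hot encodings, renormalised.

    Order-independent: permuting the subject list leaves the result
    bit-identical (pairwise summation over a stacked array).
    """
    vols = list(deformed_onehot_labels)
    if not vols:
        raise ValueError("cannot average an empty list of segmentations")
    stack = np.stack([np.asarray(v, float) for v in vols])
    mean = stack.mean(axis=0)
    mean = np.maximum(mean, 0.0)
    mean /= np.maximum(mean.sum(axis=-1, keepdims=True), 1e-12)
    n_labels = mean.shape[-1]
    labels = np.arange(n_labels) if label_list is None else np.asarray(label_list)
    return ProbAtlas(mean, labels, affine if affine is not None else np.eye(4))


def register_labels_to_atlas(
    labels: LabelVolume | np.ndarray,
    atlas: ProbAtlas,
    cp_spacing: float = 4.0,
    reg_weight: float = 0.01,
    dirichlet_alpha: float = DIRICHLET_ALPHA,
    n_iters: int = 40,
    init_cv: np.ndarray | None = None,
) -> _optim.SVFResult:
    """SVF deforming the atlas onto a subject's labels.

    Maximises ``Σ_v log[(p̃_v(l_v) + α)/(1 + αL)]`` (p̃ the warped atlas,
    α the weak Dirichlet prior, L the label count) minus bending energy.
    Atlas channels are smoothed slightly so one-hot atlases still produce
    gradients.
    """
    lab = labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)
    present = set(int(l) for l in np.unique(lab))
    known = set(int(l) for l in atlas.labels)
    extra = sorted(present - known)
    if extra:
        raise ValueError(f"labels absent from the atlas: {extra}")
    L = len(atlas.labels)
    # both sides carry the same smoothing: the data term is then a
    # cross-entropy Σ q log p maximised exactly when the warped atlas equals
    # the subject's soft encoding, so perfect alignment is a true optimum
    channels = [
        ndimage.gaussian_filter(atlas.probs[..., i], ONEHOT_SMOOTH_SIGMA)
        for i in range(L)
    ]
    q = onehot(lab, atlas.labels, smooth_sigma=ONEHOT_SMOOTH_SIGMA)
    norm = np.log(1.0 + dirichlet_alpha * L)
    nvox = lab.size

    def loss(d):
        val = 0.0
        g = np.zeros(lab.shape + (lab.ndim,))
        for i in range(L):
            w = deform.warp(channels[i], d, mode="linear", boundary="nearest")
            p = np.maximum(w, 0.0) + dirichlet_alpha
            val += float((q[..., i] * np.log(p)).sum())
            # ascent direction damped where p -> alpha: the raw 1/p weight
            # concentrates the whole gradient on a handful of mismatched
            # voxels and stalls the line search
            coef = q[..., i] / (np.maximum(w, 0.0) + 0.05)
            spat = np.stack(np.gradient(w), axis=-1)
            g += coef[..., None] * spat
        return (val / nvox - norm), g / nvox

    return _optim.optimize_svf(
        loss,
        lab.shape,
        cp_spacing,
        reg_weight=reg_weight,
        n_iters=n_iters,
        init_cv=init_cv,
    )


def init_template(
    intensity_volumes,
    label_volumes,
    reference_intensity,
    cp_spacing: float = 4.0,
    lncc_sigma: float = 3.0,
    reg_weight: float = 0.05,
    n_iters: int = 40,
) -> ProbAtlas:
    """Intensity-based initial atlas.

    Each subject is registered to the reference with a local-NCC SVF; the
    deformed one-hot segmentations are averaged and normalised.
    """
    if len(intensity_volumes) != len(label_volumes):
        raise ValueError("need one label volume per intensity volume")
    ref = np.asarray(
        reference_intensity.data
        if isinstance(reference_intensity, Volume)
        else reference_intensity,
        float,
    )
    all_labels = sorted(
        set(
            int(l)
            for lv in label_volumes
            for l in np.unique(lv.data if isinstance(lv, LabelVolume) else lv)
        )
    )
    deformed = []
    affine = np.eye(4)
    for iv, lv in zip(intensity_volumes, label_volumes):
        img = np.asarray(iv.data if isinstance(iv, Volume) else iv, float)
        lab = lv.data if isinstance(lv, LabelVolume) else np.asarray(lv)
        if img.shape != lab.shape:
            raise ValueError(
                f"intensity {img.shape} and label {lab.shape} grids differ"
            )
        if isinstance(lv, LabelVolume):
            affine = lv.affine
        # moving = subject, fixed = reference: exp(v) maps subject into the
        # reference frame, and the same displacement resamples its labels
        res = _optim.optimize_svf(
            _optim.make_lncc_loss(img, ref, lncc_sigma),
            ref.shape,
            cp_spacing,
            reg_weight=reg_weight,
            n_iters=n_iters,
        )
        oh = onehot(lab, all_labels, smooth_sigma=0.0)
        deformed.append(warp_onehot(oh, res.displacement, all_labels))
    return update_atlas(deformed, all_labels, affine)


@dataclass
class AtlasBuildResult:
    atlas: ProbAtlas
    change_log: list = field(default_factory=list)
    registration_objectives: list = field(default_factory=list)
    min_jacobian: float = np.inf


def build_atlas(
    subjects,
    reference=None,
    max_iters: int = 10,
    tol: float = 1e-3,
    flip_spec=None,
    cp_spacing: float = 4.0,
    reg_weight: float = 0.01,
    n_reg_iters: int = 30,
) -> AtlasBuildResult:
    """Alternate label registration and averaging until convergence.

    ``subjects`` is a list of ``(intensity, labels)`` pairs (intensity may
    be None once a reference-free start is acceptable: the initial atlas is
    then the plain average of the unregistered one-hot labels).  Subjects
    listed in ``flip_spec`` (by index) are mirrored along the first axis
    before entering, the mechanism used to pool both hemispheres.
    Convergence: max voxelwise absolute probability change below ``tol``.
    """
    if not subjects:
        raise ValueError("need at least one subject")
    pairs = []
    for k, sub in enumerate(subjects):
        iv, lv = sub if isinstance(sub, (tuple, list)) else (None, sub)
        lab = lv.data if isinstance(lv, LabelVolume) else np.asarray(lv)
        img = None if iv is None else np.asarray(
            iv.data if isinstance(iv, Volume) else iv, float
        )
        if flip_spec and k in set(flip_spec):
            lab = lab[::-1].copy()
            img = None if img is None else img[::-1].copy()
        pairs.append((img, lab))

    all_labels = sorted(set(int(l) for _, lab in pairs for l in np.unique(lab)))
    if reference is not None and all(img is not None for img, _ in pairs):
        atlas = init_template(
            [Volume(img) for img, _ in pairs],
            [LabelVolume(lab.astype(np.int32)) for _, lab in pairs],
            reference,
            cp_spacing=cp_spacing,
        )
    else:
        atlas = update_atlas(
            [onehot(lab, all_labels) for _, lab in pairs], all_labels
        )

    change_log = []
    reg_objectives = []
    min_jac = np.inf
    warm = [None] * len(pairs)
    for _ in range(max_iters):
        deformed = []
        for k, (_, lab) in enumerate(pairs):
            res = register_labels_to_atlas(
                lab,
                atlas,
                cp_spacing=cp_spacing,
                reg_weight=reg_weight,
                n_iters=n_reg_iters,
                init_cv=warm[k],
            )
            if res.history[-1] < res.history[0] - 1e-9:
                raise RuntimeError("registration objective decreased")
            reg_objectives.append(res.history)
            warm[k] = res.control_values
            jac = deform.jacobian_determinant(res.displacement)
            min_jac = min(min_jac, float(jac.min()))
            inv = deform.exp_svf(-res.velocity)
            oh = onehot(lab, all_labels, smooth_sigma=0.0)
            deformed.append(warp_onehot(oh, inv, all_labels))
        new_atlas = update_atlas(deformed, all_labels, atlas.affine)
        change = float(np.abs(new_atlas.probs - atlas.probs).max())
        change_log.append(change)
        atlas = new_atlas
        atlas.check_normalised(1e-6)
        if change < tol:
            break
    return AtlasBuildResult(atlas, change_log, reg_objectives, min_jac)
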