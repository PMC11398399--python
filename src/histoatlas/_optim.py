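"""Shared numerical machinery for B-spline SVF registration.

The registration energy is ``similarity − reg_weight · bending(control
lattice)`` maximised by gradient ascent with backtracking.  The similarity
gradient with respect to the velocity is taken at first order in the SVF
(the exact objective is still evaluated through the full exponential), a
standard approximation that keeps iterations cheap while the line search
guarantees monotone improvement of the true objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import deform

EPS = 1e-8
# variance regulariser for local NCC windows; small enough that a perfectly
# registered textured pair scores 1 to ~1e-7, large enough to keep the
# gradient finite on near-flat windows of noisy images
LNCC_EPS = 1e-11


# ---------------------------------------------------------------------------
# local normalised cross-correlation

def lncc_maps(fixed: np.ndarray, moving: np.ndarray, sigma: float):
    """Per-voxel squared local NCC and the quantities needed for its gradient."""
    G = lambda a: ndimage.gaussian_filter(a, sigma, mode="nearest")
    mu_f = G(fixed)
    mu_m = G(moving)
    var_f = np.maximum(G(fixed * fixed) - mu_f ** 2, 0.0) + LNCC_EPS
    var_m = np.maximum(G(moving * moving) - mu_m ** 2, 0.0) + LNCC_EPS
    cov = G(fixed * moving) - mu_f * mu_m
    cc = cov ** 2 / (var_f * var_m)
    return cc, (mu_f, mu_m, var_f, var_m, cov, G)


def lncc(fixed: np.ndarray, moving: np.ndarray, sigma: float) -> float:
    """Mean squared local NCC; 1 for a perfectly correlated pair."""
    cc, _ = lncc_maps(fixed, moving, sigma)
    return float(cc.mean())


def lncc_and_grad(fixed: np.ndarray, moving: np.ndarray, sigma: float):
    """Mean LNCC and its voxelwise gradient with respect to ``moving``."""
    cc, (mu_f, mu_m, var_f, var_m, cov, G) = lncc_maps(fixed, moving, sigma)
    r = cov / (var_f * var_m)
    q = cov ** 2 / (var_f * var_m ** 2)
    # exact adjoint: the window means stay inside the convolutions
    grad = 2.0 * (
        fixed * G(r) - G(r * mu_f) - moving * G(q) + G(q * mu_m)
    ) / fixed.size
    return float(cc.mean()), grad


def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Global normalised cross-correlation (Pearson) of two images."""
    if mask is not None:
        a = a[mask]
        b = b[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom < EPS:
        raise ValueError("NCC undefined: an image is constant on the support")
    return float((a * b).sum() / denom)


# ---------------------------------------------------------------------------
# bending penalty on the control lattice (value + analytic gradient)

def _axis_slices(ndim, axis, sl):
    out = [slice(None)] * ndim
    out[axis] = sl
    return tuple(out)


def bending_cv(cv: np.ndarray) -> float:
    """Second-difference bending penalty of a control lattice (per component)."""
    naxes = cv.ndim - 1
    e = 0.0
    for a in range(naxes):
        d2 = np.diff(cv, n=2, axis=a)
        e += float((d2 ** 2).sum())
        for b in range(a + 1, naxes):
            dab = np.diff(np.diff(cv, axis=a), axis=b)
            e += 2.0 * float((dab ** 2).sum())
    return e


def _adj_diff(t: np.ndarray, axis: int, out: np.ndarray) -> None:
    nd = out.ndim
    out[_axis_slices(nd, axis, slice(1, None))] += t
    out[_axis_slices(nd, axis, slice(None, -1))] -= t


def _adj_diff2(t: np.ndarray, axis: int, out: np.ndarray) -> None:
    nd = out.ndim
    out[_axis_slices(nd, axis, slice(2, None))] += t
    out[_axis_slices(nd, axis, slice(1, -1))] -= 2.0 * t
    out[_axis_slices(nd, axis, slice(None, -2))] += t


def bending_cv_grad(cv: np.ndarray) -> np.ndarray:
    grad = np.zeros_like(cv)
    naxes = cv.ndim - 1
    for a in range(naxes):
        _adj_diff2(2.0 * np.diff(cv, n=2, axis=a), a, grad)
        for b in range(a + 1, naxes):
            t = np.diff(np.diff(cv, axis=a), axis=b)
            g1 = np.zeros(t.shape[:b] + (t.shape[b] + 1,) + t.shape[b + 1 :])
            _adj_diff(4.0 * t, b, g1)
            _adj_diff(g1, a, grad)
    return grad


# ---------------------------------------------------------------------------
# generic SVF optimiser

@dataclass
class SVFResult:
    control_values: np.ndarray
    velocity: np.ndarray
    displacement: np.ndarray
    objective: float
    history: list = field(default_factory=list)


def optimize_svf(
    loss,
    shape,
    cp_spacing,
    reg_weight: float = 0.05,
    n_iters: int = 60,
    step0: float = 2.0,
    n_exp: int = 6,
    init_cv: np.ndarray | None = None,
    tol: float = 1e-7,
) -> SVFResult:
    """Maximise ``loss(displacement) − reg_weight · bending(controls)``.

    ``loss`` maps a dense displacement field to ``(value, grad)`` where
    ``grad`` is the voxelwise gradient with respect to the displacement.
    The bending penalty is averaged over the control lattice so
    ``reg_weight`` keeps one meaning across grid sizes and dimensions.
    Returns the best iterate found; the objective history is monotone
    non-decreasing by construction of the backtracking line search.
    """
    shape = tuple(shape)
    ndim = len(shape)
    sp = np.broadcast_to(np.asarray(cp_spacing, dtype=float), (ndim,))
    cshape = tuple(deform.n_controls(L, s) for L, s in zip(shape, sp)) + (ndim,)
    cv = np.zeros(cshape) if init_cv is None else init_cv.copy()
    ncv = float(np.prod(cshape))

    def evaluate(c):
        v = deform.bspline_field(c, sp, shape)
        d = deform.exp_svf(v, n_steps=n_exp)
        val, g = loss(d)
        return val - reg_weight * bending_cv(c) / ncv, v, d, g

    obj, v, d, g_dense = evaluate(cv)
    history = [obj]
    step = step0
    for _ in range(n_iters):
        g_cv = deform.bspline_adjoint(g_dense, sp, n_components=ndim)
        g_cv -= reg_weight * bending_cv_grad(cv) / ncv
        gnorm = np.abs(g_cv).max()
        if gnorm < 1e-12:
            break
        direction = g_cv / gnorm  # max-norm normalised: step is in voxels
        improved = False
        s = step
        for _ in range(12):
            cand = cv + s * direction
            cand_obj, cand_v, cand_d, cand_g = evaluate(cand)
            if cand_obj > obj + tol * max(1.0, abs(obj)):
                cv, obj, v, d, g_dense = cand, cand_obj, cand_v, cand_d, cand_g
                step = min(s * 1.5, 4.0)
                improved = True
                break
            s *= 0.5
        history.append(obj)
        if not improved:
            break
    return SVFResult(cv, v, d, obj, history)


def make_lncc_loss(moving: np.ndarray, fixed: np.ndarray, sigma: float):
    """LNCC similarity between warped ``moving`` and ``fixed`` as an SVF loss."""
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    for name, im in (("moving", moving), ("fixed", fixed)):
        if np.ptp(im) < EPS:
            raise ValueError(f"constant {name} image: local NCC undefined")

    def loss(d):
        w = deform.warp(moving, d, mode="linear", boundary="nearest")
        val, g_im = lncc_and_grad(fixed, w, sigma)
        spat = np.stack(np.gradient(w), axis=-1)
        return val, g_im[..., None] * spat

    return loss
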