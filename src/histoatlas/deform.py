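"""Deformation engine: SVF exponentials, composition, warping, B-spline
fields and bending energy.

A stationary velocity field (SVF) ``v`` parameterises a diffeomorphism
through its flow; the time-1 flow is computed by scaling and squaring.
Displacements map a fixed-grid voxel ``x`` to the sampling position
``x + d(x)`` in the moving image, in voxel units.

Two composition conventions coexist in the package, on purpose:

* everywhere except the reconstruction refinement, transforms are composed
  on their *exponentiated* displacement fields with :func:`compose`;
* inside the reconstruction's Bayesian refinement, SVFs are combined by
  *addition of velocities* (the first-order Baker–Campbell–Hausdorff
  truncation), which is what turns transform synchronisation into a linear
  problem.  That code path documents the approximation explicitly.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import as_field_array

__all__ = [
    "identity_grid",
    "exp_svf",
    "compose",
    "warp",
    "bspline_kernel",
    "bspline_field",
    "bspline_adjoint",
    "bending_energy",
    "invert",
    "jacobian_determinant",
]


def identity_grid(shape) -> np.ndarray:
    """Voxel-centre coordinates, shape ``grid + (ndim,)``."""
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    return np.stack(grids, axis=-1)


def _interp_field(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Linearly interpolate a vector field at fractional voxel coordinates.

    Out-of-grid positions clamp to the edge value, which keeps the
    exponential stable near boundaries.
    """
    pts = np.moveaxis(coords, -1, 0)
    out = np.empty_like(coords)
    for c in range(field.shape[-1]):
        out[..., c] = ndimage.map_coordinates(
            field[..., c], pts, order=1, mode="nearest"
        )
    return out


def compose(outer, inner) -> np.ndarray:
    """Displacement of (outer ∘ inner): apply ``inner`` first.

    ``result(x) = inner(x) + outer(x + inner(x))``.
    """
    outer = as_field_array(outer)
    inner = as_field_array(inner)
    if outer.shape != inner.shape:
        raise ValueError(
            f"grid mismatch: outer {outer.shape} vs inner {inner.shape}"
        )
    coords = identity_grid(inner.shape[:-1]) + inner
    return inner + _interp_field(outer, coords)


def exp_svf(v, n_steps: int = 8) -> np.ndarray:
    """Exponentiate an SVF by scaling and squaring.

    The field is scaled by ``2**-n_steps`` (small enough that a single Euler
    step is accurate) and the resulting displacement is composed with itself
    ``n_steps`` times.
    """
    v = as_field_array(v)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity field contains non-finite entries")
    d = v / (2.0 ** n_steps)
    for _ in range(n_steps):
        d = compose(d, d)
    return d


def invert(v, n_steps: int = 8) -> np.ndarray:
    """Inverse deformation of an SVF: ``exp(-v)``."""
    return exp_svf(-as_field_array(v), n_steps=n_steps)


def warp(volume: np.ndarray, d, mode: str = "linear", fill=0.0,
         boundary: str = "constant") -> np.ndarray:
    """Resample ``volume`` through a displacement field.

    Modes: ``linear`` for intensities, ``nearest`` for labels,
    ``onehot_linear`` for labels via linearly-warped one-hot channels with an
    argmax (lowest label wins ties).  Out-of-field voxels take ``fill`` when
    ``boundary="constant"``; ``boundary="nearest"`` clamps to the edge value
    instead (the smooth choice registration objectives need).
    """
    d = as_field_array(d)
    if d.shape[:-1] != volume.shape:
        raise ValueError(
            f"grid mismatch: field {d.shape[:-1]} vs volume {volume.shape}"
        )
    coords = np.moveaxis(identity_grid(volume.shape) + d, -1, 0)
    if mode == "linear":
        return ndimage.map_coordinates(
            volume.astype(float), coords, order=1, mode=boundary, cval=fill
        )
    if mode == "nearest":
        return ndimage.map_coordinates(
            volume, coords, order=0, mode=boundary, cval=fill
        )
    if mode == "onehot_linear":
        labels = np.unique(volume)
        stack = np.empty(volume.shape + (len(labels),))
        for i, lab in enumerate(labels):
            stack[..., i] = ndimage.map_coordinates(
                (volume == lab).astype(float),
                coords,
                order=1,
                mode="constant",
                cval=1.0 if lab == fill else 0.0,
            )
        return labels[np.argmax(stack, axis=-1)].astype(volume.dtype)
    raise ValueError(f"unknown warp mode: {mode!r}")


def bspline_kernel(t: np.ndarray) -> np.ndarray:
    """The cubic B-spline kernel β₃, support (−2, 2), partition of unity."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    m1 = t < 1
    out[m1] = 2.0 / 3.0 - t[m1] ** 2 + 0.5 * t[m1] ** 3
    m2 = (t >= 1) & (t < 2)
    out[m2] = (2.0 - t[m2]) ** 3 / 6.0
    return out


def n_controls(length: int, spacing: float) -> int:
    """Control points needed for full cubic support on ``length`` voxels."""
    return int(np.ceil((length - 1) / spacing)) + 3


def _basis_matrix(length: int, spacing: float) -> np.ndarray:
    """1D dense-grid × control-grid cubic B-spline basis.

    Control point k sits at voxel position ``(k − 1) · spacing`` so one
    control lies outside each end of the grid.
    """
    k = np.arange(n_controls(length, spacing))
    i = np.arange(length, dtype=float)
    return bspline_kernel(i[:, None] / spacing - (k[None, :] - 1))


def bspline_field(control_values: np.ndarray, spacing, target_shape) -> np.ndarray:
    """Evaluate a separable cubic B-spline field on a dense grid.

    ``control_values`` has one axis per grid axis plus, optionally, a
    trailing component axis; its per-axis sizes must match
    :func:`n_controls` for the target grid.  Constant control values yield a
    constant dense field (partition of unity).
    """
    target_shape = tuple(target_shape)
    ndim = len(target_shape)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (ndim,))
    if np.any(spacing < 2):
        raise ValueError("control spacing must be >= 2 voxels")
    cv = np.asarray(control_values, dtype=float)
    has_comp = cv.ndim == ndim + 1
    if not (has_comp or cv.ndim == ndim):
        raise ValueError("control_values rank does not match target grid")
    for ax in range(ndim):
        need = n_controls(target_shape[ax], spacing[ax])
        if cv.shape[ax] != need:
            raise ValueError(
                f"axis {ax}: expected {need} control points for length "
                f"{target_shape[ax]} at spacing {spacing[ax]}, got {cv.shape[ax]}"
            )
    out = cv
    for ax in range(ndim):
        B = _basis_matrix(target_shape[ax], spacing[ax])
        out = np.moveaxis(np.tensordot(B, out, axes=(1, ax)), 0, ax)
    return out


def bspline_adjoint(dense: np.ndarray, spacing, n_components: int | None = None) -> np.ndarray:
    """Adjoint of :func:`bspline_field`: project a dense (gradient) field
    back onto the control grid.  Used by registration optimisers."""
    dense = np.asarray(dense, dtype=float)
    ndim = dense.ndim - (0 if n_components is None else 1)
    target_shape = dense.shape[:ndim]
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (ndim,))
    out = dense
    for ax in range(ndim):
        B = _basis_matrix(target_shape[ax], spacing[ax])
        out = np.moveaxis(np.tensordot(B.T, out, axes=(1, ax)), 0, ax)
    return out


def bending_energy(field) -> float:
    """Sum of squared second spatial derivatives (finite differences).

    Zero for any affine field; quadratic in the field; invariant to adding
    an affine component.
    """
    f = as_field_array(field)
    # trailing axis is a component axis when its size matches a vector field
    # on the remaining axes; otherwise the array is a scalar field
    if f.ndim >= 2 and f.shape[-1] == f.ndim - 1:
        naxes = f.ndim - 1
        arr = f
    else:
        naxes = f.ndim
        arr = f[..., None]
    energy = 0.0
    for c in range(arr.shape[-1]):
        g = arr[..., c]
        firsts = [np.gradient(g, axis=a) for a in range(naxes)]
        for a in range(naxes):
            for b in range(a, naxes):
                second = np.gradient(firsts[a], axis=b)
                w = 1.0 if a == b else 2.0
                energy += w * float((second ** 2).sum())
    return energy


def jacobian_determinant(d) -> np.ndarray:
    """Per-voxel determinant of ∂(x + d(x))/∂x by central differences."""
    d = as_field_array(d)
    ndim = d.ndim - 1
    J = np.empty(d.shape[:-1] + (ndim, ndim))
    for c in range(ndim):
        for a in range(ndim):
            J[..., c, a] = np.gradient(d[..., c], axis=a)
        J[..., c, c] += 1.0
    return np.linalg.det(J)
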