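"""Similarity-transform parameterisation shared by the phantom and the
reconstruction stages.

A similarity transform is parameterised as ``[t..., angles..., log_scale]``
acting about a centre: ``x = s·R·(x₀ − c) + c + t``.  2D uses one angle,
3D uses Euler angles with ``R = Rx · Ry · Rz``.
"""

from __future__ import annotations

import numpy as np


def rotation_matrix(angles, ndim: int) -> np.ndarray:
    if ndim == 2:
        c, s = np.cos(angles[0]), np.sin(angles[0])
        return np.array([[c, -s], [s, c]])
    rx, ry, rz = angles
    Rx = np.array([[1, 0, 0], [0, np.cos(rx), -np.sin(rx)], [0, np.sin(rx), np.cos(rx)]])
    Ry = np.array([[np.cos(ry), 0, np.sin(ry)], [0, 1, 0], [-np.sin(ry), 0, np.cos(ry)]])
    Rz = np.array([[np.cos(rz), -np.sin(rz), 0], [np.sin(rz), np.cos(rz), 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def n_pose_params(ndim: int) -> int:
    return ndim + (1 if ndim == 2 else 3) + 1


def params_to_similarity(params: np.ndarray, center: np.ndarray):
    """Matrix pair (A, b) of the similarity ``x = sR(x₀ − c) + c + t``."""
    center = np.asarray(center, float)
    ndim = len(center)
    nang = 1 if ndim == 2 else 3
    t = np.asarray(params[:ndim], float)
    R = rotation_matrix(params[ndim : ndim + nang], ndim)
    s = np.exp(params[-1])
    A = s * R
    return A, center + t - A @ center


def similarity_to_params(A: np.ndarray, b: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Inverse of :func:`params_to_similarity` (Euler xyz convention in 3D)."""
    center = np.asarray(center, float)
    ndim = A.shape[0]
    s = np.linalg.det(A) ** (1.0 / ndim)
    R = A / s
    if ndim == 2:
        angles = [np.arctan2(R[1, 0], R[0, 0])]
    else:
        ry = np.arcsin(np.clip(R[0, 2], -1.0, 1.0))
        rx = np.arctan2(-R[1, 2], R[2, 2])
        rz = np.arctan2(-R[0, 1], R[0, 0])
        angles = [rx, ry, rz]
    t = b - center + A @ center
    return np.concatenate([t, angles, [np.log(s)]])


def compose_similarity(outer, inner):
    """(A, b) of outer ∘ inner (inner applied first)."""
    Ao, bo = outer
    Ai, bi = inner
    return Ao @ Ai, Ao @ bi + bo
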