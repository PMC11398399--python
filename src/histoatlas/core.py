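"""Shared lightweight containers for volumes, fields, and atlases.

Conventions used throughout the package:

* Voxel indices are 0-based; sampling is at voxel centres.
* World coordinates are ``affine @ (i, j, k, 1)`` (RAS assumed on write).
* Displacement and velocity fields are stored in **voxel units of the fixed
  grid**, as arrays of shape ``grid_shape + (ndim,)``.  Conversion to world
  (mm) space happens only at I/O time through the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


def _default_affine(ndim: int = 3) -> np.ndarray:
    return np.eye(4)


@dataclass
class Volume:
    """An intensity volume (2D or 3D) with a world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))[: self.data.ndim]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class LabelVolume(Volume):
    """Integer ROI map.  Label 0 is background."""

    def __post_init__(self):
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError("label volume must have an integer dtype")

    @property
    def labels(self) -> np.ndarray:
        return np.unique(self.data)


@dataclass
class ProbAtlas:
    """Per-voxel categorical distribution over labels.

    ``probs`` has shape ``grid_shape + (n_labels,)``; ``labels`` gives the
    label id carried by each channel.  Every voxel's probabilities sum to 1.
    """

    probs: np.ndarray
    labels: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.probs.shape[-1] != len(self.labels):
            raise ValueError("channel count does not match label list")

    @property
    def grid_shape(self):
        return self.probs.shape[:-1]

    def check_normalised(self, tol: float = 1e-6) -> None:
        s = self.probs.sum(axis=-1)
        err = float(np.abs(s - 1.0).max())
        if err > tol:
            raise ValueError(f"atlas not normalised: max |sum-1| = {err:.3g}")

    def argmax_labels(self) -> np.ndarray:
        # ties break to the lowest channel index == lowest label id when the
        # label list is sorted (it always is for atlases built here)
        return self.labels[np.argmax(self.probs, axis=-1)]


@dataclass
class VelocityField:
    """Stationary velocity field (SVF): ``data`` shape grid + (ndim,)."""

    data: np.ndarray

    def __post_init__(self):
        if self.data.shape[-1] != self.data.ndim - 1:
            raise ValueError("last axis must hold one component per grid axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("velocity field contains non-finite entries")

    @property
    def ndim(self) -> int:
        return self.data.ndim - 1

    @property
    def grid_shape(self):
        return self.data.shape[:-1]


@dataclass
class DeformationField:
    """Dense displacement field in voxel units of the fixed grid."""

    data: np.ndarray

    def __post_init__(self):
        if self.data.shape[-1] != self.data.ndim - 1:
            raise ValueError("last axis must hold one component per grid axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("deformation field contains non-finite entries")

    @property
    def ndim(self) -> int:
        return self.data.ndim - 1

    @property
    def grid_shape(self):
        return self.data.shape[:-1]


def as_field_array(f) -> np.ndarray:
    """Accept a VelocityField/DeformationField or a bare array."""
    if isinstance(f, (VelocityField, DeformationField)):
        return f.data
    return np.asarray(f, dtype=float)
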