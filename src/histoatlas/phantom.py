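"""Seeded generators of every synthetic input the pipeline consumes.

Each generator is a pure function of its arguments (same seed, same bits)
and returns its ground truth next to the data, so recovery tests compare
against stored truth instead of re-deriving it.  The geometry is deliberately
simple — ellipsoidal ROIs placed by rejection sampling — because their
volumes and overlaps are trivially verifiable; none of this emulates real
cortical folding or histological texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from . import deform, stats
from .core import LabelVolume, Volume
from .segment import TissueClustering, GMMParams, polynomial_basis
from .transforms import (
    compose_similarity,
    params_to_similarity,
    similarity_to_params,
)

SAFE_SVF_FRACTION = 0.4  # max |velocity| <= 0.4 x control spacing keeps exp diffeomorphic


# ---------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple
    voxel_size: tuple = (0.5, 0.5, 0.5)
    n_rois: int = 5
    hierarchy: tuple | None = None  # tuple of tuples of label ids
    seed: int = 0

    def __post_init__(self):
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("all grid dimensions must be >= 8")
        if self.n_rois < 1:
            raise ValueError("need at least one foreground ROI")

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        vs = list(self.voxel_size) + [1.0] * 3
        for i in range(3):
            A[i, i] = vs[i]
        return A


@dataclass
class ClassIntensityModel:
    """Per tissue class mixture parameters on the raw intensity scale."""

    gmm: GMMParams

    @classmethod
    def from_means(cls, means, sds) -> "ClassIntensityModel":
        return cls(
            GMMParams(
                weights=[np.array([1.0]) for _ in means],
                means=[np.array([m], float) for m in means],
                variances=[np.array([max(s ** 2, 1e-12)], float) for s in sds],
            )
        )


@dataclass
class TrajectorySpec:
    """Ground-truth location/scale B-spline curves per ROI."""

    knot_ages: np.ndarray
    theta_mu: Mapping[str, np.ndarray]
    theta_b: Mapping[str, np.ndarray]
    sex_effect: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.knot_ages = np.asarray(self.knot_ages, float)
        for roi in self.theta_mu:
            tm = np.asarray(self.theta_mu[roi], float)
            tb = np.asarray(self.theta_b[roi], float)
            if len(tm) != len(self.knot_ages) or len(tb) != len(self.knot_ages):
                raise ValueError(
                    f"{roi}: control values must match the {len(self.knot_ages)} knots"
                )
            if np.any(tb <= 0):
                raise ValueError(f"{roi}: scale control values must be positive")

    def mu(self, roi, ages):
        return stats.trajectory_basis(ages, self.knot_ages) @ np.asarray(
            self.theta_mu[roi], float
        )

    def b(self, roi, ages):
        return stats.trajectory_basis(ages, self.knot_ages) @ np.asarray(
            self.theta_b[roi], float
        )


# ---------------------------------------------------------------------------
# label geometry

def _ellipsoid_mask(shape, center, axes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return q <= 1.0


def make_label_phantom(spec: PhantomSpec) -> LabelVolume:
    """Ellipsoidal ROI phantom: labels 1..n_rois on background 0.

    ROIs are placed by rejection sampling without overlap.  If a hierarchy
    is given, each group's children are clustered inside a shared parent
    territory so sibling labels end up adjacent.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    vol = np.zeros(shape, dtype=np.int32)
    min_dim = min(shape)
    max_ax = max(min_dim / 5.0, 2.5)
    min_ax = 2.0

    groups = spec.hierarchy
    if groups is None:
        groups = tuple((l,) for l in range(1, spec.n_rois + 1))
    territory_centers = {}
    for gi, g in enumerate(groups):
        territory_centers[gi] = rng.uniform(
            0.3 * np.asarray(shape), 0.7 * np.asarray(shape)
        )

    for gi, group in enumerate(groups):
        for lab in group:
            placed = False
            for attempt in range(400):
                spread = 0.15 * min_dim if spec.hierarchy is not None else 0.5 * min_dim
                center = territory_centers[gi] + rng.normal(0, spread, len(shape))
                center = np.clip(center, max_ax + 1, np.asarray(shape) - max_ax - 2)
                axes = rng.uniform(min_ax, max_ax, len(shape))
                m = _ellipsoid_mask(shape, center, axes)
                if m.any() and not (vol[m] != 0).any():
                    vol[m] = lab
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place ROI {lab} without overlap after 400 attempts: "
                    f"grid {shape} is too small for {spec.n_rois} ROIs"
                )
    return LabelVolume(vol, affine=spec.affine)


# ---------------------------------------------------------------------------
# intensities, bias, SVFs

def sample_intensity(
    labels: LabelVolume,
    model: ClassIntensityModel,
    clustering: TissueClustering,
    seed: int = 0,
    texture_sd: float = 0.0,
    texture_sigma: float = 1.5,
) -> Volume:
    """Draw each voxel from its tissue class's Gaussian mixture.

    ``texture_sd`` optionally adds a smooth random texture so every region
    carries registerable signal (set 0 for the pure mixture draw).
    """
    rng = np.random.default_rng(seed)
    lab = labels.data
    clustering.check_covers(np.unique(lab))
    out = np.zeros(lab.shape, dtype=float)
    for l in np.unique(lab):
        c = clustering.class_of(l)
        w = np.asarray(model.gmm.weights[c], float)
        m = np.asarray(model.gmm.means[c], float)
        s2 = np.asarray(model.gmm.variances[c], float)
        sel = lab == l
        n = int(sel.sum())
        comp = rng.choice(len(w), size=n, p=w / w.sum())
        out[sel] = rng.normal(m[comp], np.sqrt(s2[comp]))
    if texture_sd > 0:
        tex = ndimage.gaussian_filter(rng.normal(size=lab.shape), texture_sigma)
        tex /= max(tex.std(), 1e-12)
        out = out + texture_sd * tex
    if not np.all(np.isfinite(out)):
        raise RuntimeError("sampled intensities contain non-finite values")
    return Volume(out, affine=labels.affine)


def sample_bias(grid_shape, basis_order: int = 2, amplitude: float = 0.1, seed: int = 0):
    """Smooth strictly-positive multiplicative bias: exp of a random
    low-order polynomial with unit-variance log-field scaled by ``amplitude``."""
    if amplitude < 0:
        raise ValueError("bias amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    basis = polynomial_basis(grid_shape, basis_order)
    if basis.shape[1] == 0 or amplitude == 0:
        return np.ones(tuple(grid_shape))
    logf = (basis @ rng.normal(size=basis.shape[1])).reshape(tuple(grid_shape))
    sd = logf.std()
    if sd > 0:
        logf = logf / sd * amplitude
    return np.exp(logf)


def sample_svf(grid_shape, control_spacing: float = 8.0, amplitude: float = 1.0, seed: int = 0):
    """Smooth random B-spline SVF with max |velocity| equal to ``amplitude``.

    Amplitudes up to ``0.4 × control_spacing`` are guaranteed safe (positive
    Jacobian of the exponential).
    """
    if control_spacing < 2:
        raise ValueError("control spacing must be >= 2 voxels")
    rng = np.random.default_rng(seed)
    shape = tuple(grid_shape)
    ndim = len(shape)
    cshape = tuple(deform.n_controls(s, control_spacing) for s in shape) + (ndim,)
    cv = rng.normal(size=cshape)
    v = deform.bspline_field(cv, control_spacing, shape)
    vmax = np.sqrt((v ** 2).sum(axis=-1)).max()
    if amplitude == 0 or vmax == 0:
        return np.zeros_like(v)
    return v * (amplitude / vmax)


# ---------------------------------------------------------------------------
# section stacks

STAIN_REMAPS = {
    # monotone intensity remaps standing in for the two histological stains
    "stain_a": lambda x: x ** 0.7,
    "stain_b": lambda x: 0.2 + 0.8 * x ** 1.5,
}


@dataclass
class SectionStack:
    """Ordered sections with three modalities and retained ground truth.

    ``images[modality][s]`` is the 2D image of section ``s``; modalities are
    ``reference`` (the undistorted resampled slice) and two stains.
    ``true_svf[(modality, s)]`` is the SVF whose exponential registers the
    stain section back to its reference slice.  ``landmarks[s]`` maps
    reference-frame points through each stain's ground-truth transform.
    """

    images: dict
    true_svf: dict
    landmarks: list
    n_sections: int

    def __post_init__(self):
        if self.n_sections < 3:
            raise ValueError("a stack needs at least 3 sections")


def make_section_stack(
    volume: Volume,
    labels: LabelVolume,
    n_sections: int,
    distortion: Mapping[str, float] | None = None,
    seed: int = 0,
    n_landmarks: int = 12,
) -> SectionStack:
    """Slice a volume into an ordered stack of distorted stained sections.

    ``distortion`` keys: ``rigid`` (voxels of translation / comparable
    rotation at the section edge) and ``bspline`` (max voxels of smooth
    nonlinear velocity).  Zero distortion makes each stain an exact
    deterministic intensity remap of its reference slice.
    """
    distortion = dict(distortion or {})
    rigid_sd = float(distortion.get("rigid", 0.0))
    bsp_sd = float(distortion.get("bspline", 0.0))
    rng = np.random.default_rng(seed)
    data = np.asarray(volume.data, float)
    if n_sections > data.shape[0]:
        raise ValueError(
            f"requested {n_sections} sections but volume has {data.shape[0]} slices"
        )
    start = (data.shape[0] - n_sections) // 2
    lo, hi = data.min(), data.max()
    norm = lambda im: (im - lo) / max(hi - lo, 1e-12)

    shape2 = data.shape[1:]
    images = {"reference": [], "stain_a": [], "stain_b": []}
    true_svf = {}
    landmarks = []
    for s in range(n_sections):
        sl = norm(data[start + s])
        images["reference"].append(sl)
        fg = np.argwhere(labels.data[start + s] > 0)
        if len(fg):
            pick = fg[rng.choice(len(fg), size=min(n_landmarks, len(fg)), replace=False)]
        else:
            pick = np.empty((0, 2))
        lm = {"reference": pick.astype(float)}
        for stain, remap in STAIN_REMAPS.items():
            base = remap(sl)
            v = np.zeros(shape2 + (2,))
            if rigid_sd > 0:
                c = (np.asarray(shape2, float) - 1) / 2
                t = rng.normal(0, rigid_sd, 2)
                theta = rng.normal(0, rigid_sd / max(shape2) * 2)
                gy, gx = np.meshgrid(
                    np.arange(shape2[0], dtype=float),
                    np.arange(shape2[1], dtype=float),
                    indexing="ij",
                )
                v[..., 0] += t[0] - theta * (gx - c[1])
                v[..., 1] += t[1] + theta * (gy - c[0])
            if bsp_sd > 0:
                v += sample_svf(
                    shape2, control_spacing=8, amplitude=bsp_sd,
                    seed=int(rng.integers(2 ** 31)),
                )
            img = deform.warp(base, deform.exp_svf(v), mode="linear")
            images[stain].append(img)
            true_svf[(stain, s)] = -v  # registers the stain back to the reference
            if len(pick):
                inv = deform.exp_svf(-v)
                disp = np.stack(
                    [
                        ndimage.map_coordinates(inv[..., c], pick.T.astype(float), order=1)
                        for c in range(2)
                    ],
                    axis=-1,
                )
                lm[stain] = pick.astype(float) + disp
            else:
                lm[stain] = pick.astype(float)
        landmarks.append(lm)
    return SectionStack(images, true_svf, landmarks, n_sections)


# ---------------------------------------------------------------------------
# blocks

@dataclass
class Block:
    image: np.ndarray
    mask: np.ndarray
    origin: np.ndarray  # voxel offset of the block box in the reference grid
    pose: np.ndarray  # similarity params [t..., angles..., log_scale]
    true_pose: np.ndarray
    group: int


@dataclass
class BlockSet:
    blocks: list
    reference_shape: tuple


def pose_identity(ndim: int) -> np.ndarray:
    nang = 1 if ndim == 2 else 3
    return np.zeros(ndim + nang + 1)


def _sample_pose(rng, jit: Mapping[str, float], ndim: int) -> np.ndarray:
    nang = 1 if ndim == 2 else 3
    p = pose_identity(ndim)
    p[:ndim] = rng.normal(0, jit["trans"], ndim)
    p[ndim : ndim + nang] = np.deg2rad(rng.normal(0, jit["rot_deg"], nang))
    p[-1] = rng.normal(0, jit["log_scale"])
    return p


def _normalize_jitter(j) -> dict:
    if np.isscalar(j):
        return {"trans": float(j), "rot_deg": 0.0, "log_scale": 0.0}
    return {"trans": 0.0, "rot_deg": 0.0, "log_scale": 0.0, **dict(j)}


def make_blocks(
    volume: Volume,
    block_grid: Sequence[int],
    pose_jitter: Mapping[str, float] | float = 0.0,
    seed: int = 0,
    group_jitter: Mapping[str, float] | float = 0.0,
) -> BlockSet:
    """Cut a volume into a grid of blocks with jittered similarity poses.

    Blocks are grouped by their slab along the first axis, mirroring blocks
    cut from a common slice.  ``group_jitter`` perturbs each slab coherently
    (one similarity about the slab centre shared by its blocks) and
    ``pose_jitter`` adds an independent perturbation per block — the error
    structure the hierarchical alignment exploits.  Ground-truth poses
    (identity: the cutting position) are retained; pre-jitter, block masks
    partition the volume's foreground exactly.
    """
    data = np.asarray(volume.data, float)
    if not np.any(data != 0):
        raise ValueError("cannot block an empty volume")
    ndim = data.ndim
    jit = _normalize_jitter(pose_jitter)
    gjit = _normalize_jitter(group_jitter)
    rng = np.random.default_rng(seed)
    splits = [np.array_split(np.arange(s), g) for s, g in zip(data.shape, block_grid)]
    fg = data != 0

    group_deltas = {}
    for gi in range(len(splits[0])):
        rows = splits[0][gi]
        center = np.array(
            [(rows[0] + rows[-1]) / 2.0] + [(s - 1) / 2.0 for s in data.shape[1:]]
        )
        group_deltas[gi] = params_to_similarity(_sample_pose(rng, gjit, ndim), center)

    blocks = []
    for idx in np.ndindex(*[len(s) for s in splits]):
        sl = tuple(
            slice(splits[a][i][0], splits[a][i][-1] + 1) for a, i in enumerate(idx)
        )
        img = data[sl]
        msk = fg[sl]
        if not msk.any():
            continue
        origin = np.array([splits[a][i][0] for a, i in enumerate(idx)], float)
        cb = (np.asarray(img.shape, float) - 1) / 2
        center_world = origin + cb
        own = params_to_similarity(_sample_pose(rng, jit, ndim), center_world)
        net_A, net_b = compose_similarity(group_deltas[idx[0]], own)
        # re-express the world->world similarity as local params about the
        # block centre (the convention block poses use everywhere)
        local_b = net_A @ origin + net_b - origin
        pose = similarity_to_params(net_A, local_b, cb)
        blocks.append(
            Block(
                image=img.copy(),
                mask=msk.copy(),
                origin=origin,
                pose=pose,
                true_pose=pose_identity(ndim),
                group=idx[0],
            )
        )
    return BlockSet(blocks, data.shape)


# ---------------------------------------------------------------------------
# cohorts

def default_trajectories(
    roi_names: Sequence[str], seed: int = 0, knot_ages=stats.DEFAULT_KNOT_AGES
) -> TrajectorySpec:
    """Plausible declining normalised-volume curves with mild heteroscedasticity.

    Control values are on the volume/ICV scale (a subcortical ROI occupies
    roughly 0.1–0.5% of ICV) and decline by 15–35% over the adult age range.
    """
    rng = np.random.default_rng(seed)
    tm, tb, sx = {}, {}, {}
    for roi in roi_names:
        base = rng.uniform(1e-3, 5e-3)
        drop = base * rng.uniform(0.15, 0.35)
        ctrl = base - drop * np.linspace(0, 1, len(knot_ages)) ** rng.uniform(1.0, 2.0)
        tm[roi] = ctrl
        tb[roi] = np.full(len(knot_ages), base * rng.uniform(0.05, 0.12))
        sx[roi] = base * rng.uniform(-0.03, 0.03)
    return TrajectorySpec(np.asarray(knot_ages, float), tm, tb, sx)


def make_cohort(
    n_subjects: int,
    age_range: tuple = (30.0, 95.0),
    trajectories: TrajectorySpec | None = None,
    seed: int = 0,
    icv_log_mean: float = np.log(1.45e6),
    icv_log_sd: float = 0.12,
) -> stats.CohortTable:
    """Synthetic cohort drawn from the exact model the statistics fit.

    Per ROI: ``volume = ICV · (μ(age) + sex_offset·[male] + Laplace(0, b(age)))``
    with ages uniform, balanced sexes, lognormal ICV.  The ground-truth
    trajectory spec is attached as ``table.truth``.
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    if trajectories is None:
        trajectories = default_trajectories(["roi1", "roi2"], seed=seed)
    rng = np.random.default_rng(seed)
    rois = list(trajectories.theta_mu)
    import pandas as pd

    ages = rng.uniform(age_range[0], age_range[1], n_subjects)
    sexes = np.array(["F", "M"] * (n_subjects // 2 + 1))[:n_subjects]
    sexes = sexes[rng.permutation(n_subjects)] if n_subjects else sexes
    icv = np.exp(rng.normal(icv_log_mean, icv_log_sd, n_subjects))
    cols = {
        "subject_id": [f"sub-{i:04d}" for i in range(n_subjects)],
        "age_years": ages,
        "sex": sexes,
        "icv_mm3": icv,
    }
    male = (sexes == "M").astype(float)
    for roi in rois:
        mu = trajectories.mu(roi, ages) if n_subjects else np.array([])
        b = trajectories.b(roi, ages) if n_subjects else np.array([])
        off = trajectories.sex_effect.get(roi, 0.0)
        noise = rng.laplace(0.0, b) if n_subjects else np.array([])
        cols[f"{roi}_mm3"] = icv * (mu + off * male + noise)
    table = stats.CohortTable(pd.DataFrame(cols))
    table.truth = trajectories
    return table
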