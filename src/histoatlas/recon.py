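"""3D reconstruction of a blocked, distorted section stack.

Three stages mirror the physical workflow:

1. **Joint block alignment** — every tissue block is registered to the
   reference volume with a similarity transform (rotation, translation,
   isotropic scaling), jointly across blocks, with a differentiable
   regulariser that punishes overlap between blocks and gaps between them.
   Optimisation is hierarchical: early levels share one transform per block
   group, later levels free each block.
2. **Per-section nonlinear refinement** — B-spline SVF registration of each
   stained section with a local NCC similarity.
3. **Bayesian spanning-tree refinement** — all pairwise registrations
   (15S−18 for an S-section stack) are treated as noisy L1 (Laplace)
   measurements of signed sums of the 3S−1 latent spanning-tree SVFs.
   Because SVF composition is linearised to velocity addition here (and only
   here), maximum-likelihood inference is a linear program, solved
   independently per control point and component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import ndimage, optimize

from . import deform, _optim
from .phantom import Block, BlockSet, SectionStack
from .transforms import params_to_similarity, similarity_to_params

MODALITIES = ("reference", "stain_a", "stain_b")


def block_pose_matrix(block: Block, params: np.ndarray | None = None):
    """Matrix form of a block's similarity pose (local voxel → reference)."""
    p = block.pose if params is None else params
    cb = (np.asarray(block.image.shape, float) - 1) / 2
    A, b = params_to_similarity(p, cb)
    return A, b + block.origin


def warp_block(arr: np.ndarray, A: np.ndarray, b: np.ndarray, out_shape, order=1):
    """Resample a block array into the reference grid under ``x = A u + b``."""
    Ainv = np.linalg.inv(A)
    return ndimage.affine_transform(
        np.asarray(arr, float),
        Ainv,
        offset=-Ainv @ b,
        output_shape=tuple(out_shape),
        order=order,
        mode="constant",
        cval=0.0,
    )


def similarity_errors(A_est, b_est, A_true, b_true, center):
    """Translation (voxels at the block centre), rotation (deg), scale errors."""
    ndim = A_est.shape[0]
    d = (A_est @ center + b_est) - (A_true @ center + b_true)
    s_est = np.linalg.det(A_est) ** (1.0 / ndim)
    s_true = np.linalg.det(A_true) ** (1.0 / ndim)
    Rrel = (A_est / s_est) @ np.linalg.inv(A_true / s_true)
    cosang = np.clip((np.trace(Rrel) - (ndim - 2)) / 2.0, -1.0, 1.0)
    return float(np.linalg.norm(d)), float(np.degrees(np.arccos(cosang))), float(
        s_est / s_true
    )


# ---------------------------------------------------------------------------
# overlap / gap regulariser

def overlap_gap_penalty(
    blocks: BlockSet, poses, reference_foreground: np.ndarray
) -> float:
    """``mean((Σ soft masks − 1)²)`` over the reference foreground.

    Zero exactly when the warped block masks tile the foreground with
    neither overlap (Σ>1) nor gap (Σ<1); smooth in the pose parameters.
    """
    if not blocks.blocks:
        return 0.0
    fg = np.asarray(reference_foreground, bool)
    total = np.zeros(blocks.reference_shape)
    for blk, (A, b) in zip(blocks.blocks, poses):
        total += warp_block(blk.mask.astype(float), A, b, blocks.reference_shape)
    return float(((total[fg] - 1.0) ** 2).mean())


# ---------------------------------------------------------------------------
# joint hierarchical block registration

@dataclass
class BlockAlignment:
    poses: list  # (A, b) per block
    objective_per_level: list = field(default_factory=list)


def _assemble(blocks: BlockSet, poses):
    img = np.zeros(blocks.reference_shape)
    msk = np.zeros(blocks.reference_shape)
    for blk, (A, b) in zip(blocks.blocks, poses):
        img += warp_block(blk.image * blk.mask, A, b, blocks.reference_shape)
        msk += warp_block(blk.mask.astype(float), A, b, blocks.reference_shape)
    return img, msk


def register_blocks_joint(
    blocks: BlockSet,
    reference: np.ndarray,
    hierarchy_schedule=None,
    penalty_weight: float = 10.0,
    n_sweeps: int = 2,
    smooth_sigma: float = 0.0,
) -> BlockAlignment:
    """Hierarchical joint similarity registration of blocks to the reference.

    ``hierarchy_schedule`` is a list of per-level group assignments (one
    group id per block), coarse to fine; the default shares parameters per
    block group first and then frees every block.  Levels are solved by
    coordinate descent over groups (each group's delta transform optimised
    with the others frozen), each level initialising the next, so the joint
    objective is non-increasing across levels.  Images are pre-smoothed for
    a better-behaved similarity landscape.
    """
    ref = ndimage.gaussian_filter(np.asarray(reference, float), smooth_sigma)
    fg = np.asarray(reference, float) != 0
    ndim = ref.ndim
    nang = 1 if ndim == 2 else 3
    npar = ndim + nang + 1
    if hierarchy_schedule is None:
        hierarchy_schedule = [
            [blk.group for blk in blocks.blocks],
            list(range(len(blocks.blocks))),
        ]
    smoothed = [
        ndimage.gaussian_filter(blk.image * blk.mask, smooth_sigma)
        for blk in blocks.blocks
    ]

    poses = [block_pose_matrix(blk) for blk in blocks.blocks]

    def render(i, pose):
        A, b = pose
        im = warp_block(smoothed[i], A, b, blocks.reference_shape)
        mk = warp_block(
            blocks.blocks[i].mask.astype(float), A, b, blocks.reference_shape
        )
        return im, mk

    rendered = [render(i, p) for i, p in enumerate(poses)]
    total_img = np.sum([r[0] for r in rendered], axis=0)
    total_msk = np.sum([r[1] for r in rendered], axis=0)
    if not ((total_msk > 0.5) & fg).any():
        warnings.warn(
            "blocks do not overlap the reference foreground; returning the "
            "initial poses unchanged"
        )
        return BlockAlignment(poses, [])

    def objective(img, msk, pw=penalty_weight):
        support = (msk > 0.5) & fg
        if support.sum() < 8:
            return 1e6
        try:
            sim = _optim.ncc(img, ref, support)
        except ValueError:
            return 1e6
        penalty = float(((msk[fg] - 1.0) ** 2).mean())
        return -sim + pw * penalty

    history = []
    for groups in hierarchy_schedule:
        uniq = sorted(set(groups))
        members = {g: [i for i, gg in enumerate(groups) if gg == g] for g in uniq}
        independent_level = all(len(m) == 1 for m in members.values())
        for sweep in range(n_sweeps):
            # at the per-block level the first sweep decouples the blocks
            # (similarity only) so a badly jittered neighbour cannot drag its
            # peers via the tiling term; shared levels keep the full penalty
            pw = 0.0 if (sweep == 0 and independent_level) else penalty_weight
            for g in uniq:
                idx = members[g]
                other_img = total_img - np.sum([rendered[i][0] for i in idx], axis=0)
                other_msk = total_msk - np.sum([rendered[i][1] for i in idx], axis=0)
                cb_world = [
                    poses[i][0] @ ((np.asarray(blocks.blocks[i].image.shape) - 1) / 2)
                    + poses[i][1]
                    for i in idx
                ]
                center = np.mean(cb_world, axis=0)

                def fun(x):
                    dA, db = params_to_similarity(x, center)
                    img = other_img.copy()
                    msk = other_msk.copy()
                    for i in idx:
                        A, b = poses[i]
                        im, mk = render(i, (dA @ A, dA @ b + db))
                        img += im
                        msk += mk
                    return objective(img, msk, pw)

                x0 = np.zeros(npar)
                f0 = fun(x0)
                # trust region per sweep: a block may move a few voxels and
                # degrees at a time, never run off to a spurious NCC optimum
                bnds = (
                    [(-4.0, 4.0)] * ndim
                    + [(-0.12, 0.12)] * nang
                    + [(-0.12, 0.12)]
                )
                res = optimize.minimize(
                    fun, x0, method="Powell", bounds=bnds,
                    options={"maxiter": 4, "xtol": 1e-3, "ftol": 1e-7},
                )
                best = res.x if res.fun <= f0 else x0
                dA, db = params_to_similarity(best, center)
                for i in idx:
                    A, b = poses[i]
                    poses[i] = (dA @ A, dA @ b + db)
                    rendered[i] = render(i, poses[i])
                total_img = other_img + np.sum([rendered[i][0] for i in idx], axis=0)
                total_msk = other_msk + np.sum([rendered[i][1] for i in idx], axis=0)
        history.append(objective(total_img, total_msk))
    return BlockAlignment(poses, history)


# ---------------------------------------------------------------------------
# per-section nonlinear registration

def register_section_nonlinear(
    moving_image: np.ndarray,
    fixed_image: np.ndarray,
    control_spacing_mm: float = 10.0,
    lncc_sigma_mm: float = 2.0,
    voxel_size_mm: float = 1.0,
    reg_weight: float = 0.05,
    n_iters: int = 80,
    init_cv: np.ndarray | None = None,
) -> _optim.SVFResult:
    """B-spline SVF registration maximising local NCC − bending energy.

    Runs a coarse-to-fine LNCC window schedule; the returned SVF satisfies
    ``warp(moving, exp(v)) ≈ fixed``.
    """
    sp = max(control_spacing_mm / voxel_size_mm, 2.0)
    sigma = max(lncc_sigma_mm / voxel_size_mm, 1.0)
    cv = init_cv
    res = None
    for s in (2.5 * sigma, sigma):
        res = _optim.optimize_svf(
            _optim.make_lncc_loss(np.asarray(moving_image, float),
                                  np.asarray(fixed_image, float), s),
            np.asarray(fixed_image).shape,
            sp,
            reg_weight=reg_weight,
            n_iters=n_iters,
            init_cv=cv,
        )
        cv = res.control_values
    return res


def _match_histogram(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Monotone quantile mapping of ``moving`` onto ``fixed``'s intensities."""
    q = np.linspace(0, 1, 256)
    src = np.quantile(moving, q)
    dst = np.quantile(fixed, q)
    return np.interp(moving, src, dst)


# ---------------------------------------------------------------------------
# registration graph

@dataclass
class Edge:
    source: tuple  # (modality, section)
    target: tuple
    kind: str  # 'inter' or 'intra'
    svf: np.ndarray | None = None


@dataclass
class RegistrationGraph:
    """Measured pairwise registrations plus the latent spanning tree.

    ``path_matrix[k, e]`` ∈ {−1, 0, +1} expresses measurement k as the
    signed sum of latent tree edges along the path from its source to its
    target (velocity addition — the first-order SVF composition used by the
    refinement only).
    """

    n_sections: int
    nodes: list
    measured: list  # list[Edge]
    latent: list  # list[(source, target)]
    path_matrix: np.ndarray

    @property
    def n_measured(self) -> int:
        return len(self.measured)

    @property
    def n_latent(self) -> int:
        return len(self.latent)


def build_registration_graph(stack_or_S) -> RegistrationGraph:
    """Enumerate the 15S−18 measurements and 3S−1 latent tree edges.

    Inter-modality registrations (stain_a→reference, stain_b→reference,
    stain_b→stain_a per section) are single-direction; intra-modality
    neighbour registrations at offsets ±1 and ±2 are computed in both
    directions — the only convention consistent with the 15S−18 count.
    """
    S = stack_or_S.n_sections if isinstance(stack_or_S, SectionStack) else int(stack_or_S)
    if S < 3:
        raise ValueError("graph construction needs at least 3 sections")
    nodes = [(m, s) for m in MODALITIES for s in range(S)]
    measured: list[Edge] = []
    for s in range(S):
        measured.append(Edge(("stain_a", s), ("reference", s), "inter"))
        measured.append(Edge(("stain_b", s), ("reference", s), "inter"))
        measured.append(Edge(("stain_b", s), ("stain_a", s), "inter"))
    for m in MODALITIES:
        for off in (1, 2):
            for s in range(S - off):
                measured.append(Edge((m, s), (m, s + off), "intra"))
                measured.append(Edge((m, s + off), (m, s), "intra"))
    latent = [(("reference", s), ("reference", s + 1)) for s in range(S - 1)]
    latent += [(("stain_a", s), ("reference", s)) for s in range(S)]
    latent += [(("stain_b", s), ("reference", s)) for s in range(S)]

    tree = nx.Graph()
    tree.add_nodes_from(nodes)
    eidx = {}
    for i, (a, b) in enumerate(latent):
        tree.add_edge(a, b, index=i)
        eidx[frozenset((a, b))] = (i, a, b)
    P = np.zeros((len(measured), len(latent)))
    for k, e in enumerate(measured):
        path = nx.shortest_path(tree, e.source, e.target)
        for a, b in zip(path[:-1], path[1:]):
            i, src, _ = eidx[frozenset((a, b))]
            P[k, i] = 1.0 if src == a else -1.0
    assert len(measured) == 15 * S - 18
    assert len(latent) == 3 * S - 1
    return RegistrationGraph(S, nodes, measured, latent, P)


def run_pairwise_registrations(
    stack: SectionStack,
    graph: RegistrationGraph,
    control_spacing: float = 8.0,
    lncc_sigma: float = 2.0,
    n_iters: int = 60,
) -> RegistrationGraph:
    """Compute the SVF measurement of every graph edge.

    Cross-modality pairs are histogram-matched (monotone quantile remap)
    before the local-NCC registration, standing in for learned contrast
    transfer.  Measurements are stored as B-spline control velocities on a
    shared lattice.
    """
    for e in graph.measured:
        mov = stack.images[e.source[0]][e.source[1]]
        fix = stack.images[e.target[0]][e.target[1]]
        if e.kind == "inter":
            mov = _match_histogram(mov, fix)
        try:
            res = register_section_nonlinear(
                mov,
                fix,
                control_spacing_mm=control_spacing,
                lncc_sigma_mm=lncc_sigma,
                voxel_size_mm=1.0,
                n_iters=n_iters,
            )
        except Exception as err:
            raise RuntimeError(
                f"registration failed for edge {e.source}->{e.target}: {err}"
            ) from err
        e.svf = res.control_values
    return graph


# ---------------------------------------------------------------------------
# Bayesian (L1 / linear-program) refinement

def refine_bayesian(
    graph: RegistrationGraph, weights_by_type: dict | None = None
) -> np.ndarray:
    """Latent tree SVFs minimising ``Σ_k w_k ‖y_k − P_k x‖₁``.

    Laplace measurement noise makes the MAP problem an L1 fit, solved as a
    linear program with slack variables; the problem decouples per control
    point and per vector component, so each LP is tiny.  Returns an array of
    shape ``(n_latent,) + measurement_shape``.
    """
    P = graph.path_matrix
    if np.linalg.matrix_rank(P) < graph.n_latent:
        raise ValueError("path matrix is rank deficient; tree not identifiable")
    if any(e.svf is None for e in graph.measured):
        raise ValueError("all measurements must be populated before refinement")
    w = np.array(
        [
            (weights_by_type or {}).get(e.kind, 1.0)
            for e in graph.measured
        ]
    )
    Y = np.stack([np.asarray(e.svf, float) for e in graph.measured])
    K = Y.shape[0]
    flat = Y.reshape(K, -1)
    E = graph.n_latent
    c = np.concatenate([np.zeros(E), w])
    A_ub = np.block([[P, -np.eye(K)], [-P, -np.eye(K)]])
    bounds = [(None, None)] * E + [(0, None)] * K
    X = np.empty((E, flat.shape[1]))
    for j in range(flat.shape[1]):
        y = flat[:, j]
        if not np.any(y):
            X[:, j] = 0.0
            continue
        res = optimize.linprog(
            c,
            A_ub=A_ub,
            b_ub=np.concatenate([y, -y]),
            bounds=bounds,
            method="highs",
        )
        if not res.success:
            raise RuntimeError(
                f"LP refinement infeasible at component {j}: {res.message}"
            )
        X[:, j] = res.x[:E]
    return X.reshape((E,) + Y.shape[1:])


def refine_least_squares(graph: RegistrationGraph, weights_by_type=None) -> np.ndarray:
    """L2 baseline on the same measurement system (for robustness contrasts)."""
    P = graph.path_matrix
    w = np.sqrt(
        np.array([(weights_by_type or {}).get(e.kind, 1.0) for e in graph.measured])
    )
    Y = np.stack([np.asarray(e.svf, float) for e in graph.measured])
    flat = Y.reshape(Y.shape[0], -1)
    X, *_ = np.linalg.lstsq(P * w[:, None], flat * w[:, None], rcond=None)
    return X.reshape((graph.n_latent,) + Y.shape[1:])


def l1_objective(graph: RegistrationGraph, latents: np.ndarray, weights_by_type=None):
    w = np.array([(weights_by_type or {}).get(e.kind, 1.0) for e in graph.measured])
    Y = np.stack([np.asarray(e.svf, float) for e in graph.measured]).reshape(
        len(graph.measured), -1
    )
    R = Y - graph.path_matrix @ latents.reshape(graph.n_latent, -1)
    return float((w[:, None] * np.abs(R)).sum())


def latent_index(graph: RegistrationGraph, source, target) -> int:
    for i, (a, b) in enumerate(graph.latent):
        if (a, b) == (source, target):
            return i
    raise KeyError(f"no latent edge {source}->{target}")


def stain_transforms_from_latents(
    graph: RegistrationGraph, latents: np.ndarray
) -> dict:
    """Per stain section, the latent SVF registering it to its reference slice."""
    out = {}
    for m in ("stain_a", "stain_b"):
        for s in range(graph.n_sections):
            i = latent_index(graph, (m, s), ("reference", s))
            out[(m, s)] = latents[i]
    return out


def independent_transforms(graph: RegistrationGraph) -> dict:
    """Direct stain→reference measurements, one registration per section."""
    out = {}
    for e in graph.measured:
        if e.kind == "inter" and e.target[0] == "reference":
            out[e.source] = np.asarray(e.svf, float)
    return out


def chained_transforms(graph: RegistrationGraph, anchor: int | None = None) -> dict:
    """Neighbour-only chaining: each stain section reaches the reference
    through its stain's offset-1 chain and a single anchor registration.

    This is the strategy that produces the "banana effect": smooth stacks
    whose curvature has been straightened away.
    """
    S = graph.n_sections
    anchor = S // 2 if anchor is None else anchor
    emap = {(e.source, e.target): np.asarray(e.svf, float) for e in graph.measured}
    out = {}
    for m in ("stain_a", "stain_b"):
        direct = emap[((m, anchor), ("reference", anchor))]
        for s in range(S):
            v = np.zeros_like(direct)
            step = 1 if s < anchor else -1
            for t in range(s, anchor, step):
                v = v + emap[((m, t), (m, t + step))]
            out[(m, s)] = v + direct
    return out


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class ReconMetrics:
    mean_error_voxels: float
    sd_error_voxels: float
    mean_error_mm: float
    smoothness: float
    per_landmark_voxels: np.ndarray


def evaluate_reconstruction(
    stack: SectionStack,
    transforms: dict,
    control_spacing: float = 8.0,
    voxel_size_mm: float = 1.0,
) -> ReconMetrics:
    """Landmark-pair error of estimated stain→reference transforms.

    ``transforms[(stain, s)]`` holds B-spline control velocities (or a dense
    SVF).  For a reference-frame landmark p with true stain-frame partner q,
    the error is ``|p + exp(v)(p) − q|`` — how far the estimated transform
    lands from the planted counterpart.  Also reports a cross-section
    smoothness score (second differences of transforms along the stack).
    """
    shape2 = stack.images["reference"][0].shape
    errs = []
    for (m, s), v in transforms.items():
        lm = stack.landmarks[s]
        p = lm["reference"]
        if len(p) == 0:
            continue
        q = lm[m]
        vv = np.asarray(v, float)
        if vv.shape[:-1] != shape2:
            vv = deform.bspline_field(vv, control_spacing, shape2)
        d = deform.exp_svf(vv)
        disp = np.stack(
            [ndimage.map_coordinates(d[..., c], p.T, order=1) for c in range(2)],
            axis=-1,
        )
        errs.append(np.linalg.norm(p + disp - q, axis=1))
    if not errs:
        raise ValueError("no landmark pairs available for evaluation")
    errs = np.concatenate(errs)
    smooth = 0.0
    for m in ("stain_a", "stain_b"):
        vs = [np.asarray(transforms[(m, s)], float) for s in range(stack.n_sections)
              if (m, s) in transforms]
        for a, b, c in zip(vs[:-2], vs[1:-1], vs[2:]):
            smooth += float(np.abs(a - 2 * b + c).mean())
    return ReconMetrics(
        float(errs.mean()),
        float(errs.std()),
        float(errs.mean() * voxel_size_mm),
        smooth,
        errs,
    )
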