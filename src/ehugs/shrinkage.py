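"""Groupwise registration by iterative shrinkage of the hierarchical graph.

Each outer iteration: (1) pairwise distances on the current deformed
images, (2) affinity-propagation clustering, (3) hierarchical graph
build, (4) velocity estimation on every graph edge, giving the energy

    F(t) = sum_ij e_ij ||v_ij(t)||^2,

then (5) a low-level pass shrinking each subgroup star and (6) a
high-level pass in which the representatives move toward the global
center and carry their whole subgroup along.  Every node i moves along
the mean of its incident edge velocities,

    vhat_i = (1/N_i) sum_j e_ij v_ij,

for a time step bounded by

    dt = min( 1 / max_i ||vhat_i|| ,
              sum_i N_i ||vhat_i||^2 / sum_i (N_i + 1) ||vhat_i||^2 ),

which guarantees descent of F for exact geodesics; because discrete
registration is approximate, every step is verified by re-measuring the
energy and backtracked (dt halved, up to ``max_backtracks`` times) if the
measured energy would increase.  The recorded energy trace contains only
accepted measurements and is therefore non-increasing.

Cumulative warps are composed in the diffeomorphism group and images are
always resampled once from their originals, never from previously
resampled copies, bounding interpolation blur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusteringResult, cluster_images
from .core import (
    ConfigurationError,
    DisplacementField,
    ImageVolume,
    PopulationGraph,
    VelocityField,
    apply_warp,
    compose,
    make_identity_warp,
    min_interior_jacobian,
)
from .hgraph import build_hierarchical_graph, global_center
from .pairreg import RegistrationParams, estimate_velocity, exp_map, scale_velocity
from .similarity import distance_matrix

logger = logging.getLogger("ehugs")

_EPS = 1e-12


@dataclass
class ShrinkParams:
    """Controls of the outer shrinkage loop.

    norm_mode
        Field norm used in the energy and the dt bound: "sup" (max voxel
        magnitude, keeps per-step displacement at or below one voxel) or
        "l2" (root sum of squares over the grid).
    level_schedule
        "alternate" (default): one intra-subgroup pass then one
        inter-subgroup pass per outer iteration; "joint": a single pass
        over all edges (flat graph dynamics on the hierarchical edge set).
    freeze_graph
        Build the graph once from the input images instead of re-clustering
        every iteration.
    """

    max_outer_iters: int = 20
    energy_rel_tol: float = 1e-3
    norm_mode: str = "sup"
    level_schedule: str = "alternate"
    freeze_graph: bool = False
    max_backtracks: int = 5
    check_jacobian: bool = True

    def __post_init__(self):
        if self.max_outer_iters < 1 or self.energy_rel_tol <= 0:
            raise ValueError("max_outer_iters >= 1 and energy_rel_tol > 0 required")
        if self.norm_mode not in ("sup", "l2"):
            raise ValueError("norm_mode must be 'sup' or 'l2'")
        if self.level_schedule not in ("alternate", "joint"):
            raise ValueError("level_schedule must be 'alternate' or 'joint'")


def field_norm(vectors: np.ndarray, mode: str = "sup") -> float:
    """Norm of a vector field: sup voxel magnitude or global l2."""
    mag2 = (vectors * vectors).sum(axis=-1)
    if mode == "sup":
        return float(np.sqrt(mag2.max()))
    return float(np.sqrt(mag2.sum()))


def _edge_key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def oriented_velocity(velocities: dict, i: int, j: int) -> np.ndarray:
    """Velocity pointing from node i toward neighbour j.

    Edge velocities are stored once per undirected edge (i < j) as the
    field taking image i toward image j; the reverse orientation is the
    negation (the inverse of a stationary flow).
    """
    v = velocities[_edge_key(i, j)]
    vec = v.vectors if isinstance(v, VelocityField) else np.asarray(v)
    return vec if i < j else -vec


def graph_energy(velocities: dict, E: np.ndarray, norm_mode: str = "sup") -> float:
    """F = sum over ordered connected pairs of squared edge-velocity norms.

    Both orientations count (||v_ji|| = ||v_ij||), so a single edge with
    norm 3 contributes 18.
    """
    E = np.asarray(E)
    ii, jj = np.nonzero(np.triu(E, k=1))
    total = 0.0
    for i, j in zip(ii.tolist(), jj.tolist()):
        key = _edge_key(i, j)
        if key not in velocities:
            raise KeyError(f"missing velocity for edge {key}")
        total += 2.0 * field_norm(velocities[key].vectors, norm_mode) ** 2
    return total


def average_velocity(i: int, velocities: dict, neighbors) -> VelocityField:
    """Voxelwise mean of the velocities on node i's incident edges."""
    neighbors = list(neighbors)
    if not neighbors:
        raise ValueError(f"node {i} is isolated; the population graph must be connected")
    acc = None
    spacing = None
    for j in neighbors:
        vec = oriented_velocity(velocities, i, int(j))
        spacing = velocities[_edge_key(i, int(j))].spacing
        acc = vec.copy() if acc is None else acc + vec
    return VelocityField(acc / len(neighbors), spacing)


def time_step(avg_velocities: dict, degrees: dict, norm_mode: str = "sup") -> float | None:
    """Descent-preserving time step for the current averaged velocities.

    Returns None when every averaged velocity vanishes (convergence).
    The ratio term is always in (0, 1) and the whole step is bounded by
    1 / max_i ||vhat_i||.
    """
    norms = {i: field_norm(v.vectors, norm_mode) for i, v in avg_velocities.items()}
    vmax = max(norms.values(), default=0.0)
    if vmax <= _EPS:
        return None
    num = sum(degrees[i] * norms[i] ** 2 for i in norms)
    den = sum((degrees[i] + 1) * norms[i] ** 2 for i in norms)
    return min(1.0 / vmax, num / den)


@dataclass
class StepResult:
    warps: list
    images: list
    velocities: dict  # re-estimated velocities on the level edges
    dt: float
    moved: bool
    accepted: bool
    min_jacobian: float = 1.0


def _level_energy(velocities: dict, edges, norm_mode: str) -> float:
    return sum(2.0 * field_norm(velocities[_edge_key(*e)].vectors, norm_mode) ** 2 for e in edges)


def shrink_step(
    originals: list[ImageVolume],
    warps: list[DisplacementField],
    graph: PopulationGraph,
    level_edges: list[tuple[int, int]],
    velocities: dict,
    params: ShrinkParams,
    reg_params: RegistrationParams,
    carry_members: bool = False,
    images: list[ImageVolume] | None = None,
    dt_scale: float = 1.0,
) -> StepResult:
    """One level pass: warp every node incident to ``level_edges``.

    Each incident node i is advanced by exp(vhat_i * dt); with
    ``carry_members`` (high-level pass) a representative's incremental
    warp is also composed onto every member of its subgroup, so subgroups
    move as wholes toward the center.  The step is accepted only if the
    level energy, re-measured by re-registering the level edges on the
    moved images, does not increase (dt halved on failure, up to
    ``max_backtracks`` retries) and, when enabled, all cumulative warps
    keep a positive interior Jacobian determinant.
    """
    if images is None:
        images = [apply_warp(o, w) for o, w in zip(originals, warps)]
    nbrs: dict[int, list[int]] = {}
    for i, j in level_edges:
        nbrs.setdefault(i, []).append(j)
        nbrs.setdefault(j, []).append(i)
    if not nbrs:
        return StepResult(warps, images, {}, 0.0, False, True)
    avg = {i: average_velocity(i, velocities, js) for i, js in nbrs.items()}
    degrees = {i: len(js) for i, js in nbrs.items()}
    dt0 = time_step(avg, degrees, params.norm_mode)
    if dt0 is None:
        return StepResult(warps, images, dict(velocities), 0.0, False, True)
    dt0 *= dt_scale
    f_old = _level_energy(velocities, level_edges, params.norm_mode)

    for attempt in range(params.max_backtracks + 1):
        dt = dt0 * 0.5**attempt
        steps = {i: exp_map(scale_velocity(v, dt)) for i, v in avg.items()}
        new_warps = list(warps)
        changed = set(nbrs)
        for i, step in steps.items():
            new_warps[i] = compose(warps[i], step)
        if carry_members:
            for alpha, rep in graph.representatives.items():
                if rep not in steps:
                    continue
                for m in graph.members(alpha):
                    m = int(m)
                    if m != rep:
                        new_warps[m] = compose(warps[m], steps[rep])
                        changed.add(m)
        new_images = list(images)
        for i in changed:
            new_images[i] = apply_warp(originals[i], new_warps[i])
        new_vel = {
            _edge_key(i, j): estimate_velocity(new_images[min(i, j)], new_images[max(i, j)], reg_params)
            for i, j in level_edges
        }
        f_new = _level_energy(new_vel, level_edges, params.norm_mode)
        min_jac = 1.0
        if params.check_jacobian:
            min_jac = min(min_interior_jacobian(new_warps[i]) for i in changed)
        if f_new <= f_old * (1.0 + 1e-9) + _EPS and min_jac > 0.0:
            logger.debug(
                "level step accepted: dt=%.4g F %.4g -> %.4g (attempt %d)",
                dt, f_old, f_new, attempt,
            )
            return StepResult(new_warps, new_images, new_vel, dt, True, True, min_jac)
        logger.debug(
            "level step rejected (F %.4g -> %.4g, minJ=%.3g), halving dt", f_old, f_new, min_jac
        )
    logger.warning("shrink step rejected after %d backtracks; declaring convergence", params.max_backtracks)
    return StepResult(warps, images, dict(velocities), 0.0, False, False)


@dataclass
class GroupwiseResult:
    """Everything a run produces: aligned images, warps, traces, graphs."""

    images: list
    warps: list
    energy_trace: list
    dt_history: list
    graph_history: list
    clustering_history: list
    jacobian_trace: list = field(default_factory=list)
    converged: bool = False
    message: str = ""

    @property
    def n_iterations(self) -> int:
        return len(self.graph_history)


def _single_group(D) -> ClusteringResult:
    o = global_center(D)
    return ClusteringResult(np.zeros(D.n, dtype=np.int64), np.array([o]))


def run_groupwise(
    images: list[ImageVolume],
    shrink_params: ShrinkParams | None = None,
    reg_params: RegistrationParams | None = None,
    metric: str = "ssd",
    star_graph: bool = False,
    mi_bins: int = 32,
) -> GroupwiseResult:
    """Register a population of images to their hidden common space.

    With ``star_graph`` the clustering is bypassed and every image is
    connected directly to the global center (a group-mean-style baseline
    with identical shrinkage dynamics).
    """
    sp = shrink_params or ShrinkParams()
    rp = reg_params or RegistrationParams()
    if len(images) < 2:
        raise ConfigurationError("run_groupwise requires at least 2 images")
    for img in images[1:]:
        if not images[0].same_grid(img):
            raise ConfigurationError(
                f"image {img.id!r} grid {img.data.shape} does not match {images[0].data.shape}"
            )

    originals = list(images)
    n = len(images)
    warps = [make_identity_warp(img.grid) for img in images]
    current = [ImageVolume(img.data.copy(), img.spacing, img.id) for img in images]

    energy_trace: list[float] = []
    dt_history: list[float] = []
    graph_history: list[PopulationGraph] = []
    clustering_history: list[ClusteringResult] = []
    jacobian_trace: list[float] = []
    converged = False
    message = ""
    graph = None
    clus = None
    vel_cache: dict = {}  # velocities measured on the *current* images

    for k in range(sp.max_outer_iters):
        prev_graph, prev_clus = graph, clus
        if graph is None or not sp.freeze_graph:
            D = distance_matrix(current, metric=metric, bins=mi_bins)
            clus = _single_group(D) if star_graph else cluster_images(D=D)
            graph = build_hierarchical_graph(clus, D)

        velocities = {
            (i, j): vel_cache.get((i, j)) or estimate_velocity(current[i], current[j], rp)
            for i, j in graph.edges()
        }
        f_pre = graph_energy(velocities, graph.connection, sp.norm_mode)
        if (
            energy_trace
            and prev_graph is not None
            and graph is not prev_graph
            and f_pre > energy_trace[-1] * (1.0 + 1e-9)
            and all(e in vel_cache for e in prev_graph.edges())
        ):
            # re-clustering raised the measured energy on unchanged images:
            # keep shrinking the previous graph instead (monotone trace)
            logger.info(
                "iter %d: rebuilt graph raises energy (%.6g > %.6g); keeping previous graph",
                k, f_pre, energy_trace[-1],
            )
            graph, clus = prev_graph, prev_clus
            velocities = {e: vel_cache[e] for e in graph.edges()}
            f_pre = graph_energy(velocities, graph.connection, sp.norm_mode)
        graph_history.append(graph)
        clustering_history.append(clus)
        if not energy_trace:
            energy_trace.append(f_pre)
        logger.info(
            "iter %d: Omega=%d edges=%d F=%.6g", k, graph.n_subgroups, graph.n_edges, f_pre
        )
        if f_pre <= _EPS:
            converged, message = True, "zero energy: all images coincide"
            break

        intra = [e for e, lvl in graph.edge_levels.items() if lvl == "intra"]
        inter = [e for e, lvl in graph.edge_levels.items() if lvl == "inter"]
        if sp.level_schedule == "joint":
            passes = [(intra + inter, False)]
        else:
            passes = [(intra, False), (inter, True)]

        # whole-iteration descent with global dt backtracking: the per-level
        # acceptance is local to each level's edges, so the full-graph energy
        # can still regress near convergence; halving all time steps restores
        # the theoretical descent regime
        accepted_iter = False
        moved_any = True
        for m in range(min(2, sp.max_backtracks) + 1):
            t_warps, t_current = list(warps), list(current)
            moved_any = False
            iter_jacs, iter_dts = [], []
            for idx, (edges, carry) in enumerate(passes):
                if not edges:
                    continue
                if idx == 0:
                    lvl_vel = {e: velocities[e] for e in edges}
                else:  # re-estimate after the previous pass moved the nodes
                    lvl_vel = {
                        e: estimate_velocity(t_current[e[0]], t_current[e[1]], rp)
                        for e in edges
                    }
                res = shrink_step(
                    originals, t_warps, graph, edges, lvl_vel, sp, rp,
                    carry_members=carry, images=t_current, dt_scale=0.5**m,
                )
                if res.accepted and res.moved:
                    t_warps, t_current = res.warps, res.images
                    iter_dts.append(res.dt)
                    iter_jacs.append(res.min_jacobian)
                    moved_any = True
            if not moved_any:
                break
            # accepted-step energy: re-measure the full graph on moved images
            post_vel = {
                (i, j): estimate_velocity(t_current[i], t_current[j], rp)
                for i, j in graph.edges()
            }
            f_post = graph_energy(post_vel, graph.connection, sp.norm_mode)
            if f_post <= energy_trace[-1] * (1.0 + 1e-9) + _EPS:
                warps, current = t_warps, t_current
                prev = energy_trace[-1]
                energy_trace.append(min(f_post, prev))
                dt_history.extend(iter_dts)
                jacobian_trace.append(min(iter_jacs) if iter_jacs else 1.0)
                vel_cache = post_vel
                accepted_iter = True
                if prev > 0 and (prev - energy_trace[-1]) <= sp.energy_rel_tol * prev:
                    converged, message = True, "relative energy change below tolerance"
                break
            logger.info(
                "iter %d: global energy regressed (%.6g -> %.6g); retrying with halved dt",
                k, energy_trace[-1], f_post,
            )

        if moved_any and not accepted_iter and sp.level_schedule == "alternate":
            # the level-alternating heuristic cannot descend globally any
            # more; fall back to the joint dynamics on all edges, whose
            # step acceptance is the global energy measurement itself
            logger.info("iter %d: alternating passes stalled; trying joint pass", k)
            res = shrink_step(
                originals, warps, graph, intra + inter, velocities, sp, rp,
                carry_members=False, images=current,
            )
            if res.accepted and res.moved:
                warps, current = res.warps, res.images
                f_post = graph_energy(res.velocities, graph.connection, sp.norm_mode)
                prev = energy_trace[-1]
                energy_trace.append(min(f_post, prev))
                dt_history.append(res.dt)
                jacobian_trace.append(res.min_jacobian)
                vel_cache = res.velocities
                accepted_iter = True
                if prev > 0 and (prev - energy_trace[-1]) <= sp.energy_rel_tol * prev:
                    converged, message = True, "relative energy change below tolerance"

        if not moved_any:
            converged, message = True, "no admissible descent step"
            break
        if not accepted_iter:
            converged, message = True, "energy regression persisted; iteration reverted"
            break
        if converged:
            break
    else:
        message = message or "max_outer_iters reached"

    final = [apply_warp(o, w) for o, w in zip(originals, warps)]
    for img, o in zip(final, originals):
        img.id = o.id
    return GroupwiseResult(
        final, warps, energy_trace, dt_history, graph_history, clustering_history,
        jacobian_trace, converged, message or "completed",
    )
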