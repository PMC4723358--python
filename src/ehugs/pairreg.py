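"""Pairwise diffeomorphic registration and stationary-velocity algebra.

The edge velocities of the population graph are estimated with a
log-domain diffeomorphic-demons-style method: SSD intensity forces,
"fluid" Gaussian smoothing of each update, "diffusion" Gaussian smoothing
of the accumulated stationary velocity field, run over a multi-resolution
pyramid.  The output of :func:`estimate_velocity` is a stationary velocity
field v such that warping the moving image by exp(v) reduces its SSD to
the fixed image.

exp is the exponential map integrated by scaling and squaring: v is
divided by 2^n so the largest step is below half a voxel, converted to a
small displacement, and self-composed n times.  Velocity/time scaling is
elementwise, so exp(v * dt) advances the flow for time dt.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    DisplacementField,
    GridMismatchError,
    ImageVolume,
    VelocityField,
    compose,
    make_identity_warp,
    warp_array,
)

logger = logging.getLogger("ehugs")


class RegistrationDivergenceError(RuntimeError):
    """Raised when a pairwise registration fails to reduce SSD at all."""


@dataclass
class RegistrationParams:
    """Tunables of the demons-style pairwise engine.

    pyramid_levels
        Number of resolution levels; level L works at shape / 2^L.
    iters_per_level
        Gradient-descent iterations at each level.
    fluid_sigma
        Gaussian std (voxels) smoothing each force update.
    diffusion_sigma
        Gaussian std (voxels) smoothing the accumulated velocity field.
    step_scale
        Multiplier on the demons update (the classic force is already
        bounded by half a voxel per iteration).
    squaring_steps
        Minimum scaling-and-squaring steps for exp; None chooses
        automatically so the scaled step stays below ``max_step`` voxels.
    """

    pyramid_levels: int = 3
    iters_per_level: int = 30
    fluid_sigma: float = 2.0
    diffusion_sigma: float = 1.0
    step_scale: float = 1.0
    squaring_steps: int | None = None
    max_step: float = 0.25

    def __post_init__(self):
        if self.pyramid_levels < 1 or self.iters_per_level < 1:
            raise ValueError("pyramid_levels and iters_per_level must be >= 1")
        if min(self.fluid_sigma, self.diffusion_sigma) < 0 or self.step_scale <= 0:
            raise ValueError("sigmas must be >= 0 and step_scale > 0")
        if self.squaring_steps is not None and self.squaring_steps < 1:
            raise ValueError("squaring_steps must be >= 1")


# ---------------------------------------------------------------------------
# Velocity algebra
# ---------------------------------------------------------------------------

def scale_velocity(v: VelocityField, s: float) -> VelocityField:
    """Elementwise velocity/time scaling: exp(scale_velocity(v, dt)) = flow for dt."""
    if not np.isfinite(s) or s < 0:
        raise ValueError("scale must be finite and >= 0")
    return VelocityField(v.vectors * s, v.spacing)


def negate_velocity(v: VelocityField) -> VelocityField:
    """Group inverse of a stationary field: exp(-v) approximates exp(v)^-1."""
    return VelocityField(-v.vectors, v.spacing)


def _exp_array(vec: np.ndarray, squaring_steps: int | None, max_step: float) -> np.ndarray:
    vmax = float(np.sqrt((vec * vec).sum(axis=-1).max()))
    if vmax == 0.0:
        return np.zeros_like(vec)
    n_auto = max(0, math.ceil(math.log2(vmax / max_step))) if vmax > max_step else 0
    n = n_auto if squaring_steps is None else max(squaring_steps, n_auto)
    if squaring_steps is not None and n > squaring_steps:
        logger.debug("exp_map: increasing squaring steps %d -> %d", squaring_steps, n)
    u = vec / (2.0**n)
    spacing = (1.0,) * (vec.ndim - 1)
    fld = DisplacementField(u, spacing)
    for _ in range(n):
        fld = compose(fld, fld)
    return fld.displacements


def exp_map(v: VelocityField, squaring_steps: int | None = None, max_step: float = 0.25) -> DisplacementField:
    """Exponential map of a stationary velocity field (scaling and squaring).

    exp(0) is the identity warp; the number of squarings is raised
    automatically whenever the requested count would leave a scaled step
    above ``max_step`` voxels.
    """
    return DisplacementField(_exp_array(v.vectors, squaring_steps, max_step), v.spacing)


# ---------------------------------------------------------------------------
# Multi-resolution demons
# ---------------------------------------------------------------------------

def _resize(data: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Linear resampling of a scalar array to a new shape."""
    if data.shape == tuple(shape):
        return data.copy()
    coords = np.meshgrid(
        *[
            np.linspace(0.0, s - 1.0, t) if t > 1 else np.array([0.5 * (s - 1)])
            for s, t in zip(data.shape, shape)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(data, np.stack(coords), order=1, mode="nearest")


def _downsample(data: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    factors = [s / t for s, t in zip(data.shape, shape)]
    if max(factors) > 1.0:
        data = ndimage.gaussian_filter(data, sigma=[0.5 * (f - 1.0) for f in factors])
    return _resize(data, shape)


def _resize_field(vec: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Resample a velocity field to a new grid, rescaling voxel units."""
    d = vec.shape[-1]
    out = np.empty((*shape, d))
    for k in range(d):
        out[..., k] = _resize(vec[..., k], shape) * (shape[k] / vec.shape[k])
    return out


def _smooth_field(vec: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return vec
    out = np.empty_like(vec)
    for k in range(vec.shape[-1]):
        out[..., k] = ndimage.gaussian_filter(vec[..., k], sigma)
    return out


def _ssd(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    return float(np.sum(diff * diff))


def _demons_level(
    mov: np.ndarray,
    fix: np.ndarray,
    v: np.ndarray,
    params: RegistrationParams,
) -> tuple[np.ndarray, list[float]]:
    """Demons iterations at one pyramid level; returns best velocity and SSD trace."""
    best_v = v.copy()
    best_ssd = _ssd(warp_array(mov, _exp_array(v, None, params.max_step)), fix)
    trace = [best_ssd]
    for _ in range(params.iters_per_level):
        disp = _exp_array(v, None, params.max_step)
        warped = warp_array(mov, disp)
        diff = fix - warped
        grads = np.gradient(warped)
        if warped.ndim == 1:
            grads = [grads]
        g2 = np.zeros_like(diff)
        for g in grads:
            g2 += g * g
        denom = g2 + diff * diff
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(denom > 1e-12, diff / denom, 0.0)
        update = np.stack([scale * g for g in grads], axis=-1)
        update = _smooth_field(update, params.fluid_sigma)
        v = v + params.step_scale * update
        v = _smooth_field(v, params.diffusion_sigma)
        ssd = _ssd(warp_array(mov, _exp_array(v, None, params.max_step)), fix)
        trace.append(ssd)
        if ssd < best_ssd:
            best_ssd, best_v = ssd, v.copy()
    return best_v, trace


def estimate_velocity(
    moving: ImageVolume,
    fixed: ImageVolume,
    params: RegistrationParams | None = None,
    convergence_log=None,
) -> VelocityField:
    """Stationary velocity v such that warp(moving, exp(v)) approaches fixed.

    Coarse-to-fine over a Gaussian pyramid; at each level the best
    velocity seen (lowest SSD) is carried forward, so the final field
    never does worse than the identity.  Deterministic given inputs.
    Raises :class:`RegistrationDivergenceError` only if the result would
    be worse than no registration at all (which keep-best prevents; the
    guard catches numerical corruption).

    ``convergence_log``, if given, is a path receiving the per-iteration
    SSD trace as CSV (level, iteration, ssd).
    """
    if params is None:
        params = RegistrationParams()
    if not moving.same_grid(fixed):
        raise GridMismatchError("estimate_velocity requires a common grid")
    shape = moving.data.shape
    ndim = len(shape)
    # drop pyramid levels whose coarse grid would fall below 8 voxels per axis
    levels = [
        l
        for l in range(params.pyramid_levels)
        if min(math.ceil(s / 2**l) for s in shape) >= 8 or l == 0
    ]
    v: np.ndarray | None = None
    log_rows: list[str] = []
    for l in sorted(levels, reverse=True):
        lshape = tuple(math.ceil(s / 2**l) for s in shape)
        mov_l = _downsample(moving.data, lshape)
        fix_l = _downsample(fixed.data, lshape)
        v = np.zeros((*lshape, ndim)) if v is None else _resize_field(v, lshape)
        v, trace = _demons_level(mov_l, fix_l, v, params)
        logger.debug(
            "demons level %d (%s): SSD %.4g -> %.4g", l, lshape, trace[0], min(trace)
        )
        log_rows.extend(f"{l},{i},{s!r}" for i, s in enumerate(trace))
    if convergence_log is not None:
        with open(convergence_log, "w") as fh:
            fh.write("level,iteration,ssd\n")
            fh.write("\n".join(log_rows) + "\n")
    initial = _ssd(moving.data, fixed.data)
    final = _ssd(warp_array(moving.data, _exp_array(v, None, params.max_step)), fixed.data)
    if final > initial * (1.0 + 1e-9) + 1e-12:
        raise RegistrationDivergenceError(
            f"registration increased SSD from {initial:.4g} to {final:.4g}"
        )
    return VelocityField(v, moving.spacing)


def identity_like(img: ImageVolume) -> DisplacementField:
    """Identity warp on an image's grid (convenience wrapper)."""
    return make_identity_warp(img.grid)
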