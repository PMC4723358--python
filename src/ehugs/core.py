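"""Domain types and grid conventions shared by the whole pipeline.

All spatial quantities live in 0-based voxel index space.  A displacement
field ``u`` maps an output voxel ``x`` to the input sample position
``x + u(x)`` (backward / pull-back warping), the convention used by
demons-style registration: it avoids hole filling and makes composition a
single resampling step.  Intensities are resampled with linear
interpolation and nearest-border extension outside the grid; integer label
maps use nearest-neighbour sampling with background (0) outside the grid,
so warped labels always stay inside the original label set.

Grids are 2-D or 3-D.  Every image in one run must share the same shape
and spacing; physical-space headers beyond voxel spacing are out of scope
(inputs are assumed affinely pre-aligned).
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger("ehugs")

Grid = namedtuple("Grid", ["shape", "spacing"])


class GridMismatchError(ValueError):
    """Raised when two volumes or fields do not share a common grid."""


class ConfigurationError(ValueError):
    """Raised for invalid run configurations (e.g. fewer than 2 images)."""


def _check_grid(data: np.ndarray, spacing) -> tuple[float, ...]:
    if data.ndim not in (2, 3):
        raise ValueError(f"only 2-D and 3-D grids are supported, got {data.ndim}-D")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != data.ndim:
        raise ValueError("spacing length must match dimensionality")
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    return spacing


@dataclass
class ImageVolume:
    """A scalar image on a regular voxel grid.

    Parameters
    ----------
    data
        Scalar array (2-D or 3-D); intensities in arbitrary units.
    spacing
        Physical voxel size per axis in mm.  Defaults to isotropic 1 mm.
    id
        Stable string identifier used in reports and file names.
    """

    data: np.ndarray
    spacing: tuple[float, ...] = None
    id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = _check_grid(self.data, self.spacing)
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"image {self.id!r} contains non-finite values")

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.spacing)

    def same_grid(self, other) -> bool:
        return self.data.shape == other.data.shape and self.spacing == tuple(other.spacing)


@dataclass
class LabelVolume:
    """An integer tissue-label map paired with an :class:`ImageVolume` grid.

    Label 0 is background; other codes are tissue classes
    (conventionally 1 = WM, 2 = GM, 3 = CSF).
    """

    data: np.ndarray
    spacing: tuple[float, ...] = None
    id: str = ""
    label_set: frozenset = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label data must be integer-valued")
            self.data = rounded.astype(np.int32)
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = _check_grid(self.data, self.spacing)
        present = frozenset(int(v) for v in np.unique(self.data)) - {0}
        if self.label_set is None:
            self.label_set = present
        else:
            self.label_set = frozenset(int(v) for v in self.label_set)
            if not present <= self.label_set:
                raise ValueError(f"labels {sorted(present - self.label_set)} outside label_set")

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.spacing)


def _check_field(vectors: np.ndarray) -> np.ndarray:
    vectors = np.asarray(vectors, dtype=np.float64)
    ndim = vectors.ndim - 1
    if ndim not in (2, 3) or vectors.shape[-1] != ndim:
        raise ValueError(
            f"vector field must have shape (*grid, D) with D = grid rank, got {vectors.shape}"
        )
    if not np.all(np.isfinite(vectors)):
        raise ValueError("vector field contains non-finite values")
    return vectors


@dataclass
class VelocityField:
    """A stationary velocity field in voxel units, shape ``(*grid, D)``.

    Its flow for unit time, :func:`ehugs.pairreg.exp_map`, yields a
    diffeomorphic displacement.  The zero field is valid and maps to the
    identity warp.
    """

    vectors: np.ndarray
    spacing: tuple[float, ...] = None

    def __post_init__(self):
        self.vectors = _check_field(self.vectors)
        if self.spacing is None:
            self.spacing = (1.0,) * (self.vectors.ndim - 1)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def grid(self) -> Grid:
        return Grid(self.vectors.shape[:-1], self.spacing)


@dataclass
class DisplacementField:
    """A dense warp: output voxel ``x`` samples input position ``x + u(x)``.

    Displacements are in voxel units; the all-zero field is the identity.
    """

    displacements: np.ndarray
    spacing: tuple[float, ...] = None

    def __post_init__(self):
        self.displacements = _check_field(self.displacements)
        if self.spacing is None:
            self.spacing = (1.0,) * (self.displacements.ndim - 1)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def grid(self) -> Grid:
        return Grid(self.displacements.shape[:-1], self.spacing)


# ---------------------------------------------------------------------------
# Warping primitives
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _identity_coords(shape: tuple[int, ...]) -> np.ndarray:
    """Cached mesh of voxel indices, shape (D, *shape). Treated as read-only."""
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"))


def make_identity_warp(grid) -> DisplacementField:
    """Return the identity displacement field (all zeros) for a grid.

    ``grid`` may be a :class:`Grid`, a shape tuple, or any object with
    ``shape``/``spacing`` attributes.
    """
    if isinstance(grid, tuple) and all(isinstance(n, (int, np.integer)) for n in grid):
        shape, spacing = tuple(grid), (1.0,) * len(grid)
    else:
        shape, spacing = tuple(grid.shape), tuple(grid.spacing)
    return DisplacementField(np.zeros((*shape, len(shape))), spacing)


def _sample_coords(disp: np.ndarray) -> np.ndarray:
    """Coordinates x + u(x) as a (D, *shape) array for map_coordinates."""
    return _identity_coords(disp.shape[:-1]) + np.moveaxis(disp, -1, 0)


def warp_array(data: np.ndarray, disp: np.ndarray, order: int = 1) -> np.ndarray:
    """Backward-warp an array through a displacement array.

    ``order=1`` (intensities): linear interpolation, nearest-border
    extension.  ``order=0`` (labels): nearest-neighbour sampling, value 0
    outside the grid.
    """
    if data.shape != disp.shape[:-1]:
        raise GridMismatchError(f"data shape {data.shape} != field grid {disp.shape[:-1]}")
    if not disp.any():  # identity warp is exact, skip interpolation entirely
        return data.copy()
    coords = _sample_coords(disp)
    if order == 0:
        return ndimage.map_coordinates(data, coords, order=0, mode="grid-constant", cval=0)
    return ndimage.map_coordinates(data, coords, order=1, mode="nearest")


def apply_warp(img: ImageVolume, warp: DisplacementField) -> ImageVolume:
    """Resample an image through a displacement field (linear interpolation)."""
    out = warp_array(img.data, warp.displacements, order=1)
    return ImageVolume(out, img.spacing, img.id)


def apply_warp_labels(lab: LabelVolume, warp: DisplacementField) -> LabelVolume:
    """Resample a label map through a displacement field (nearest neighbour)."""
    out = warp_array(lab.data.astype(np.float64), warp.displacements, order=0)
    return LabelVolume(out.astype(np.int32), lab.spacing, lab.id, lab.label_set)


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Compose two warps so that warping sequentially equals warping once.

    Under the backward convention, ``warp(img, compose(outer, inner)) ==
    warp(warp(img, outer), inner)``; as point mappings ``T(x) = x + u(x)``
    this is ``T_outer ∘ T_inner``.  The composite is

        c(x) = inner(x) + outer(x + inner(x)),

    i.e. the outer field resampled at the inner-warped position plus the
    inner field.  Composition with the identity returns the other argument
    (up to exact copy).
    """
    uo, ui = outer.displacements, inner.displacements
    if uo.shape != ui.shape:
        raise GridMismatchError("cannot compose fields on different grids")
    if not ui.any():
        return DisplacementField(uo.copy(), outer.spacing)
    if not uo.any():
        return DisplacementField(ui.copy(), inner.spacing)
    coords = _sample_coords(ui)
    out = np.empty_like(ui)
    for d in range(ui.shape[-1]):
        out[..., d] = ndimage.map_coordinates(uo[..., d], coords, order=1, mode="nearest")
    out += ui
    return DisplacementField(out, outer.spacing)


def jacobian_determinant(warp: DisplacementField) -> np.ndarray:
    """Voxelwise Jacobian determinant of the mapping ``x + u(x)``.

    Central differences; boundary estimates are one-sided and unreliable,
    use :func:`min_interior_jacobian` for diffeomorphism checks.
    """
    u = warp.displacements
    ndim = u.shape[-1]
    # J[d, e] = d(u_d)/d(x_e) + delta_de
    J = np.empty((ndim, ndim, *u.shape[:-1]))
    for d in range(ndim):
        grads = np.gradient(u[..., d])
        if ndim == 1:
            grads = [grads]
        for e in range(ndim):
            J[d, e] = grads[e] + (1.0 if d == e else 0.0)
    if ndim == 2:
        return J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    det = (
        J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
        - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
        + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])
    )
    return det


def min_interior_jacobian(warp: DisplacementField, margin: int = 2) -> float:
    """Minimum Jacobian determinant away from the grid boundary."""
    det = jacobian_determinant(warp)
    sl = tuple(slice(margin, max(margin + 1, n - margin)) for n in det.shape)
    return float(det[sl].min())


# ---------------------------------------------------------------------------
# Population graph
# ---------------------------------------------------------------------------

@dataclass
class PopulationGraph:
    """Two-level hierarchical graph over a population of N images.

    ``connection`` is the N x N symmetric 0/1 matrix E (authoritative);
    within each subgroup a star centred on the representative, across
    subgroups a star of representatives centred on the global center, so
    the graph is connected with exactly N - 1 undirected edges.
    ``edge_levels`` tags each undirected edge ``(i, j)`` (i < j) as
    ``"intra"`` (representative-member) or ``"inter"`` (center-representative).
    """

    connection: np.ndarray
    subgroup_of: np.ndarray
    representatives: dict
    center: int
    edge_levels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.connection = np.asarray(self.connection, dtype=np.int8)
        self.subgroup_of = np.asarray(self.subgroup_of, dtype=np.int64)

    @property
    def n_images(self) -> int:
        return self.connection.shape[0]

    @property
    def n_subgroups(self) -> int:
        return len(self.representatives)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges as sorted (i, j) pairs with i < j."""
        ii, jj = np.nonzero(np.triu(self.connection, k=1))
        return list(zip(ii.tolist(), jj.tolist()))

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.connection, k=1).sum())

    def neighbors(self, i: int) -> np.ndarray:
        return np.nonzero(self.connection[i])[0]

    def members(self, alpha: int) -> np.ndarray:
        return np.nonzero(self.subgroup_of == alpha)[0]

    def validate(self) -> None:
        """Assert all structural invariants; raises AssertionError on violation."""
        E = self.connection
        N = self.n_images
        assert E.shape == (N, N) and np.array_equal(E, E.T), "E must be symmetric"
        assert not E.diagonal().any(), "no image is self-connected"
        assert self.n_edges == N - 1, f"edge count {self.n_edges} != N-1 = {N - 1}"
        if N > 1:
            ncomp, _ = connected_components(csr_matrix(E), directed=False)
            assert ncomp == 1, "graph must be connected"
        reps = set(self.representatives.values())
        assert self.center in reps, "center must be a representative"
        for alpha, r in self.representatives.items():
            assert self.subgroup_of[r] == alpha, "representative must belong to its subgroup"
        for i in range(N):
            if i not in reps:
                assert E[i].sum() == 1, "non-representative must have exactly one edge"
                j = int(np.nonzero(E[i])[0][0])
                assert self.representatives[int(self.subgroup_of[i])] == j

    def to_edge_list(self, path, ids=None) -> None:
        """Write the edge list as TSV: id_i, id_j, level."""
        name = (lambda i: ids[i]) if ids is not None else str
        with open(path, "w") as fh:
            fh.write("id_i\tid_j\tlevel\n")
            for i, j in self.edges():
                fh.write(f"{name(i)}\t{name(j)}\t{self.edge_levels.get((i, j), 'intra')}\n")


# ---------------------------------------------------------------------------
# Shrinkage state
# ---------------------------------------------------------------------------

@dataclass
class ShrinkState:
    """Mutable per-iteration state of a graph-shrinkage run.

    ``warps[i]`` is the cumulative warp of image i at the current
    iteration (identity at iteration 0); ``images[i]`` is the original
    image resampled once through that warp.  ``energy_trace`` holds the
    accepted-step energies and is non-increasing by construction.
    """

    iteration: int
    images: list
    warps: list
    velocities: dict
    energy_trace: list
    dt_history: list
    jacobian_trace: list = field(default_factory=list)
    converged: bool = False


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing: tuple[float, ...]) -> np.ndarray:
    aff = np.eye(4)
    for d, s in enumerate(spacing[:3]):
        aff[d, d] = s
    return aff


def save_image(img: ImageVolume, path) -> None:
    nib.save(nib.Nifti1Image(img.data.astype(np.float32), _affine(img.spacing)), str(path))


def load_image(path, id: str | None = None) -> ImageVolume:
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj).astype(np.float64)
    data = np.squeeze(data)
    spacing = tuple(float(z) for z in nii.header.get_zooms()[: data.ndim])
    return ImageVolume(data, spacing, id if id is not None else Path(path).name.split(".")[0])


def save_labels(lab: LabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(lab.data.astype(np.int16), _affine(lab.spacing)), str(path))


def load_labels(path, id: str | None = None) -> LabelVolume:
    nii = nib.load(str(path))
    data = np.squeeze(np.asanyarray(nii.dataobj)).astype(np.int32)
    spacing = tuple(float(z) for z in nii.header.get_zooms()[: data.ndim])
    return LabelVolume(data, spacing, id if id is not None else Path(path).name.split(".")[0])


def save_field(fld, path) -> None:
    """Serialize a velocity or displacement field as a D-component vector NIfTI."""
    arr = fld.vectors if isinstance(fld, VelocityField) else fld.displacements
    nib.save(nib.Nifti1Image(arr.astype(np.float32), _affine(fld.spacing)), str(path))


def load_field(path, kind: str = "displacement"):
    nii = nib.load(str(path))
    arr = np.asanyarray(nii.dataobj).astype(np.float64)
    spacing = tuple(float(z) for z in nii.header.get_zooms()[: arr.ndim - 1])
    cls = DisplacementField if kind == "displacement" else VelocityField
    return cls(arr, spacing)
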