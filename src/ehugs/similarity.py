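"""Pairwise image distances feeding clustering and graph construction.

The default distance is the sum of squared intensity differences (SSD)
over the full grid, d_ij = ||I_i - I_j||^2.  Mutual information is
provided as an alternative for multi-contrast populations: the "distance"
is the negated joint-histogram MI, so it decreases as the images become
more statistically dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigurationError, GridMismatchError, ImageVolume


@dataclass
class DistanceMatrix:
    """N x N symmetric pairwise distance matrix with image ids."""

    values: np.ndarray
    metric_tag: str
    ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if self.metric_tag == "ssd":
            if (self.values < 0).any() or np.abs(self.values.diagonal()).max() > 1e-9:
                raise ValueError("ssd matrix must be non-negative with zero diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)


def _require_same_grid(a: ImageVolume, b: ImageVolume) -> None:
    if not a.same_grid(b):
        raise GridMismatchError(
            f"images {a.id!r} ({a.data.shape}) and {b.id!r} ({b.data.shape}) "
            "are not on a common grid"
        )


def ssd_distance(a: ImageVolume, b: ImageVolume, mask: np.ndarray | None = None) -> float:
    """Sum of squared intensity differences over the full grid.

    An optional boolean ``mask`` restricts the sum to foreground voxels
    (off by default: the distance is computed over the whole grid).
    """
    _require_same_grid(a, b)
    diff = a.data - b.data
    if mask is not None:
        diff = diff[mask]
    return float(np.sum(diff * diff))


def mi_distance(a: ImageVolume, b: ImageVolume, bins: int = 32) -> float:
    """Negated mutual information (bits) of the joint intensity histogram.

    Equal-width bins over each image's observed range; a constant image
    has zero entropy, so MI (and hence the distance) is 0.  Symmetric in
    its arguments.
    """
    _require_same_grid(a, b)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x, y = a.data.ravel(), b.data.ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    mi = float(np.sum(pxy[nz] * np.log2(pxy[nz] / np.outer(px, py)[nz])))
    return -mi


def distance_matrix(
    images: list[ImageVolume],
    metric: str = "ssd",
    bins: int = 32,
    mask: np.ndarray | None = None,
) -> DistanceMatrix:
    """All pairwise distances d_ij on the current images.

    SSD uses the Gram-matrix identity ||x - y||^2 = ||x||^2 + ||y||^2 -
    2<x, y> for an O(N^2 P) vectorized evaluation; MI falls back to a
    pairwise loop.
    """
    if len(images) < 2:
        raise ConfigurationError("distance_matrix requires at least 2 images")
    for img in images[1:]:
        _require_same_grid(images[0], img)
    ids = [img.id for img in images]
    n = len(images)
    if metric == "ssd":
        X = np.stack([img.data.ravel() for img in images])
        if mask is not None:
            X = X[:, np.asarray(mask).ravel()]
        sq = np.einsum("ip,ip->i", X, X)
        D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        np.maximum(D, 0.0, out=D)
        np.fill_diagonal(D, 0.0)
        D = 0.5 * (D + D.T)
    elif metric == "mi":
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = mi_distance(images[i], images[j], bins=bins)
    else:
        raise ConfigurationError(f"unknown metric {metric!r}")
    return DistanceMatrix(D, metric, ids)
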