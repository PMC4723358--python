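"""Affinity-propagation clustering of the image population into subgroups.

Affinity propagation is used because the number of subgroups emerges from
the data rather than being fixed in advance.  Similarities are negated
distances, s_ij = -d_ij, and every image receives the same preference

    p = (1/N^2) sum_ij s_ij,

i.e. the mean pairwise similarity, so all images are a priori equally
likely to become subgroup exemplars.

The message-passing solver (responsibilities/availabilities with damping)
is implemented here rather than delegated, so that the tie-break rule is
explicit and deterministic: no noise is injected and equal messages are
resolved toward the lowest index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError
from .similarity import DistanceMatrix, distance_matrix

logger = logging.getLogger("ehugs")


@dataclass
class ClusteringResult:
    """Partition of N images into subgroups with one exemplar each."""

    labels: np.ndarray  # image index -> subgroup index in [0, n_clusters)
    exemplars: np.ndarray  # subgroup index -> exemplar image index
    converged: bool = True

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.exemplars = np.asarray(self.exemplars, dtype=np.int64)
        for alpha, ex in enumerate(self.exemplars):
            if self.labels[ex] != alpha:
                raise ValueError("each exemplar must belong to its own subgroup")
        if not np.array_equal(np.unique(self.labels), np.arange(len(self.exemplars))):
            raise ValueError("labels must cover subgroups 0..Omega-1")

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def members(self, alpha: int) -> np.ndarray:
        return np.nonzero(self.labels == alpha)[0]

    def to_csv(self, path, ids=None) -> None:
        with open(path, "w") as fh:
            fh.write("image_id,subgroup\n")
            for i, lab in enumerate(self.labels):
                fh.write(f"{ids[i] if ids is not None else i},{lab}\n")


def preference_value(D: DistanceMatrix) -> float:
    """Shared affinity-propagation preference: mean of all -d_ij.

    Includes the zero diagonal, so for N identical images p = 0; it is
    never positive for a distance matrix.
    """
    return float(-D.values.sum() / D.n**2)


def affinity_propagation(
    S: np.ndarray,
    preference: float,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_window: int = 50,
) -> ClusteringResult:
    """Exemplar-based clustering by responsibility/availability message passing.

    Parameters
    ----------
    S
        N x N similarity matrix (off-diagonal entries used; the diagonal
        is overwritten with ``preference``).
    preference
        Self-similarity s_kk controlling how readily points become
        exemplars; lower values yield fewer clusters.
    damping
        Message damping factor in [0.5, 1).
    max_iter, convergence_window
        Iteration cap and the number of consecutive iterations the
        exemplar set must stay unchanged to declare convergence.

    Deterministic: no noise is added; ties resolve to the lowest index.
    Non-convergence logs a warning and returns the current assignment.
    """
    S = np.array(S, dtype=np.float64)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if not (0.5 <= damping < 1.0):
        raise ValueError("damping must be in [0.5, 1)")
    if n == 1:
        return ClusteringResult(np.array([0]), np.array([0]))
    np.fill_diagonal(S, preference)

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    rows = np.arange(n)
    stable = 0
    prev_exemplars: np.ndarray | None = None
    converged = False
    for _ in range(max_iter):
        # responsibilities: r(i,k) = s(i,k) - max_{k' != k} (a(i,k') + s(i,k'))
        AS = A + S
        top = np.argmax(AS, axis=1)
        first = AS[rows, top]
        AS[rows, top] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[rows, top] = S[rows, top] - second
        R = damping * R + (1.0 - damping) * Rnew
        # availabilities: a(i,k) = min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        Anew = Rp.sum(axis=0)[None, :] - Rp
        diag = Anew.diagonal().copy()
        Anew = np.minimum(Anew, 0.0)
        np.fill_diagonal(Anew, diag)
        A = damping * A + (1.0 - damping) * Anew

        exemplars = np.nonzero((A + R).diagonal() > 0)[0]
        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars):
            stable += 1
            if stable >= convergence_window and len(exemplars) > 0:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars
    if not converged:
        logger.warning("affinity propagation did not converge in %d iterations", max_iter)

    net = (A + R).diagonal()
    exemplars = np.nonzero(net > 0)[0]
    if len(exemplars) == 0:
        exemplars = np.array([int(np.argmax(net))])  # argmax -> lowest index on ties
    # assign each point to its most similar exemplar; exemplars to themselves
    labels = np.argmax(S[:, exemplars], axis=1)
    labels[exemplars] = np.arange(len(exemplars))
    return ClusteringResult(labels, exemplars, converged)


def cluster_images(
    images=None,
    metric: str = "ssd",
    D: DistanceMatrix | None = None,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_window: int = 50,
) -> ClusteringResult:
    """Cluster images into subgroups: distances -> similarities -> AP.

    Either ``images`` or a precomputed distance matrix ``D`` must be
    given.  If AP degenerates to all-singleton clusters (Omega = N), the
    result falls back to a single subgroup whose exemplar is the global
    center, keeping the downstream graph valid.
    """
    from .hgraph import global_center  # local import to avoid a cycle

    if D is None:
        if images is None or len(images) < 2:
            raise ConfigurationError("cluster_images requires at least 2 images")
        D = distance_matrix(images, metric=metric)
    S = -D.values
    p = preference_value(D)
    result = affinity_propagation(
        S, p, damping=damping, max_iter=max_iter, convergence_window=convergence_window
    )
    if result.n_clusters == D.n and D.n > 1:
        logger.warning(
            "affinity propagation yielded all singletons; falling back to a "
            "single subgroup centred on the global center"
        )
        o = global_center(D)
        result = ClusteringResult(np.zeros(D.n, dtype=np.int64), np.array([o]))
    return result
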