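"""Two-level hierarchical graph construction.

Given a clustering into subgroups, the graph connects each subgroup's
members to a representative (the member nearest the global center) and
connects all representatives to the global center itself, yielding a
connected graph with exactly N - 1 undirected edges for any partition:
sum_alpha (n_alpha - 1) intra edges plus (Omega - 1) inter edges.
"""

from __future__ import annotations

import numpy as np

from .clustering import ClusteringResult
from .core import PopulationGraph
from .similarity import DistanceMatrix


def global_center(D: DistanceMatrix) -> int:
    """Index of the image minimizing the sum of distances to all others.

    Ties broken toward the lowest index (np.argmin).
    """
    return int(np.argmin(D.values.sum(axis=0)))


def subgroup_representative(members, center: int, D: DistanceMatrix) -> int:
    """Member of a subgroup nearest the global center.

    If the subgroup contains the center, the representative is the center
    itself; otherwise the argmin of d(i, center) over members, ties to the
    lowest index.
    """
    members = sorted(int(m) for m in members)
    if not members:
        raise ValueError("subgroup must be non-empty")
    if center in members:
        return center
    dist = D.values[members, center]
    return members[int(np.argmin(dist))]


def build_hierarchical_graph(clustering: ClusteringResult, D: DistanceMatrix) -> PopulationGraph:
    """Assemble the two-level graph from a clustering and distance matrix."""
    n = D.n
    if len(clustering.labels) != n:
        raise ValueError("clustering does not cover all images")
    E = np.zeros((n, n), dtype=np.int8)
    o = global_center(D)
    representatives: dict[int, int] = {}
    edge_levels: dict[tuple[int, int], str] = {}
    for alpha in range(clustering.n_clusters):
        members = clustering.members(alpha)
        rep = subgroup_representative(members, o, D)
        representatives[alpha] = rep
        for m in members:
            m = int(m)
            if m != rep:
                E[m, rep] = E[rep, m] = 1
                edge_levels[(min(m, rep), max(m, rep))] = "intra"
    for rep in representatives.values():
        if rep != o:
            E[rep, o] = E[o, rep] = 1
            edge_levels[(min(rep, o), max(rep, o))] = "inter"
    graph = PopulationGraph(E, clustering.labels, representatives, o, edge_levels)
    graph.validate()
    return graph


def neighbor_count(E: np.ndarray, i: int) -> int:
    """Row sum N_i of the connection matrix at node i."""
    return int(np.asarray(E)[i].sum())
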