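"""Weighted similarity-graph machinery and the two baseline clusterers.

The similarity graph is the off-diagonal part of an affinity matrix:
vertices are sequences, edge weights are similarity scores.  This module
provides connected components, peeling of small components before the
spectral stage, random bridging of residual components, and the two
classical baselines — connected component analysis at an E-value
threshold and average-linkage hierarchical clustering with a distance
cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components as _csgraph_cc
from scipy.spatial.distance import squareform

from specfam.similarity import AffinityMatrix, EValueRecord, collapse_min_evalues

__all__ = [
    "SimilarityGraph",
    "Partition",
    "ComponentDecomposition",
    "connected_components",
    "peel_small_components",
    "bridge_components",
    "cca_cluster",
    "hierarchical_cluster",
]


@dataclass
class SimilarityGraph:
    """Undirected weighted graph over sequence ids.

    ``adjacency`` is symmetric with a zero diagonal: self-similarities
    are excluded from the edge set, so vertex weights ``d_i`` and the
    total weight ``m`` count genuine pairwise edges only.
    """

    ids: list[str]
    adjacency: sp.csr_array

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match id count")

    @classmethod
    def from_affinity(cls, affinity: AffinityMatrix) -> "SimilarityGraph":
        adj = sp.lil_array(affinity.matrix.copy())
        adj.setdiag(0)
        adj = sp.csr_array(adj)
        adj.eliminate_zeros()
        return cls(ids=list(affinity.ids), adjacency=adj)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def vertex_weights(self) -> np.ndarray:
        """d_i = sum of weights of edges adjacent to vertex i."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def total_weight(self) -> float:
        """m = sum of all edge weights (each edge counted once)."""
        return float(self.adjacency.sum()) / 2.0

    def edge_list(self) -> list[tuple[str, str, float]]:
        coo = sp.coo_array(self.adjacency)
        return [
            (self.ids[i], self.ids[j], float(w))
            for i, j, w in zip(coo.row, coo.col, coo.data)
            if i < j
        ]


@dataclass
class Partition:
    """Assignment of every id to exactly one cluster label."""

    assignment: dict[str, int]

    @classmethod
    def from_labels(cls, ids: Sequence[str], labels: Iterable[int]) -> "Partition":
        return cls(dict(zip(ids, (int(c) for c in labels), strict=True)))

    @classmethod
    def from_clusters(cls, clusters: Iterable[Iterable[str]]) -> "Partition":
        assignment: dict[str, int] = {}
        for label, members in enumerate(clusters):
            for name in members:
                if name in assignment:
                    raise ValueError(f"id {name!r} appears in more than one cluster")
                assignment[name] = label
        return cls(assignment)

    @property
    def ids(self) -> list[str]:
        return list(self.assignment)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[i] for i in ids])

    def clusters(self) -> list[list[str]]:
        """Clusters sorted by decreasing size, ties by first id."""
        groups: dict[int, list[str]] = {}
        for name, label in self.assignment.items():
            groups.setdefault(label, []).append(name)
        return sorted(groups.values(), key=lambda c: (-len(c), sorted(c)[0]))

    def renumbered(self) -> "Partition":
        """Relabel clusters as 0..K-1 in decreasing-size order."""
        return Partition.from_clusters(self.clusters())

    def same_cluster(self, a: str, b: str) -> bool:
        return self.assignment[a] == self.assignment[b]


@dataclass
class ComponentDecomposition:
    """Connected components split into small (< threshold) and large ones."""

    components: list[set[str]]
    threshold: int = 5
    small: list[set[str]] = field(init=False)
    large: list[set[str]] = field(init=False)

    def __post_init__(self) -> None:
        self.small = [c for c in self.components if len(c) < self.threshold]
        self.large = [c for c in self.components if len(c) >= self.threshold]


def connected_components(
    graph: SimilarityGraph, threshold: int = 5
) -> ComponentDecomposition:
    """Maximal sets of vertices mutually reachable via positive-weight edges."""
    if graph.n == 0:
        return ComponentDecomposition(components=[], threshold=threshold)
    n_comp, labels = _csgraph_cc(graph.adjacency, directed=False)
    comps: list[set[str]] = [set() for _ in range(n_comp)]
    for name, label in zip(graph.ids, labels):
        comps[label].add(name)
    return ComponentDecomposition(components=comps, threshold=threshold)


def _subgraph(graph: SimilarityGraph, keep: Sequence[str]) -> SimilarityGraph:
    pos = {name: k for k, name in enumerate(graph.ids)}
    idx = np.array([pos[name] for name in keep], dtype=np.int64)
    sub = graph.adjacency[np.ix_(idx, idx)]
    return SimilarityGraph(ids=list(keep), adjacency=sp.csr_array(sub))


def peel_small_components(
    graph: SimilarityGraph, min_size: int = 5
) -> tuple[SimilarityGraph, list[set[str]]]:
    """Remove components smaller than ``min_size``; return them for merge-back.

    Small components are unlikely to need further subdivision, so they
    bypass the spectral stage and re-enter as final clusters.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    decomp = connected_components(graph, threshold=min_size)
    keep = [name for name in graph.ids if any(name in c for c in decomp.large)]
    return _subgraph(graph, keep), decomp.small


def bridge_components(
    graph: SimilarityGraph, bridge_weight: float = 0.005, seed: int = 0
) -> SimilarityGraph:
    """Connect residual components with a chain of light random edges.

    The top eigenvalue of the normalized matrix has multiplicity equal
    to the number of connected components, which destabilizes iterative
    eigensolvers; a chain of ``c - 1`` edges of weight ``bridge_weight``
    (well below any genuine similarity of interest) reduces the
    multiplicity to one while perturbing the spectrum negligibly.
    """
    if graph.n == 0:
        raise ValueError("cannot bridge an empty graph")
    if not (0 < bridge_weight < 0.01):
        raise ValueError("bridge_weight must lie in (0, 0.01)")
    decomp = connected_components(graph)
    if len(decomp.components) <= 1:
        return graph
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(decomp.components))
    pos = {name: k for k, name in enumerate(graph.ids)}
    adj = sp.lil_array(graph.adjacency.copy())
    prev_comp = None
    for comp_idx in order:
        members = sorted(decomp.components[comp_idx])
        if prev_comp is not None:
            a = prev_comp[rng.integers(len(prev_comp))]
            b = members[rng.integers(len(members))]
            adj[pos[a], pos[b]] = bridge_weight
            adj[pos[b], pos[a]] = bridge_weight
        prev_comp = members
    return SimilarityGraph(ids=list(graph.ids), adjacency=sp.csr_array(adj))


def _threshold_graph(
    ids: list[str], pairs: Mapping[tuple[int, int], float], evalue_threshold: float
) -> SimilarityGraph:
    n = len(ids)
    rows, cols, data = [], [], []
    for (i, j), ev in pairs.items():
        if ev <= evalue_threshold:
            rows += [i, j]
            cols += [j, i]
            data += [1.0, 1.0]
    adj = sp.csr_array(sp.coo_array((data, (rows, cols)), shape=(n, n)))
    return SimilarityGraph(ids=ids, adjacency=adj)


def cca_cluster(
    records: Sequence[EValueRecord], evalue_threshold: float = 1e-6
) -> Partition:
    """Connected component analysis baseline.

    Keeps only pairs whose minimum-direction E-value is at or below the
    threshold and reports the connected components of the result.  The
    default threshold of 1e-6 is the conventional benchmark setting.
    """
    if not (evalue_threshold > 0):
        raise ValueError("evalue_threshold must be positive")
    ids, pairs = collapse_min_evalues(records)
    graph = _threshold_graph(ids, pairs, evalue_threshold)
    decomp = connected_components(graph)
    return Partition.from_clusters(sorted(c) for c in decomp.components)


def hierarchical_cluster(
    records: Sequence[EValueRecord],
    cut_evalue: float = 1e-6,
    missing_evalue: float = 10.0,
) -> Partition:
    """Average-linkage hierarchical clustering baseline on E-value distances.

    Pairs without a reported hit take distance ``missing_evalue`` (the
    default BLAST reporting ceiling of 10); asymmetric pairs are
    symmetrized with the minimum.  Merging stops at the first merge
    whose average linkage distance exceeds ``cut_evalue`` and the
    current forest is returned.  Average linkage is monotone, so this
    equals a flat cut of the dendrogram at ``cut_evalue``.
    """
    if not (cut_evalue > 0):
        raise ValueError("cut_evalue must be positive")
    ids, pairs = collapse_min_evalues(records)
    n = len(ids)
    if n == 0:
        raise ValueError("no sequences in input")
    if n == 1:
        return Partition.from_labels(ids, [0])
    dist = np.full((n, n), float(missing_evalue))
    np.fill_diagonal(dist, 0.0)
    for (i, j), ev in pairs.items():
        dist[i, j] = dist[j, i] = min(ev, missing_evalue)
    tree = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(tree, t=cut_evalue, criterion="distance")
    return Partition.from_labels(ids, labels).renumbered()
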