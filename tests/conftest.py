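"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from specfam.graph import Partition, SimilarityGraph
from specfam.similarity import AffinityMatrix, LogisticModel, build_affinity
from specfam.synthetic import PlantedSpec, generate_planted, toy_worked_example

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_model() -> LogisticModel:
    """Identity-feature model: similarity = sigmoid(-log10 E)."""
    return LogisticModel(intercept=0.0, slope=1.0)


@pytest.fixture
def toy():
    """The fixed 12-sequence, 3-family worked example."""
    return toy_worked_example()


@pytest.fixture
def planted():
    """The standard planted fixture: 3 blocks of 20, seeded."""
    spec = PlantedSpec(seed=1)
    records, gold = generate_planted(spec)
    return spec, records, gold


@pytest.fixture
def planted_affinity(planted):
    _, records, gold = planted
    return build_affinity(records), gold


# ---------------------------------------------------------------- oracles


def bfs_components(ids: list[str], edges: list[tuple[str, str]]) -> list[set[str]]:
    """Exhaustive reachability oracle, independent of scipy's csgraph."""
    adj: dict[str, set[str]] = {i: set() for i in ids}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    comps: list[set[str]] = []
    for start in ids:
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            v = queue.pop()
            if v in comp:
                continue
            comp.add(v)
            queue.extend(adj[v] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def all_partitions(items: list):
    """Enumerate every set partition (Bell-number many) of ``items``."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1 :]
        yield smaller + [[first]]


def brute_modularity(graph: SimilarityGraph, partition: Partition) -> float:
    """Direct double-loop evaluation of the modularity definition."""
    s = graph.adjacency.toarray()
    ids = graph.ids
    labels = partition.labels_for(ids)
    d = s.sum(axis=1)
    two_m = s.sum()
    q = 0.0
    for i in range(len(ids)):
        for j in range(len(ids)):
            if labels[i] == labels[j]:
                q += s[i, j] - d[i] * d[j] / two_m
    return q / two_m


def brute_mass_fraction(graph: SimilarityGraph, partition: Partition) -> float:
    """Direct pair-sum evaluation of the mass fraction definition."""
    s = graph.adjacency.toarray()
    ids = graph.ids
    labels = partition.labels_for(ids)
    intra = total = 0.0
    for i, j in combinations(range(len(ids)), 2):
        total += s[i, j]
        if labels[i] == labels[j]:
            intra += s[i, j]
    return intra / total


def random_graph(n: int, rng: np.random.Generator, density: float = 0.5) -> SimilarityGraph:
    """A random weighted graph with at least one edge."""
    import scipy.sparse as sp

    while True:
        w = rng.random((n, n)) * (rng.random((n, n)) < density)
        w = np.triu(w, k=1)
        w = w + w.T
        if w.sum() > 0:
            break
    ids = [f"v{i}" for i in range(n)]
    return SimilarityGraph(ids=ids, adjacency=sp.csr_array(w))


def clique_affinity(n_cliques: int, size: int = 5) -> AffinityMatrix:
    """Disjoint unit-weight cliques as an affinity matrix (unit diagonal)."""
    import scipy.sparse as sp

    n = n_cliques * size
    mat = np.zeros((n, n))
    for c in range(n_cliques):
        lo = c * size
        mat[lo : lo + size, lo : lo + size] = 1.0
    ids = [f"q{c}_{k}" for c in range(n_cliques) for k in range(size)]
    return AffinityMatrix(ids=ids, matrix=sp.csr_array(mat))
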