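"""Cluster quality statistics.

Internal measures (no gold standard needed): the mass fraction — the
share of total edge weight falling inside clusters — and the weighted
Newman modularity, which compares intra-cluster weight with its
expectation under degree-preserving random rewiring.  External
measures: the contingency table against a gold-standard partition and
the size-weighted combined F-score derived from it, plus hypergeometric
term-enrichment assessment with Benjamini-Hochberg FDR control.  The
rearranged-matrix helper orders rows/columns by cluster so a good
clustering shows up as a block-diagonal heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from specfam.graph import Partition, SimilarityGraph
from specfam.similarity import AffinityMatrix

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "mass_fraction",
    "modularity",
    "contingency",
    "combined_fscore",
    "rearrange_matrix",
    "enrichment",
]


def mass_fraction(graph: SimilarityGraph, partition: Partition) -> float:
    """Fraction of total edge weight concentrated inside clusters.

    Self-similarities are excluded from both sums, so the all-singleton
    partition scores exactly 0 and the single-cluster partition exactly 1.
    """
    total = graph.total_weight
    if total <= 0:
        raise ValueError("graph has zero total edge weight")
    labels = partition.labels_for(graph.ids)
    coo = graph.adjacency.tocoo()
    same = labels[coo.row] == labels[coo.col]
    intra = float(coo.data[same].sum()) / 2.0
    return intra / total


def modularity(graph: SimilarityGraph, partition: Partition) -> float:
    """Weighted Newman modularity of a partition.

    Q = (1/2m) * sum_{ij} (s_ij - d_i d_j / 2m) * delta_ij over all
    ordered vertex pairs (including i = j, where s_ii = 0 since
    self-similarities are excluded from the edge set).  The one-cluster
    partition scores exactly 0.
    """
    two_m = float(graph.adjacency.sum())
    if two_m <= 0:
        raise ValueError("graph has zero total edge weight")
    labels = partition.labels_for(graph.ids)
    d = graph.vertex_weights
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        idx = np.flatnonzero(mask)
        intra = float(graph.adjacency[np.ix_(idx, idx)].sum())
        q += intra / two_m - (d[mask].sum() / two_m) ** 2
    return q


@dataclass
class ContingencyTable:
    """Gold-family x predicted-cluster counts n_ij with marginals.

    Rows index gold families (n_i.), columns predicted clusters (n_.j).
    Precision p_ij = n_ij / n_.j and recall r_ij = n_ij / n_i. follow.
    """

    cells: pd.DataFrame  # rows: gold labels, cols: predicted labels

    @property
    def n(self) -> int:
        return int(self.cells.to_numpy().sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.cells.to_numpy().sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.cells.to_numpy().sum(axis=0)

    @property
    def precision(self) -> np.ndarray:
        return self.cells.to_numpy() / self.col_totals[None, :]

    @property
    def recall(self) -> np.ndarray:
        return self.cells.to_numpy() / self.row_totals[:, None]


def contingency(gold: Partition, predicted: Partition) -> ContingencyTable:
    """Cross-tabulate a gold-standard partition against a predicted one."""
    gold_ids, pred_ids = set(gold.assignment), set(predicted.assignment)
    if gold_ids != pred_ids:
        missing = sorted(gold_ids ^ pred_ids)
        raise ValueError(
            f"gold and predicted partitions cover different ids; "
            f"symmetric difference: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    ids = sorted(gold_ids)
    table = pd.crosstab(
        pd.Series(gold.labels_for(ids), name="gold"),
        pd.Series(predicted.labels_for(ids), name="predicted"),
    )
    return ContingencyTable(cells=table)


def combined_fscore(table: ContingencyTable) -> float:
    """Size-weighted best-match combined F-score between two clusterings.

    For each gold family i, the best harmonic mean of precision and
    recall over predicted clusters j is taken, weighted by family size:
    F = (1/n) * sum_i n_i. * max_j 2 p_ij r_ij / (p_ij + r_ij).
    Equals 1 iff the clusterings are identical up to label renaming.
    """
    n = table.n
    if n <= 0:
        raise ValueError("empty contingency table")
    p, r = table.precision, table.recall
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 2.0 * p * r / (p + r)
    f = np.nan_to_num(f)  # p_ij = r_ij = 0 contributes 0
    return float((table.row_totals * f.max(axis=1)).sum() / n)


def rearrange_matrix(
    affinity: AffinityMatrix, partition: Partition
) -> tuple[np.ndarray, list[int]]:
    """Permute the affinity matrix so same-cluster ids are contiguous.

    Clusters are ordered by decreasing size; returns the permuted dense
    matrix and the cumulative cluster boundary indices.  A good
    clustering shows a block-diagonal pattern.
    """
    pos = {name: k for k, name in enumerate(affinity.ids)}
    order: list[int] = []
    boundaries: list[int] = []
    for members in partition.clusters():
        order.extend(pos[name] for name in members)
        boundaries.append(len(order))
    idx = np.array(order, dtype=np.int64)
    dense = affinity.matrix.toarray()[np.ix_(idx, idx)]
    return dense, boundaries


@dataclass
class EnrichmentResult:
    """Per-(cluster, term) hypergeometric tests plus summary ratios.

    ``tests`` has one row per (cluster, term) pair with the raw and
    BH-adjusted p-values; a cluster is significant when at least one of
    its terms passes at level alpha after correction.  Summary ratios
    are restricted to clusters of at least ``min_cluster_size`` ids.
    """

    tests: pd.DataFrame
    cluster_significant: dict[int, bool]
    n_clusters: int
    n_significant: int
    total_size: int
    significant_size: int
    alpha: float
    min_cluster_size: int

    @property
    def count_ratio(self) -> float:
        return self.n_significant / self.n_clusters if self.n_clusters else 0.0

    @property
    def size_ratio(self) -> float:
        return self.significant_size / self.total_size if self.total_size else 0.0


def enrichment(
    partition: Partition,
    annotations: Mapping[str, set[str]],
    alpha: float = 0.05,
    min_cluster_size: int = 3,
) -> EnrichmentResult:
    """Assess clusters for over-represented annotation terms.

    For every cluster of size >= ``min_cluster_size`` and every term
    occurring in it, a one-sided hypergeometric upper-tail p-value is
    computed (population = all annotated ids, successes = ids carrying
    the term, draws = annotated ids in the cluster).  Benjamini-Hochberg
    correction is applied jointly over all (cluster, term) tests, and a
    cluster counts as significant if at least one term passes at
    ``alpha``.  Unannotated ids are ignored throughout.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    annotated = {i for i, terms in annotations.items() if terms}
    background = annotated & set(partition.assignment)
    if not background:
        raise ValueError("no annotated ids overlap the partition")
    pop = len(background)
    term_counts: dict[str, int] = {}
    for name in background:
        for term in annotations[name]:
            term_counts[term] = term_counts.get(term, 0) + 1

    rows = []
    eligible: list[tuple[int, list[str]]] = []
    for label, members in enumerate(partition.clusters()):
        if len(members) < min_cluster_size:
            continue
        eligible.append((label, members))
        inside = [m for m in members if m in background]
        if not inside:
            continue
        draw = len(inside)
        counts: dict[str, int] = {}
        for name in inside:
            for term in annotations[name]:
                counts[term] = counts.get(term, 0) + 1
        for term, k in counts.items():
            pval = float(stats.hypergeom.sf(k - 1, pop, term_counts[term], draw))
            rows.append((label, term, k, draw, term_counts[term], pval))

    tests = pd.DataFrame(
        rows,
        columns=["cluster", "term", "in_cluster", "cluster_annotated",
                 "term_total", "pvalue"],
    )
    if len(tests):
        tests["adjusted"] = stats.false_discovery_control(
            tests["pvalue"].to_numpy(), method="bh"
        )
        tests["significant"] = tests["adjusted"] <= alpha
    else:
        tests["adjusted"] = pd.Series(dtype=float)
        tests["significant"] = pd.Series(dtype=bool)

    sig_clusters = set(tests.loc[tests["significant"], "cluster"])
    cluster_sig = {label: label in sig_clusters for label, _ in eligible}
    total_size = sum(len(m) for _, m in eligible)
    sig_size = sum(len(m) for label, m in eligible if cluster_sig[label])
    return EnrichmentResult(
        tests=tests,
        cluster_significant=cluster_sig,
        n_clusters=len(eligible),
        n_significant=len(sig_clusters),
        total_size=total_size,
        significant_size=sig_size,
        alpha=alpha,
        min_cluster_size=min_cluster_size,
    )
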