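"""The spectral clustering engine.

Given a symmetrized affinity matrix S, the pipeline (i) peels connected
components smaller than ``min_component_size`` — they re-enter as final
clusters untouched — (ii) bridges the remaining components with light
random edges so the top eigenvalue of the normalized matrix has
multiplicity one, (iii) builds L = D^{-1/2} S' D^{-1/2}, (iv) computes
the leading eigenpairs, (v) selects the number of clusters K from the
first eigengap ratio exceeding epsilon (unless fixed by the user),
(vi) row-normalizes the K leading eigenvectors and (vii) runs k-means
with orthogonal centroid seeding on the embedded points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from specfam.graph import (
    Partition,
    SimilarityGraph,
    bridge_components,
    peel_small_components,
)
from specfam.similarity import AffinityMatrix

__all__ = [
    "SpectralOptions",
    "NormalizedMatrix",
    "EigenSystem",
    "Embedding",
    "normalize",
    "top_eigenpairs",
    "select_k",
    "embed",
    "orthogonal_init",
    "kmeans",
    "spectral_cluster",
]

Mode = Literal["automatic", "bounded", "exact"]

#: Residual tolerance required of every returned eigenpair.
EIG_RESIDUAL_TOL = 1e-6

#: Row norms below this are treated as numerically degenerate.
DEGENERATE_ROW_TOL = 1e-12


@dataclass(frozen=True)
class SpectralOptions:
    """Tunable knobs of the spectral pipeline.

    mode
        ``automatic`` scans the full available spectrum for the first
        eigengap; ``bounded`` computes only ``k_max`` eigenpairs and
        falls back to ``k_max`` when no gap appears below it; ``exact``
        uses ``k_exact`` clusters with no gap scan.
    epsilon
        Eigengap ratio threshold; K is the smallest k with
        lambda_k / lambda_{k+1} > epsilon.  Default 1.02.
    """

    mode: Mode = "automatic"
    epsilon: float = 1.02
    k_max: int | None = None
    k_exact: int | None = None
    min_component_size: int = 5
    bridge_weight: float = 0.005
    seed: int = 0
    max_eigenvalues: int = 200
    kmeans_max_iter: int = 300
    kmeans_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.mode not in ("automatic", "bounded", "exact"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (self.epsilon > 1):
            raise ValueError("epsilon must exceed 1")
        if self.mode == "bounded" and (self.k_max is None or self.k_max < 1):
            raise ValueError("bounded mode requires k_max >= 1")
        if self.mode == "exact" and (self.k_exact is None or self.k_exact < 1):
            raise ValueError("exact mode requires k_exact >= 1")


@dataclass
class NormalizedMatrix:
    """L = D^{-1/2} S' D^{-1/2} with D the diagonal of vertex degrees.

    Degrees include the unit diagonal of S', so they are strictly
    positive and the eigenvalues of L lie in [-1, 1]; for a connected
    graph the largest eigenvalue is exactly 1.
    """

    matrix: sp.csr_array
    degrees: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EigenSystem:
    """Leading eigenpairs, eigenvalues descending, eigenvectors as columns."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def k(self) -> int:
        return len(self.eigenvalues)


@dataclass
class Embedding:
    """Row-normalized spectral coordinates, one row per retained vertex.

    Rows whose pre-normalization norm fell below ``DEGENERATE_ROW_TOL``
    are flagged in ``degenerate`` and left as zero vectors; the caller
    assigns them after k-means.
    """

    points: np.ndarray
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.points), dtype=bool)


def normalize(affinity_reduced: AffinityMatrix) -> NormalizedMatrix:
    """Build the degree-normalized matrix L from a (reduced) affinity matrix."""
    s = sp.csr_array(affinity_reduced.matrix)
    d = np.asarray(s.sum(axis=1)).ravel()
    if np.any(d <= 0):
        raise ValueError("isolated vertex with zero self-similarity")
    inv_sqrt = 1.0 / np.sqrt(d)
    scale = sp.dia_array((inv_sqrt[None, :], [0]), shape=s.shape)
    lmat = sp.csr_array(scale @ s @ scale)
    return NormalizedMatrix(matrix=lmat, degrees=d)


def top_eigenpairs(lmat: NormalizedMatrix, k: int, seed: int = 0) -> EigenSystem:
    """The k largest-eigenvalue pairs of L, sorted descending.

    Small problems (or k close to n) are solved densely; larger ones go
    through the implicitly restarted Lanczos iteration with a seeded
    start vector for determinism.  Each returned pair satisfies
    ``||L u - lambda u|| <= 1e-6``.
    """
    n = lmat.n
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if n <= 64 or k >= n - 1:
        vals, vecs = np.linalg.eigh(lmat.matrix.toarray())
        vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(n)
        try:
            vals, vecs = spla.eigsh(lmat.matrix, k=k, which="LA", v0=v0)
        except spla.ArpackNoConvergence as exc:
            raise RuntimeError(
                f"eigensolver failed to converge for k={k}, n={n}: {exc}"
            ) from exc
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    resid = np.linalg.norm(lmat.matrix @ vecs - vecs * vals[None, :], axis=0)
    if np.any(resid > EIG_RESIDUAL_TOL):
        raise RuntimeError(
            f"eigenpair residual {resid.max():.2e} exceeds {EIG_RESIDUAL_TOL:.0e}"
        )
    return EigenSystem(eigenvalues=vals, eigenvectors=vecs)


def select_k(eigenvalues: Sequence[float], options: SpectralOptions) -> int:
    """Choose the cluster count K from the eigengap ratios.

    K is the smallest k with lambda_k / lambda_{k+1} > epsilon.  A
    non-positive lambda_{k+1} makes the ratio meaningless and is treated
    as an immediate gap at k.  In bounded mode only k < k_max is
    scanned and k_max is returned when no gap is found; automatic mode
    returns the full scan length with a warning in that case.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("empty eigenvalue spectrum")
    if lam.size == 1:
        return 1
    limit = lam.size - 1
    if options.mode == "bounded":
        limit = min(limit, options.k_max - 1) if options.k_max else limit
    for k in range(1, limit + 1):
        nxt = lam[k]
        if nxt <= 0:
            return k
        if lam[k - 1] / nxt > options.epsilon:
            return k
    if options.mode == "bounded" and options.k_max is not None:
        return min(options.k_max, lam.size)
    warnings.warn(
        "no eigengap ratio exceeded epsilon; using the full scanned spectrum",
        RuntimeWarning,
        stacklevel=2,
    )
    return lam.size


def embed(eigsys: EigenSystem, K: int) -> Embedding:
    """Row-normalize the K leading eigenvectors into unit-norm points."""
    if K > eigsys.k:
        raise ValueError(f"K={K} exceeds the {eigsys.k} computed eigenpairs")
    u = eigsys.eigenvectors[:, :K].copy()
    norms = np.linalg.norm(u, axis=1)
    degenerate = norms < DEGENERATE_ROW_TOL
    safe = np.where(degenerate, 1.0, norms)
    u /= safe[:, None]
    u[degenerate] = 0.0
    return Embedding(points=u, degenerate=degenerate)


def orthogonal_init(
    points: Embedding | np.ndarray, K: int, seed: int = 0
) -> np.ndarray:
    """Pick K data points as mutually near-orthogonal initial centroids.

    The first centroid is a seeded random data point; each subsequent
    one is the data point minimizing the maximum absolute cosine
    similarity to the centroids already chosen.
    """
    pts = points.points if isinstance(points, Embedding) else np.asarray(points)
    n = len(pts)
    if n < K:
        raise ValueError(f"need at least K={K} points, have {n}")
    rng = np.random.default_rng(seed)
    norms = np.linalg.norm(pts, axis=1)
    unit = pts / np.where(norms < DEGENERATE_ROW_TOL, 1.0, norms)[:, None]
    chosen = [int(rng.integers(n))]
    for _ in range(1, K):
        cos = np.abs(unit @ unit[chosen].T)  # (n, |chosen|)
        score = cos.max(axis=1)
        score[chosen] = np.inf
        chosen.append(int(np.argmin(score)))
    return pts[chosen].copy()


def kmeans(
    points: Embedding | np.ndarray,
    centroids: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> np.ndarray:
    """Lloyd iterations from the given centroids; returns a label per point.

    Empty clusters are re-seeded with the point farthest from its
    current centroid so the requested cluster count is preserved.
    """
    pts = points.points if isinstance(points, Embedding) else np.asarray(points)
    cent = np.array(centroids, dtype=float, copy=True)
    if len(cent) == 0:
        raise ValueError("at least one centroid required")
    k = len(cent)
    labels = None
    for _ in range(max_iter):
        dist2 = ((pts[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        new_labels = dist2.argmin(axis=1)
        for c in range(k):
            if not np.any(new_labels == c):
                farthest = int(dist2[np.arange(len(pts)), new_labels].argmax())
                new_labels[farthest] = c
                cent[c] = pts[farthest]
        new_cent = np.vstack(
            [pts[new_labels == c].mean(axis=0) for c in range(k)]
        )
        shift = np.linalg.norm(new_cent - cent, axis=1).max()
        converged = labels is not None and np.array_equal(new_labels, labels)
        labels, cent = new_labels, new_cent
        if converged or shift < tol:
            break
    return labels


def _assign_degenerate(
    labels: np.ndarray,
    degenerate: np.ndarray,
    graph: SimilarityGraph,
    points: np.ndarray,
) -> np.ndarray:
    """Give degenerate (zero-row) vertices the label of their strongest
    non-degenerate neighbour in the similarity graph; isolated ones fall
    back to the nearest centroid of the non-degenerate points."""
    out = labels.copy()
    adj = graph.adjacency
    for i in np.flatnonzero(degenerate):
        row = adj[[i], :].toarray().ravel()
        row[degenerate] = 0.0
        if row.max() > 0:
            out[i] = out[int(row.argmax())]
        else:
            good = ~degenerate
            cents = np.vstack(
                [points[good][labels[good] == c].mean(axis=0)
                 for c in np.unique(labels[good])]
            )
            out[i] = int(np.unique(labels[good])[
                ((points[i] - cents) ** 2).sum(axis=1).argmin()
            ])
    return out


def spectral_cluster(
    affinity: AffinityMatrix, options: SpectralOptions | None = None
) -> Partition:
    """Run the full spectral pipeline on an affinity matrix.

    Returns a partition covering every input id exactly once: spectral
    clusters for the retained vertices plus one cluster per peeled
    small component.
    """
    if options is None:
        options = SpectralOptions()
    graph = SimilarityGraph.from_affinity(affinity)
    reduced, peeled = peel_small_components(graph, options.min_component_size)

    clusters: list[list[str]] = [sorted(c) for c in peeled]
    if reduced.n >= 2:
        bridged = bridge_components(
            reduced, bridge_weight=options.bridge_weight, seed=options.seed
        )
        # reduced affinity: bridged edges + unit diagonal
        s_prime = sp.lil_array(bridged.adjacency.copy())
        s_prime.setdiag(1.0)
        red_aff = AffinityMatrix(ids=list(bridged.ids), matrix=sp.csr_array(s_prime))
        lmat = normalize(red_aff)

        n = lmat.n
        if options.mode == "exact":
            n_eig = min(max(options.k_exact, 2), n)
        elif options.mode == "bounded":
            n_eig = min(max(options.k_max, 2), n)
        else:
            n_eig = min(max(n - 1, 1), options.max_eigenvalues, n)
        eigsys = top_eigenpairs(lmat, n_eig, seed=options.seed)

        if options.mode == "exact":
            K = min(options.k_exact, n)
        else:
            K = select_k(eigsys.eigenvalues, options)

        embedding = embed(eigsys, K)
        centroids = orthogonal_init(embedding, K, seed=options.seed)
        labels = kmeans(
            embedding, centroids, max_iter=options.kmeans_max_iter,
            tol=options.kmeans_tol,
        )
        if embedding.degenerate.any():
            labels = _assign_degenerate(
                labels, embedding.degenerate, bridged, embedding.points
            )
        for c in np.unique(labels):
            members = [bridged.ids[i] for i in np.flatnonzero(labels == c)]
            clusters.append(sorted(members))
    elif reduced.n == 1:
        clusters.append(list(reduced.ids))

    return Partition.from_clusters(clusters).renumbered()
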