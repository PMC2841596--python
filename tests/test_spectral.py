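"""Tests for the spectral engine: normalization, eigenpairs, K selection,
embedding, k-means and the full pipeline."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given
from hypothesis import strategies as st

from specfam.graph import SimilarityGraph, bridge_components
from specfam.similarity import AffinityMatrix, build_affinity
from specfam.spectral import (
    EigenSystem,
    SpectralOptions,
    embed,
    kmeans,
    normalize,
    orthogonal_init,
    select_k,
    spectral_cluster,
    top_eigenpairs,
)
from specfam.synthetic import PlantedSpec, generate_planted

from conftest import clique_affinity


def affinity_from_dense(mat: np.ndarray) -> AffinityMatrix:
    ids = [f"v{i}" for i in range(len(mat))]
    return AffinityMatrix(ids=ids, matrix=sp.csr_array(mat))


class TestNormalize:
    def test_two_by_two_closed_form(self):
        lmat = normalize(affinity_from_dense(np.ones((2, 2))))
        assert np.allclose(lmat.matrix.toarray(), 0.5)
        vals = np.linalg.eigvalsh(lmat.matrix.toarray())
        assert vals[::-1] == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_identity_is_fixed_point(self):
        lmat = normalize(affinity_from_dense(np.eye(3)))
        assert np.allclose(lmat.matrix.toarray(), np.eye(3))

    @given(seed=st.integers(0, 2**31 - 1))
    def test_connected_graph_has_top_eigenvalue_one(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        s = rng.random((n, n)) * 0.5
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        lmat = normalize(affinity_from_dense(s))
        top = np.linalg.eigvalsh(lmat.matrix.toarray()).max()
        assert top == pytest.approx(1.0, abs=1e-8)

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(5)
        s = rng.random((6, 6))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        lmat = normalize(affinity_from_dense(s)).matrix.toarray()
        assert np.allclose(lmat, lmat.T)


class TestTopEigenpairs:
    def test_bridged_two_clique_spectrum(self):
        """Two bridged 5-cliques: two eigenvalues near 1, a clear drop after."""
        aff = clique_affinity(2, 5)
        g = SimilarityGraph.from_affinity(aff)
        bridged = bridge_components(g, bridge_weight=0.005, seed=0)
        s = sp.lil_array(bridged.adjacency.copy())
        s.setdiag(1.0)
        lmat = normalize(AffinityMatrix(list(bridged.ids), sp.csr_array(s)))
        eigsys = top_eigenpairs(lmat, 3)
        assert eigsys.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert eigsys.eigenvalues[1] == pytest.approx(1.0, abs=0.02)
        assert eigsys.eigenvalues[2] < 0.5

    def test_identity_matrix_all_ones(self):
        lmat = normalize(affinity_from_dense(np.eye(5)))
        eigsys = top_eigenpairs(lmat, 3)
        assert np.allclose(eigsys.eigenvalues, 1.0)

    @given(seed=st.integers(0, 2**31 - 1), k=st.integers(1, 10))
    def test_matches_dense_decomposition(self, seed, k):
        """Leading eigenvalues agree with a full dense decomposition."""
        rng = np.random.default_rng(seed)
        s = rng.random((10, 10)) * 0.8
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        lmat = normalize(affinity_from_dense(s))
        eigsys = top_eigenpairs(lmat, k)
        dense = np.linalg.eigvalsh(lmat.matrix.toarray())[::-1]
        assert np.allclose(eigsys.eigenvalues, dense[:k], atol=1e-8)

    def test_sparse_path_matches_dense_path(self):
        """The seeded Lanczos branch (n > 64) agrees with numpy's eigh."""
        rng = np.random.default_rng(1)
        n = 80
        s = rng.random((n, n)) * (rng.random((n, n)) < 0.2)
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        lmat = normalize(affinity_from_dense(s))
        eigsys = top_eigenpairs(lmat, 5, seed=0)
        dense = np.linalg.eigvalsh(lmat.matrix.toarray())[::-1]
        assert np.allclose(eigsys.eigenvalues, dense[:5], atol=1e-8)

    def test_k_out_of_range(self):
        lmat = normalize(affinity_from_dense(np.eye(3)))
        with pytest.raises(ValueError):
            top_eigenpairs(lmat, 4)


class TestSelectK:
    def test_first_ratio_exceeding_epsilon(self):
        opts = SpectralOptions(epsilon=1.02)
        assert select_k([1.0, 0.99, 0.97, 0.50], opts) == 2

    def test_gap_at_first_position(self):
        assert select_k([1.0, 0.5, 0.4], SpectralOptions(epsilon=1.02)) == 1

    def test_flat_spectrum_warns_and_returns_all(self):
        with pytest.warns(RuntimeWarning):
            k = select_k([1.0, 1.0, 1.0], SpectralOptions(epsilon=1.02))
        assert k == 3

    def test_nonpositive_next_eigenvalue_is_immediate_gap(self):
        assert select_k([1.0, 0.999, 0.0, -0.5], SpectralOptions()) == 2

    def test_bounded_mode_caps_scan(self):
        opts = SpectralOptions(mode="bounded", k_max=2)
        assert select_k([1.0, 0.999, 0.998, 0.5], opts) == 2

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            select_k([], SpectralOptions())

    def test_larger_epsilon_never_selects_smaller_k(self):
        """The gap rule crosses a smaller threshold no later than a larger one."""
        rng = np.random.default_rng(2)
        lam = np.sort(rng.random(12))[::-1]
        k_small = select_k(lam, SpectralOptions(epsilon=1.02))
        k_large = select_k(lam, SpectralOptions(epsilon=1.5))
        assert k_small <= k_large


class TestEmbed:
    def test_rows_unit_norm(self):
        rng = np.random.default_rng(0)
        vecs = rng.standard_normal((10, 4))
        eigsys = EigenSystem(np.linspace(1, 0.5, 4), vecs)
        emb = embed(eigsys, 3)
        assert np.allclose(np.linalg.norm(emb.points, axis=1), 1.0, atol=1e-12)

    def test_one_dimensional_embedding_is_sign(self):
        vecs = np.array([[0.3], [-0.2], [0.7]])
        emb = embed(EigenSystem(np.array([1.0]), vecs), 1)
        assert np.allclose(np.abs(emb.points), 1.0)

    def test_two_disjoint_blocks_collapse_to_orthogonal_points(self):
        """Ideal case: rows of each block map to one of 2 orthogonal vectors."""
        aff = clique_affinity(2, 5)
        lmat = normalize(aff)
        eigsys = top_eigenpairs(lmat, 2)
        emb = embed(eigsys, 2)
        pts = emb.points
        blocks = [pts[:5], pts[5:]]
        for block in blocks:
            assert np.allclose(block, block[0], atol=1e-8)
        assert abs(blocks[0][0] @ blocks[1][0]) < 1e-8

    def test_degenerate_rows_flagged(self):
        vecs = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        emb = embed(EigenSystem(np.array([1.0, 0.9]), vecs), 2)
        assert list(emb.degenerate) == [False, True, False]


class TestOrthogonalInit:
    def test_standard_basis_fully_recovered(self):
        pts = np.eye(3)
        for seed in range(5):
            cents = orthogonal_init(pts, 3, seed=seed)
            assert sorted(map(tuple, cents)) == sorted(map(tuple, pts))

    def test_k_one_is_seeded_point(self):
        pts = np.eye(4)
        cents = orthogonal_init(pts, 1, seed=7)
        assert any(np.array_equal(cents[0], p) for p in pts)

    def test_orthogonal_pair_beats_near_duplicates(self):
        pts = np.array([[1.0, 0.0], [0.999, 0.04], [0.998, -0.05], [0.0, 1.0]])
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        for seed in range(5):
            cents = orthogonal_init(pts, 2, seed=seed)
            gram = np.abs(cents @ cents.T - np.eye(2))
            assert gram.max() < 0.06  # the near-orthogonal pair was picked

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            orthogonal_init(np.eye(2), 3, seed=0)


class TestKmeans:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        blob_a = rng.normal([0, 0], 0.1, (20, 2))
        blob_b = rng.normal([5, 5], 0.1, (20, 2))
        pts = np.vstack([blob_a, blob_b])
        labels = kmeans(pts, np.array([[0.0, 0.0], [5.0, 5.0]]))
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_single_centroid_means_everything(self):
        pts = np.arange(10, dtype=float).reshape(-1, 1)
        labels = kmeans(pts, np.array([[3.0]]))
        assert np.all(labels == 0)

    def test_fixed_point_converges_immediately(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        labels = kmeans(pts, pts.copy())
        assert list(labels) == [0, 1]

    def test_empty_cluster_reseeded(self):
        """A centroid that captures nothing is re-seeded, keeping K clusters."""
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = kmeans(pts, np.array([[0.05], [100.0]]))
        assert len(set(labels)) == 2


class TestSpectralCluster:
    def test_planted_three_blocks_recovered(self, planted_affinity):
        from specfam.quality import combined_fscore, contingency

        aff, gold = planted_affinity
        part = spectral_cluster(aff, SpectralOptions(seed=1))
        assert combined_fscore(contingency(gold, part)) == 1.0

    def test_tiny_component_skips_spectral_stage(self):
        """Four sequences in one component come back as a single cluster."""
        mat = np.full((4, 4), 0.9)
        np.fill_diagonal(mat, 1.0)
        part = spectral_cluster(affinity_from_dense(mat), SpectralOptions())
        assert part.n_clusters == 1 and len(part.assignment) == 4

    @pytest.mark.parametrize("c", [2, 3, 4])
    def test_exact_mode_recovers_disjoint_cliques(self, c):
        aff = clique_affinity(c, 5)
        part = spectral_cluster(aff, SpectralOptions(mode="exact", k_exact=c))
        got = sorted(sorted(members) for members in part.clusters())
        want = sorted(
            sorted(f"q{q}_{k}" for k in range(5)) for q in range(c)
        )
        assert got == want

    @pytest.mark.parametrize("c", [2, 3, 4, 5, 6])
    def test_eigengap_counts_cliques(self, c):
        """Automatic mode with the default eigengap finds K = c cliques."""
        aff = clique_affinity(c, 5)
        part = spectral_cluster(aff, SpectralOptions(seed=0))
        assert part.n_clusters == c

    def test_membership_conservation_random_inputs(self):
        for seed in range(3):
            spec = PlantedSpec(cluster_sizes=(8, 6, 9), seed=seed,
                               edge_density_inter=0.1)
            records, gold = generate_planted(spec)
            aff = build_affinity(records)
            part = spectral_cluster(aff, SpectralOptions(seed=seed))
            assert set(part.assignment) == set(gold.assignment)

    def test_pipeline_deterministic_under_seed(self, planted_affinity):
        aff, _ = planted_affinity
        p1 = spectral_cluster(aff, SpectralOptions(seed=9))
        p2 = spectral_cluster(aff, SpectralOptions(seed=9))
        assert p1.assignment == p2.assignment

    def test_raising_epsilon_never_coarsens_partition(self, planted_affinity):
        """A smaller gap threshold is crossed no later, so K(1.02) <= K(1.5)."""
        aff, _ = planted_affinity
        k_small = spectral_cluster(aff, SpectralOptions(epsilon=1.02, seed=1))
        k_large = spectral_cluster(aff, SpectralOptions(epsilon=1.5, seed=1))
        assert k_small.n_clusters <= k_large.n_clusters


def test_options_validation():
    with pytest.raises(ValueError):
        SpectralOptions(epsilon=1.0)
    with pytest.raises(ValueError):
        SpectralOptions(mode="exact")
    with pytest.raises(ValueError):
        SpectralOptions(mode="bounded")
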