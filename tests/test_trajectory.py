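import numpy as np
import pytest

from orsmell.errors import ValidationError
from orsmell.io_catalog import ExpressionMatrix, LOG2_TPM1, TPM
from orsmell.trajectory import (
    TrajectoryResult,
    _knn_graph,
    compute_pseudotime,
    embed_and_cluster,
    pseudotime_correlations,
    select_root,
)
from orsmell.repertoire import RepertoireProfile


def _blob_matrix(rng, n_per=200, n_genes=40, sep=12.0):
    """Two well-separated Gaussian blobs in expression space."""
    a = rng.normal(5, 1, size=(n_genes, n_per))
    b = rng.normal(5, 1, size=(n_genes, n_per))
    b[: n_genes // 2] += sep
    values = np.abs(np.hstack([a, b]))
    return ExpressionMatrix(values, [f"g{i}" for i in range(n_genes)],
                            [f"c{j}" for j in range(2 * n_per)], LOG2_TPM1)


def _result(embedding, clusters=None):
    n = embedding.shape[0]
    return TrajectoryResult([f"c{i}" for i in range(n)], embedding,
                            clusters if clusters is not None else np.zeros(n, int))


class TestEmbedAndCluster:
    def test_two_blobs_never_merge(self, rng):
        m = _blob_matrix(rng)
        res = embed_and_cluster(m, n_pcs=10, k_nn=15, seed=0)
        truth = np.array([0] * 200 + [1] * 200)
        # communities refine the blobs: every cluster is pure in blob identity
        for c in np.unique(res.clusters):
            members = truth[res.clusters == c]
            assert len(set(members)) == 1
        assert len(np.unique(res.clusters)) >= 2

    def test_duplicated_cells_cluster_together(self, rng):
        # three tight, well-separated blobs, every cell duplicated: the
        # communities coincide with the blobs, so each duplicate pair must
        # land in one community
        blobs = []
        for b in range(3):
            center = rng.uniform(3, 8, size=30) + 30.0 * b
            blobs.append(center[:, None] + rng.normal(0, 0.2, size=(30, 15)))
        base = np.abs(np.hstack(blobs))
        values = np.hstack([base, base])
        m = ExpressionMatrix(values, [f"g{i}" for i in range(30)],
                             [f"c{j}" for j in range(90)], LOG2_TPM1)
        res = embed_and_cluster(m, n_pcs=5, k_nn=10, seed=0)
        truth = np.tile(np.repeat([0, 1, 2], 15), 2)
        for c in np.unique(res.clusters):
            assert len(set(truth[res.clusters == c])) == 1  # blob-pure
        for j in range(45):
            assert res.clusters[j] == res.clusters[j + 45]

    def test_all_identical_cells_rejected(self):
        values = np.tile(np.arange(1.0, 21.0)[:, None], (1, 40))
        m = ExpressionMatrix(values, [f"g{i}" for i in range(20)],
                             [f"c{j}" for j in range(40)], TPM)
        with pytest.raises(ValidationError, match="zero variance"):
            embed_and_cluster(m, n_pcs=5, k_nn=5, seed=0)

    def test_needs_more_cells_than_pcs(self, rng):
        m = _blob_matrix(rng, n_per=5, n_genes=10)
        with pytest.raises(ValidationError, match="more cells"):
            embed_and_cluster(m, n_pcs=30, k_nn=3, seed=0)

    def test_deterministic(self, rng):
        m = _blob_matrix(rng, n_per=50)
        a = embed_and_cluster(m, n_pcs=5, k_nn=10, seed=1)
        b = embed_and_cluster(m, n_pcs=5, k_nn=10, seed=1)
        np.testing.assert_array_equal(a.clusters, b.clusters)
        np.testing.assert_allclose(a.embedding, b.embedding)


class TestSelectRoot:
    def test_argmax_mean_stemness(self):
        emb = np.arange(12, dtype=float).reshape(6, 2)
        clusters = np.array([0, 0, 1, 1, 2, 2])
        stemness = np.array([0.1, 0.1, 0.9, 0.9, 0.4, 0.4])
        res = select_root(_result(emb, clusters), stemness)
        assert res.root_cluster == 1
        assert res.root_cell in (2, 3)

    def test_single_cluster_is_root(self):
        res = select_root(_result(np.zeros((3, 2))), np.array([0.5, 0.2, 0.9]))
        assert res.root_cluster == 0

    def test_tie_goes_to_smaller_id_with_warning(self):
        clusters = np.array([0, 0, 1, 1])
        stemness = np.array([0.5, 0.5, 0.5, 0.5])
        with pytest.warns(UserWarning, match="tie"):
            res = select_root(_result(np.zeros((4, 2)), clusters), stemness)
        assert res.root_cluster == 0

    def test_medoid_minimizes_total_distance(self):
        emb = np.array([[0.0, 0], [1.0, 0], [10.0, 0]])
        res = select_root(_result(emb), np.ones(3))
        assert res.root_cell == 1  # middle point is the medoid


class TestComputePseudotime:
    def test_chain_graph_monotone_and_rescaled(self):
        emb = np.column_stack([np.arange(10, dtype=float), np.zeros(10)])
        res = _result(emb)
        res.root_cluster, res.root_cell = 0, 0
        res = compute_pseudotime(res, k_nn=2)
        pt = res.pseudotime
        assert pt[0] == 0.0
        assert np.all(np.diff(pt) > 0)  # strictly monotone along the chain
        assert pt.max() == pytest.approx(1.0)
        # equally spaced chain: geodesic equals cumulative distance
        np.testing.assert_allclose(pt, np.arange(10) / 9.0, atol=1e-12)

    def test_rotation_invariance(self, rng):
        emb = rng.normal(size=(60, 3))
        theta = 0.83
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        res1 = _result(emb)
        res1.root_cell = 0
        res1 = compute_pseudotime(res1, k_nn=6)
        res2 = _result(emb @ rot.T)
        res2.root_cell = 0
        res2 = compute_pseudotime(res2, k_nn=6)
        np.testing.assert_allclose(res1.pseudotime, res2.pseudotime, atol=1e-9)

    def test_triangle_inequality_on_graph_edges(self, rng):
        from scipy.sparse.csgraph import dijkstra

        emb = rng.normal(size=(80, 4))
        adj = _knn_graph(emb, 8)
        raw_dist = dijkstra(adj, directed=False, indices=0)
        coo = adj.tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            assert raw_dist[i] <= raw_dist[j] + w + 1e-9

    def test_unreachable_cells_flagged(self):
        emb = np.array([[0.0, 0], [0.1, 0], [0.2, 0], [100.0, 0], [100.1, 0]])
        res = _result(emb)
        res.root_cell = 0
        with pytest.warns(UserWarning, match="unreachable"):
            res = compute_pseudotime(res, k_nn=1)
        assert np.isnan(res.pseudotime[3]) and np.isnan(res.pseudotime[4])
        assert np.isfinite(res.pseudotime[:3]).all()

    def test_root_required_first(self):
        with pytest.raises(ValidationError, match="select_root"):
            compute_pseudotime(_result(np.zeros((5, 2))), k_nn=2)


class TestPseudotimeCorrelations:
    def _ready_result(self, n=40):
        emb = np.column_stack([np.linspace(0, 10, n), np.zeros(n)])
        res = _result(emb)
        res.root_cell = 0
        return compute_pseudotime(res, k_nn=3)

    def test_exact_negative_relation(self):
        res = self._ready_result()
        pt = res.pseudotime
        stemness = 1.0 - pt
        profile = RepertoireProfile(res.sample_ids,
                                    np.arange(len(pt))[::-1], np.zeros(len(pt)))
        table = pseudotime_correlations(res, stemness, profile)
        row = table[(table["x"] == "pseudotime") & (table["y"] == "stemness")]
        assert row["r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        res = self._ready_result()
        profile = RepertoireProfile(res.sample_ids,
                                    np.full(len(res.sample_ids), 2),
                                    np.zeros(len(res.sample_ids)))
        table = pseudotime_correlations(res, 1 - res.pseudotime, profile)
        or_row = table[table["y"] == "or_count"]
        assert or_row["test_used"].iloc[0] == "skipped_zero_variance"

    def test_too_few_cells_rejected(self):
        res = self._ready_result(n=12)
        res.pseudotime[3:] = np.nan
        profile = RepertoireProfile(res.sample_ids, np.arange(12), np.zeros(12))
        with pytest.raises(ValidationError, match="at least 10"):
            pseudotime_correlations(res, np.ones(12), profile)
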