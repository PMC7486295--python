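import numpy as np
import pytest

from orsmell.activation import ActivationMatrix
from orsmell.errors import ValidationError
from orsmell.io_catalog import ExpressionMatrix, LOG2_TPM1, TPM
from orsmell.stratification import (
    Signature,
    SimilarityMatrix,
    build_or_signatures,
    cosine_similarity,
    project_signatures,
    stratify_patients,
)


class TestCosineSimilarity:
    def test_self_similarity_is_one(self, rng):
        a = rng.uniform(0.1, 5, size=20)
        assert cosine_similarity(a, a) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_worked_example(self):
        value = cosine_similarity(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert value == pytest.approx(32 / np.sqrt(14 * 77), abs=1e-9)
        assert value == pytest.approx(0.97463, abs=1e-5)

    def test_scale_invariance(self, rng):
        a = rng.uniform(0.1, 5, size=30)
        b = rng.uniform(0.1, 5, size=30)
        base = cosine_similarity(a, b)
        for alpha in (1e-6, 0.5, 7.0, 1e6):
            assert cosine_similarity(alpha * a, b) == pytest.approx(base, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            cosine_similarity(np.zeros(3), np.ones(3))


def _activation_and_expression(binary, rng):
    """Binary OR profiles + a matching positive expression matrix."""
    binary = np.asarray(binary, np.int8)
    n_or, n_cells = binary.shape
    genes = [f"OR{i}F" for i in range(n_or)]
    cells = [f"c{j}" for j in range(n_cells)]
    amat = ActivationMatrix(binary, genes, cells, -3.0)
    expr = np.where(binary, rng.uniform(3, 6, size=binary.shape), 0.0)
    em = ExpressionMatrix(expr, genes, cells, LOG2_TPM1)
    return em, amat


class TestBuildOrSignatures:
    def test_disjoint_populations_recovered(self, rng):
        # 10 cells using ORs 0-3, 10 cells using ORs 4-7
        binary = np.zeros((8, 20), dtype=int)
        binary[:4, :10] = rng.random((4, 10)) < 0.8
        binary[4:, 10:] = rng.random((4, 10)) < 0.8
        binary[0, 0] = 1
        binary[4, 10] = 1  # ensure no all-zero cells
        em, amat = _activation_and_expression(binary, rng)
        sigs = build_or_signatures(em, amat, n_clusters=2)
        assert len(sigs) == 2
        supports = [set(np.array(s.gene_ids)[s.values > 0]) for s in sigs]
        assert supports[0].isdisjoint(supports[1])

    def test_singleton_clusters_reproduce_cells(self, rng):
        binary = np.eye(4, dtype=int)
        em, amat = _activation_and_expression(binary, rng)
        sigs = build_or_signatures(em, amat, n_clusters=4)
        assert len(sigs) == 4
        assert all(s.n_cells == 1 for s in sigs)
        # each signature equals its cell's expression exactly
        cell_cols = {tuple(np.round(em.values[:, j], 12)) for j in range(4)}
        sig_cols = {tuple(np.round(s.values, 12)) for s in sigs}
        assert sig_cols == cell_cols

    def test_mean_or_count_tracks_population_density(self, rng):
        # population A: the same single OR per cell; population B: four ORs
        binary = np.zeros((8, 30), dtype=int)
        binary[0, :15] = 1
        binary[4:8, 15:] = 1
        em, amat = _activation_and_expression(binary, rng)
        sigs = build_or_signatures(em, amat, n_clusters=2)
        counts = sorted(s.mean_or_count for s in sigs)
        assert counts[0] == pytest.approx(1.0)
        assert counts[1] == pytest.approx(4.0)

    def test_identical_profiles_cannot_split(self, rng):
        binary = np.tile(np.array([[1], [0], [1]]), (1, 6))
        em, amat = _activation_and_expression(binary, rng)
        with pytest.raises(ValidationError, match="one binary"):
            build_or_signatures(em, amat, n_clusters=2)

    def test_auto_selects_two_for_two_populations(self, rng):
        binary = np.zeros((10, 40), dtype=int)
        binary[:5, :20] = rng.random((5, 20)) < 0.9
        binary[5:, 20:] = rng.random((5, 20)) < 0.9
        binary[0, :20] = 1
        binary[5, 20:] = 1
        em, amat = _activation_and_expression(binary, rng)
        sigs = build_or_signatures(em, amat, n_clusters="auto")
        assert len(sigs) == 2


def _signatures_from(matrix):
    genes = [f"OR{i}F" for i in range(matrix.shape[0])]
    return [
        Signature(cluster_id=k, gene_ids=genes, values=matrix[:, k],
                  n_cells=5, mean_or_count=1.0)
        for k in range(matrix.shape[1])
    ]


class TestProjectSignatures:
    def test_bulk_column_equal_to_signature_scores_one(self, rng):
        sig_log = rng.uniform(1, 5, size=(12, 3))
        sigs = _signatures_from(sig_log)
        bulk_tpm = np.exp2(sig_log) - 1.0  # log2(TPM+1) reproduces signatures
        bulk = ExpressionMatrix(bulk_tpm, sigs[0].gene_ids,
                                ["p0", "p1", "p2"], TPM)
        sim = project_signatures(bulk, sigs)
        for j in range(3):
            assert sim.values[j, j] == pytest.approx(1.0, abs=1e-12)
            assert np.argmax(sim.values[j]) == j

    def test_entries_bounded_in_unit_interval(self, rng):
        sigs = _signatures_from(rng.uniform(0, 5, size=(15, 4)))
        bulk = ExpressionMatrix(rng.uniform(0, 100, size=(15, 10)),
                                sigs[0].gene_ids,
                                [f"p{j}" for j in range(10)], TPM)
        sim = project_signatures(bulk, sigs)
        assert (sim.values >= 0).all() and (sim.values <= 1 + 1e-12).all()

    def test_missing_or_genes_zero_filled_with_warning(self, rng):
        sigs = _signatures_from(rng.uniform(1, 5, size=(10, 2)))
        bulk = ExpressionMatrix(rng.uniform(1, 50, size=(6, 3)),
                                sigs[0].gene_ids[:6],
                                ["p0", "p1", "p2"], TPM)
        with pytest.warns(UserWarning):
            sim = project_signatures(bulk, sigs, min_shared=3)
        assert sim.values.shape == (3, 2)

    def test_zero_or_patient_flagged(self, rng):
        sigs = _signatures_from(rng.uniform(1, 5, size=(8, 2)))
        bulk_values = rng.uniform(1, 50, size=(8, 3))
        bulk_values[:, 1] = 0.0
        bulk = ExpressionMatrix(bulk_values, sigs[0].gene_ids,
                                ["p0", "p1", "p2"], TPM)
        with pytest.warns(UserWarning, match="all-zero"):
            sim = project_signatures(bulk, sigs)
        assert not sim.valid[1]
        assert sim.valid[[0, 2]].all()

    def test_no_shared_genes_rejected(self, rng):
        sigs = _signatures_from(rng.uniform(1, 5, size=(5, 2)))
        bulk = ExpressionMatrix(rng.uniform(1, 5, size=(4, 2)),
                                ["x1", "x2", "x3", "x4"], ["p0", "p1"], TPM)
        with pytest.raises(ValidationError, match="shares no"):
            project_signatures(bulk, sigs)


class TestStratifyPatients:
    def _sim(self, values, valid=None):
        values = np.asarray(values, float)
        n = values.shape[0]
        return SimilarityMatrix(
            values, [f"p{i}" for i in range(n)],
            list(range(values.shape[1])),
            np.ones(n, bool) if valid is None else valid,
        )

    def test_duplicated_patients_share_groups(self, rng):
        rows = rng.uniform(0, 1, size=(20, 3))
        sim = self._sim(np.vstack([rows, rows]))
        sim = stratify_patients(sim, 2)
        np.testing.assert_array_equal(sim.groups[:20], sim.groups[20:])

    def test_two_planted_populations_recovered(self, rng):
        a = np.tile([0.9, 0.1, 0.1], (30, 1)) + rng.normal(0, 0.05, (30, 3))
        b = np.tile([0.1, 0.9, 0.1], (30, 1)) + rng.normal(0, 0.05, (30, 3))
        sim = self._sim(np.vstack([a, b]))
        sim = stratify_patients(sim, "auto")
        from sklearn.metrics import adjusted_rand_score

        truth = np.array([0] * 30 + [1] * 30)
        assert adjusted_rand_score(truth, sim.groups) >= 0.9

    def test_single_group_noop(self, rng):
        sim = self._sim(rng.uniform(0, 1, size=(10, 2)))
        sim = stratify_patients(sim, 1)
        assert set(sim.groups) == {0}

    def test_invalid_rows_get_minus_one(self, rng):
        values = rng.uniform(0, 1, size=(12, 2))
        valid = np.ones(12, bool)
        valid[4] = False
        sim = stratify_patients(self._sim(values, valid), 2)
        assert sim.groups[4] == -1
        assert (sim.groups[valid] >= 0).all()

    def test_too_many_groups_rejected(self, rng):
        sim = self._sim(rng.uniform(0, 1, size=(4, 2)))
        with pytest.raises(ValidationError, match="more groups"):
            stratify_patients(sim, 10)
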